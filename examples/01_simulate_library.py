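"""Generate a toy genome plus a full-length cDNA read library.

Builds a 12-gene genome with spliced genes, readthrough clusters and
tandem duplicates, then emits error-laden reads with a ground-truth
manifest. The printed numbers describe what the downstream stages will
have to recover.
"""

from longform import SimConfig, simulate_all

cfg = SimConfig(seed=42, n_genes=12, error_rates=(0.002, 0.010, 0.008))
truth = simulate_all(cfg)

n_fl = sum(r.is_full_length for r in truth.reads)
print(f"genome: {len(truth.genome[cfg.chrom]):,} bp, {len(truth.genes)} genes")
print(f"isoforms: {len(truth.isoforms)} "
      f"({len(truth.ptu_isoforms())} polycistronic readthrough)")
print(f"reads: {len(truth.reads)} ({n_fl} full-length, "
      f"{len(truth.reads) - n_fl} 5'-degraded)")
iso = truth.isoforms[0]
print(f"example isoform {iso.id}: {iso.chain.n_exons} exons, "
      f"{iso.chain.exonic_length()} nt, class {iso.pas_class}")
# every read in the manifest points at exactly one source isoform;
# the classifier and clusterer below are graded against this truth
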