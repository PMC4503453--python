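"""Generator contracts: geometry, determinism, implanted signals, error model."""

import edlib
import numpy as np
import pytest

from longform import SimConfig, simulate_all, simulate_genome, simulate_isoforms
from longform.sim import (
    STOP_CODONS,
    simulate_reads,
    simulate_short_read_support,
)

from conftest import ERR15


def test_single_gene_single_exon_degenerate():
    """One intronless gene: the transcript is a literal genome slice."""
    cfg = SimConfig(seed=2, n_genes=1, exon_count_range=(1, 1), ptu_fraction=0,
                    tandem_dup_fraction=0, isoform_mean_extra=0)
    ann = simulate_genome(cfg)
    assert len(ann.genes) == 1
    g = ann.genes[0]
    assert g.chain.n_exons == 1
    isoforms, truth = simulate_isoforms(ann, cfg)
    assert len(isoforms) == 1
    seq = isoforms[0].seq(ann.genome)
    s, e = g.chain.exons[0]
    expected = ann.genome[g.chain.chrom][s:e]
    if g.strand == "-":
        from longform import revcomp

        expected = revcomp(expected)
    assert seq == expected


def test_tandem_duplicates_adjacent_same_strand():
    cfg = SimConfig(seed=3, n_genes=10, tandem_dup_fraction=0.2, ptu_fraction=0)
    ann = simulate_genome(cfg)
    dups = [g for g in ann.genes if g.dup_of]
    assert len(dups) == 2
    by_id = {g.id: g for g in ann.genes}
    order = [g.id for g in ann.genes]
    for d in dups:
        src = by_id[d.dup_of]
        assert src.strand == d.strand
        assert abs(order.index(d.id) - order.index(src.id)) == 1


def test_seed_determinism_byte_identical():
    cfg = SimConfig(seed=4, n_genes=6)
    t1, t2 = simulate_all(cfg), simulate_all(cfg)
    assert t1.genome == t2.genome
    assert t1.manifest() == t2.manifest()
    assert t1._read_seqs == t2._read_seqs


def test_all_introns_are_gt_ag(truth_errorfree):
    for iso in truth_errorfree.isoforms:
        for d, a in iso.chain.junction_dinucleotides(truth_errorfree.genome):
            assert (d, a) == ("GT", "AG")


def test_genes_non_overlapping(truth_errorfree):
    genes = sorted(truth_errorfree.genes, key=lambda g: g.chain.start)
    for a, b in zip(genes, genes[1:]):
        assert a.chain.end <= b.chain.start


def test_ptu_inter_orf_stops_in_all_frames(truth_default_errorfree):
    """Every readthrough isoform's inter-ORF region must contain a stop
    codon in each of the three reading frames (asserted on sequence)."""
    t = truth_default_errorfree
    for iso in t.ptu_isoforms():
        seq = iso.seq(t.genome)
        pos_index = {p: i for i, p in enumerate(iso.chain.genomic_positions())}
        spans = []
        for gid in iso.gene_ids:
            gene = t.gene(gid)
            pts = sorted(
                pos_index[p] for s, e in gene.cds_genomic for p in range(s, e)
            )
            spans.append((pts[0], pts[-1] + 1))
        spans.sort()
        assert len(spans) >= 2
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            gap = seq[e1:s2]
            for f in range(3):
                assert any(
                    gap[p : p + 3] in STOP_CODONS
                    for p in range(f, len(gap) - 2, 3)
                ), f"no frame-{f} stop between ORFs of {iso.id}"


def test_nue_composition_terminal_vs_internal(truth_default_errorfree):
    """Mean A-fraction at -30..-10 exceeds 0.5 at terminal poly(A) sites
    and stays at background for internal (pORF1-class) sites, recomputed
    directly from the emitted genome sequence."""
    t = truth_default_errorfree
    from longform import revcomp

    def upstream(chain, w=60):
        pas = chain.three_prime_pos()
        contig = t.genome[chain.chrom]
        if chain.strand == "+":
            return contig[pas - w : pas]
        return revcomp(contig[pas : pas + w])

    term, internal = [], []
    for iso in t.isoforms:
        win = upstream(iso.chain)[30:50]  # positions -30..-11
        frac = win.count("A") / len(win)
        (internal if iso.pas_class == "pORF1" else term).append(frac)
    assert np.mean(term) > 0.5
    assert abs(np.mean(internal) - 0.25) < 0.1


def test_errorfree_fl_reads_identical_after_orientation():
    cfg = SimConfig(seed=6, n_genes=1, ptu_fraction=0, tandem_dup_fraction=0,
                    isoform_mean_extra=0, error_rates=(0, 0, 0),
                    fl_coverage_per_isoform=5, nonfl_fraction=0,
                    polyA_len_range=(20, 21))
    truth = simulate_all(cfg)
    from longform import revcomp

    seqs = set()
    for (rid, seq, q), rec in zip(truth._read_seqs, truth.reads):
        assert rec.is_full_length
        seqs.add(seq if rec.strand == "+" else revcomp(seq))
    assert len(seqs) == 1
    read = seqs.pop()
    iso_seq = truth.isoforms[0].seq(truth.genome)
    assert read.startswith(cfg.primer5)
    assert iso_seq in read


def test_nonfl_fraction_one_no_primer5():
    cfg = SimConfig(seed=7, n_genes=2, ptu_fraction=0, tandem_dup_fraction=0,
                    nonfl_fraction=1.0, error_rates=(0, 0, 0))
    truth = simulate_all(cfg)
    assert truth.reads and all(not r.is_full_length for r in truth.reads)
    from longform import revcomp

    for (rid, seq, q), rec in zip(truth._read_seqs, truth.reads):
        oriented = seq if rec.strand == "+" else revcomp(seq)
        window = oriented[: 100 + len(cfg.primer5)]
        hit = edlib.align(cfg.primer5, window, mode="HW", task="distance",
                          k=int(0.3 * len(cfg.primer5)))
        assert hit["editDistance"] < 0


def test_read_count_matches_manifest(truth_small):
    assert len(truth_small._read_seqs) == len(truth_small.reads)


def test_observed_error_rate_near_fifteen_percent():
    """Aligning reads back to their source template recovers the
    configured ~15% total error rate within 2 percentage points."""
    cfg = SimConfig(seed=8, n_genes=10, error_rates=ERR15, nonfl_fraction=0)
    truth = simulate_all(cfg)
    from longform import revcomp

    iso_seq = {i.id: i.seq(truth.genome) for i in truth.isoforms}
    dists, lens = [], []
    for (rid, seq, q), rec in zip(truth._read_seqs, truth.reads):
        template = (
            cfg.primer5 + iso_seq[rec.isoform_id]
        )  # polyA length is random; align template prefix region only
        oriented = seq if rec.strand == "+" else revcomp(seq)
        res = edlib.align(template, oriented, mode="HW", task="distance")
        dists.append(res["editDistance"])
        lens.append(len(template))
    rate = sum(dists) / sum(lens)
    assert abs(rate - 0.15) < 0.02


def test_shortread_support_rules():
    cfg = SimConfig(seed=9, n_genes=3, ptu_fraction=0, tandem_dup_fraction=0,
                    isoform_mean_extra=0, shortread_scale=1.0,
                    shortread_noise=False, fl_coverage_per_isoform=10,
                    min_isoform_coverage=0)
    ann = simulate_genome(cfg)
    isoforms, truth = simulate_isoforms(ann, cfg)
    cov, junc = simulate_short_read_support(isoforms, truth.abundances, cfg)
    assert set(cov["coverage"]) == {10.0}
    exonic = {
        (i.chain.chrom, p) for i in isoforms for s, e in i.chain.exons
        for p in range(s, e)
    }
    assert set(zip(cov["chrom"], cov["pos"])) == exonic
    assert (junc["support"] == 10).all()


def test_shortread_poisson_moments():
    """With noise on and shared expected coverage, the empirical
    variance/mean ratio of the emitted counts is ~1 (Poisson)."""
    cfg = SimConfig(seed=10, n_genes=4, ptu_fraction=0, tandem_dup_fraction=0,
                    isoform_mean_extra=0, shortread_scale=2.0,
                    fl_coverage_per_isoform=10, min_isoform_coverage=0)
    ann = simulate_genome(cfg)
    isoforms, truth = simulate_isoforms(ann, cfg)
    cov, _ = simulate_short_read_support(isoforms, truth.abundances, cfg)
    vals = cov["coverage"].to_numpy()
    ratio = vals.var() / vals.mean()
    assert 0.8 < ratio < 1.2


def test_invalid_configs_fail():
    with pytest.raises(ValueError):
        SimConfig(ptu_span_range=(2, 5)).validate()
    with pytest.raises(ValueError):
        SimConfig(error_rates=(-0.1, 0, 0)).validate()
    with pytest.raises(ValueError):
        simulate_genome(SimConfig(n_genes=4, ptu_fraction=1.0,
                                  tandem_dup_fraction=0.9))
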