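"""Synthetic genome / transcriptome / long-read generator with ground truth.

The generator emulates the statistical structure of a compact fungal
transcriptome as seen by full-length cDNA sequencing:

* spliced genes with GT..AG introns, multiple isoforms per locus
  (exon skipping, alternative donors/acceptors, alternative poly(A),
  alternative TSS);
* readthrough clusters of 2-4 adjacent same-strand genes whose
  polycistronic transcript retains the intergenic sequence, with stop
  codons guaranteed in all three inter-ORF reading frames;
* adjacent same-strand tandem gene duplicates (near-copies);
* A-rich NUE (-30..-10) and U-rich FUE (-60..-30) elements implanted
  upstream of terminal cleavage sites but NOT at the internal sites of
  readthrough clusters (genes that are non-final cluster members);
* full-length reads (5' primer + transcript + polyA + 3' primer) and
  5'-degraded reads, corrupted by an i.i.d. indel-dominant error model;
* per-base short-read coverage and junction-support tables derived from
  isoform abundances.

Every output is a deterministic function of the :class:`SimConfig`
(including its seed). Read counts are fixed at the rounded expected
abundance so that reruns are byte-identical.

Intron internals are engineered so that splice boundaries are
unambiguous under alignment: a C-pad flanks every GT donor and AG
acceptor, and the 33-nt alternative donor/acceptor cassettes are T-free
(so they can never introduce an in-frame stop codon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chains import ExonChain, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)
# all-frame stop block: contains TAA starting at offsets 2, 6 and 10,
# which cover all three frames whatever the phase of the insertion
STOP_BLOCK = "ATTAATTAATTAA"

ALT_SHIFT = 33  # nt gained by an alternative donor/acceptor
_PAD = 8  # C-pad length around splice dinucleotides


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (40, 300)  # min/max CDS chunk target
    intron_len_range: tuple[int, int] = (90, 150)
    # per-locus extra isoforms ~ Poisson(mean), capped; applies to
    # loci outside readthrough clusters
    isoform_mean_extra: float = 2.5
    max_isoforms_per_locus: int = 5
    ptu_fraction: float = 0.5
    ptu_span_range: tuple[int, int] = (2, 4)
    inter_orf_distance_mean: int = 364
    inter_orf_distance_sd: int = 60
    tandem_dup_fraction: float = 0.1
    tandem_divergence: float = 0.08
    # readthrough clusters host the tandem duplicates: PTUs are
    # enriched in tandem gene duplicates
    dup_in_ptu_fraction: float = 1.0
    fl_coverage_per_isoform: float = 20.0
    min_isoform_coverage: float = 5.0
    nonfl_fraction: float = 0.25
    error_rates: tuple[float, float, float] = (0.01, 0.08, 0.06)  # sub, ins, del
    polyA_len_range: tuple[int, int] = (15, 40)
    primer5: str = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
    primer3: str = "CGCCTGAGAGTGCTAGTCGTACTTGCAATT"
    downstream_tier_factor: float = 0.5
    ptu_isoform_rel_abundance: float = 0.5
    utr5_len_range: tuple[int, int] = (90, 150)
    utr3_len_range: tuple[int, int] = (150, 220)
    cds_aa_range: tuple[int, int] = (150, 300)
    intergenic_len_range: tuple[int, int] = (700, 1200)
    apa_offset: int = 80
    alt_tss_offset: int = 60
    # deep short-read support: expected per-base coverage is
    # shortread_scale x isoform abundance
    shortread_scale: float = 10.0
    shortread_noise: bool = True
    chrom: str = "chr1"

    def validate(self) -> None:
        lo, hi = self.ptu_span_range
        if not (2 <= lo <= hi <= 4):
            raise ValueError("ptu_span_range must lie within [2, 4]")
        if any(r < 0 for r in self.error_rates):
            raise ValueError("error rates must be non-negative")
        if sum(self.error_rates) >= 1:
            raise ValueError("total error rate must be < 1")
        if len(self.primer5) < 10 or len(self.primer3) < 10:
            raise ValueError("primers must be >= 10 nt")

    @property
    def total_error(self) -> float:
        return float(sum(self.error_rates))


@dataclass
class Gene:
    id: str
    chain: ExonChain
    cds_genomic: tuple[tuple[int, int], ...] = ()
    dup_of: str | None = None
    ptu_id: str | None = None
    ptu_index: int | None = None  # 1-based position in transcription order

    @property
    def strand(self) -> str:
        return self.chain.strand

    @property
    def is_internal_ptu_member(self) -> bool:
        """Non-final member of a readthrough cluster: its poly(A) site is
        the cluster's internal (pORF1-class) site and carries no NUE/FUE."""
        return self.ptu_id is not None and not self.is_final_ptu_member

    is_final_ptu_member: bool = True


@dataclass
class Annotation:
    genome: dict[str, str]
    genes: list[Gene]
    ptus: dict[str, list[str]] = field(default_factory=dict)  # ptu id -> gene ids


@dataclass
class Isoform:
    id: str
    gene_ids: tuple[str, ...]
    chain: ExonChain
    kind: str  # canonical | exon_skip | alt_acceptor | alt_donor | apa | alt_tss | ptu
    pas_class: str  # nORF | pORF1 | pORF2
    abundance: float

    def seq(self, genome: dict[str, str]) -> str:
        return self.chain.transcript_seq(genome)


@dataclass
class ReadRecord:
    id: str
    isoform_id: str
    is_full_length: bool
    truncation_offset: int
    strand: str


@dataclass
class GroundTruth:
    config: SimConfig
    genome: dict[str, str]
    genes: list[Gene]
    isoforms: list[Isoform]
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def abundances(self) -> dict[str, float]:
        return {iso.id: iso.abundance for iso in self.isoforms}

    def gene(self, gid: str) -> Gene:
        return next(g for g in self.genes if g.id == gid)

    def isoform(self, iid: str) -> Isoform:
        return next(i for i in self.isoforms if i.id == iid)

    def ptu_isoforms(self) -> list[Isoform]:
        return [i for i in self.isoforms if i.kind == "ptu"]

    def fl_read_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            if r.is_full_length:
                counts[r.isoform_id] = counts.get(r.isoform_id, 0) + 1
        return counts

    def protein(self, gid: str) -> str:
        g = self.gene(gid)
        chain = ExonChain(g.chain.chrom, g.chain.strand, g.cds_genomic)
        cds = chain.transcript_seq(self.genome)
        return _translate(cds)

    def manifest(self) -> dict:
        return {
            "genes": [
                {
                    "id": g.id,
                    "chrom": g.chain.chrom,
                    "start": g.chain.start,
                    "end": g.chain.end,
                    "strand": g.strand,
                    "exons": list(map(list, g.chain.exons)),
                    "cds": list(map(list, g.cds_genomic)),
                    "dup_of": g.dup_of,
                    "ptu_id": g.ptu_id,
                    "ptu_index": g.ptu_index,
                }
                for g in self.genes
            ],
            "isoforms": [
                {
                    "id": i.id,
                    "gene_ids": list(i.gene_ids),
                    "chrom": i.chain.chrom,
                    "strand": i.chain.strand,
                    "exons": list(map(list, i.chain.exons)),
                    "kind": i.kind,
                    "pas_class": i.pas_class,
                    "pas_pos": i.chain.three_prime_pos(),
                    "abundance": i.abundance,
                }
                for i in self.isoforms
            ],
            "reads": [
                {
                    "id": r.id,
                    "isoform_id": r.isoform_id,
                    "is_full_length": r.is_full_length,
                    "truncation_offset": r.truncation_offset,
                    "strand": r.strand,
                }
                for r in self.reads
            ],
        }


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    return prot.rstrip("*")


# --------------------------------------------------------------- gene design


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


def _no_t(rng: np.random.Generator, n: int) -> str:
    return _rand_seq(rng, n, "ACG")


@dataclass
class _GeneDesign:
    """Transcript-sense blueprint of one gene, pre-genome-placement."""

    utr5: str
    codons: list[str]  # ATG + sense codons + stop
    utr3: str
    cuts: list[int]  # sense cut points between exons
    introns: list[str]

    @property
    def mrna(self) -> str:
        return self.utr5 + "".join(self.codons) + self.utr3

    def exon_sense_intervals(self) -> list[tuple[int, int]]:
        bounds = [0] + self.cuts + [len(self.mrna)]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _primer_like(seq: str, cfg: SimConfig) -> bool:
    """Does any transcript region resemble a sequencing primer closely
    enough to confuse read classification? Library primers are chosen
    not to cross-match the transcriptome; the generator enforces it."""
    import edlib

    for p in (cfg.primer5, cfg.primer3):
        k = int(0.3 * len(p)) + 1
        for pat in (p, revcomp(p)):
            if edlib.align(pat, seq, mode="HW", task="distance",
                           k=k)["editDistance"] >= 0:
                return True
    return False


def _make_intron(rng: np.random.Generator, length: int) -> str:
    """Alt-capable intron: GTC + T-free donor cassette + C-pads + random
    middle + C-pads + T-free acceptor cassette + AG. The cassettes at
    offsets [0, 33) and [L-33, L) are the exonic gains of the 33-nt
    alternative donor/acceptor, with secondary GT/AG at [33,35)/[L-35,L-33)."""
    if length < 2 * (ALT_SHIFT + 2 + _PAD) + 4:
        raise ValueError(f"intron length {length} too short for alt cassettes")
    head = "GTC" + _no_t(rng, ALT_SHIFT - 3 - _PAD) + "C" * _PAD + "GT" + "C" * _PAD
    tail = "C" * _PAD + "AG" + _no_t(rng, ALT_SHIFT - 2 - _PAD) + "C" * _PAD + "AG"
    middle = _rand_seq(rng, length - len(head) - len(tail))
    return head + middle + tail


def _design_gene(rng: np.random.Generator, cfg: SimConfig) -> _GeneDesign:
    for _ in range(30):
        d = _design_gene_once(rng, cfg)
        if not _primer_like(d.mrna, cfg):
            return d
    raise RuntimeError("could not design a primer-free gene in 30 draws")


def _design_gene_once(rng: np.random.Generator, cfg: SimConfig) -> _GeneDesign:
    u5 = _rand_seq(rng, int(rng.integers(*cfg.utr5_len_range)))
    aa = int(rng.integers(*cfg.cds_aa_range))
    codons = ["ATG"] + [
        SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), aa - 1)
    ] + [STOP_CODONS[int(rng.integers(0, 3))]]
    # 3'UTR: the 12 nt upstream of each cleavage site (canonical end and
    # the APA-shifted site) are A-free so the polyA-tail boundary of an
    # error-free read is unambiguous
    u3l = int(rng.integers(*cfg.utr3_len_range))
    u3 = list(_rand_seq(rng, u3l))
    for j in range(1, 13):
        u3[u3l - j] = _rand_seq(rng, 1, "CGT")
        u3[u3l - cfg.apa_offset - j] = _rand_seq(rng, 1, "CGT")
    u3 = "".join(u3)
    mrna_len = len(u5) + 3 * len(codons) + len(u3)

    lo, hi = cfg.exon_count_range
    k = int(rng.integers(lo, hi + 1))
    # first exon keeps the whole 5'UTR (alt-TSS room), last exon keeps the
    # whole 3'UTR plus the APA offset and signal windows
    first_min = len(u5) + 10
    last_min = len(u3) + cfg.apa_offset + 30
    min_chunk = max(40, cfg.exon_len_range[0])
    interior = mrna_len - first_min - last_min
    k = max(1, min(k, 1 + interior // min_chunk)) if interior > 0 else 1
    cuts: list[int] = []
    if k > 1:
        lo_cut, hi_cut = first_min, mrna_len - last_min
        for _ in range(50):
            cand = sorted(rng.integers(lo_cut, hi_cut, k - 1).tolist())
            gaps = np.diff([lo_cut - min_chunk] + cand + [hi_cut + min_chunk])
            if (gaps >= min_chunk).all():
                cuts = [int(c) for c in cand]
                break
        else:
            cuts = []
    introns = [
        _make_intron(rng, int(rng.integers(*cfg.intron_len_range)))
        for _ in range(len(cuts))
    ]
    return _GeneDesign(u5, codons, u3, cuts, introns)


def _mutate_design(
    rng: np.random.Generator, d: _GeneDesign, rate: float, cfg: SimConfig
) -> _GeneDesign:
    """Near-copy for a tandem duplicate: substitutions in UTRs and intron
    middles, whole-codon replacement in the CDS; splice cassettes are
    left intact so the copy stays a functional spliced gene."""

    def mut_seq(s: str) -> str:
        out = list(s)
        for i in np.flatnonzero(rng.random(len(s)) < rate):
            out[i] = "ACGT".replace(out[i], "")[int(rng.integers(0, 3))]
        return "".join(out)

    for _ in range(30):
        codons = list(d.codons)
        for i in range(1, len(codons) - 1):
            if rng.random() < 3 * rate:
                codons[i] = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
        introns = []
        guard = ALT_SHIFT + 2 + _PAD  # keep heads/tails with cassettes intact
        for intr in d.introns:
            mid = mut_seq(intr[guard:-guard])
            introns.append(intr[:guard] + mid + intr[-guard:])
        out = _GeneDesign(mut_seq(d.utr5), codons, mut_seq(d.utr3),
                          list(d.cuts), introns)
        if not _primer_like(out.mrna, cfg):
            return out
    raise RuntimeError("could not mutate a duplicate free of primer matches")


# ----------------------------------------------------------- genome assembly


def _realize_gene(
    design: _GeneDesign, strand: str, gstart: int, chrom: str
) -> tuple[str, ExonChain, tuple[tuple[int, int], ...]]:
    """Lay a designed gene at genomic offset ``gstart``; returns
    (genomic segment, exon chain, CDS genomic intervals)."""
    sense_parts: list[str] = []
    exon_sense: list[tuple[int, int]] = []
    pos = 0
    intervals = design.exon_sense_intervals()
    mrna = design.mrna
    for i, (s, e) in enumerate(intervals):
        sense_parts.append(mrna[s:e])
        exon_sense.append((pos, pos + (e - s)))
        pos += e - s
        if i < len(design.introns):
            sense_parts.append(design.introns[i])
            pos += len(design.introns[i])
    segment_sense = "".join(sense_parts)
    seg_len = len(segment_sense)

    # CDS interval in mRNA coordinates -> sense genomic coordinates
    cds_lo = len(design.utr5)
    cds_hi = cds_lo + 3 * len(design.codons)
    cds_sense: list[tuple[int, int]] = []
    for (s, e), (gs, ge) in zip(intervals, exon_sense):
        lo = max(cds_lo, s)
        hi = min(cds_hi, e)
        if lo < hi:
            cds_sense.append((gs + (lo - s), gs + (hi - s)))

    if strand == "+":
        segment = segment_sense
        exons = tuple((gstart + s, gstart + e) for s, e in exon_sense)
        cds = tuple((gstart + s, gstart + e) for s, e in cds_sense)
    else:
        segment = revcomp(segment_sense)
        exons = tuple(
            sorted((gstart + seg_len - e, gstart + seg_len - s) for s, e in exon_sense)
        )
        cds = tuple(
            sorted((gstart + seg_len - e, gstart + seg_len - s) for s, e in cds_sense)
        )
    return segment, ExonChain(chrom, strand, exons), cds


def _ptu_gap(rng: np.random.Generator, cfg: SimConfig) -> str:
    """Inter-ORF spacer (transcript sense) with stop blocks at both ends
    and every ~90 nt, so no reading frame can run through it."""
    n = int(
        np.clip(rng.normal(cfg.inter_orf_distance_mean, cfg.inter_orf_distance_sd),
                150, 650)
    )
    for _ in range(30):
        gap = list(_rand_seq(rng, n))
        offsets = list(range(0, n - len(STOP_BLOCK), 90)) + [n - len(STOP_BLOCK)]
        for off in offsets:
            gap[off : off + len(STOP_BLOCK)] = STOP_BLOCK
        out = "".join(gap)
        if not _primer_like(out, cfg):
            return out
    raise RuntimeError("could not draw a primer-free inter-ORF spacer")


def simulate_genome(config: SimConfig) -> Annotation:
    """Generate the toy genome and its gene annotation.

    Genes are non-overlapping and separated by intergenic gaps;
    readthrough-cluster members are adjacent, same-strand, and spaced by
    ~``inter_orf_distance_mean``; tandem duplicates are adjacent
    same-strand near-copies of their source gene.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    # ---- unit plan: PTU clusters, tandem pairs, singles
    n_ptu_genes = int(round(config.n_genes * config.ptu_fraction))
    cluster_sizes: list[int] = []
    remaining = n_ptu_genes
    while remaining >= 2:
        size = int(min(rng.integers(config.ptu_span_range[0],
                                    config.ptu_span_range[1] + 1), remaining))
        cluster_sizes.append(size)
        remaining -= size
    n_clustered = sum(cluster_sizes)
    n_dup_pairs = int(round(config.n_genes * config.tandem_dup_fraction))
    n_dup_in_ptu = min(len(cluster_sizes),
                       int(round(n_dup_pairs * config.dup_in_ptu_fraction)))
    n_free_pairs = n_dup_pairs - n_dup_in_ptu
    n_singles = config.n_genes - n_clustered - 2 * n_free_pairs
    if n_singles < 0:
        raise ValueError(
            "infeasible plan: ptu_fraction and tandem_dup_fraction demand "
            f"more than n_genes={config.n_genes} genes"
        )

    units: list[tuple[str, int]] = (
        [("ptu", s) for s in cluster_sizes]
        + [("pair", 2)] * n_free_pairs
        + [("single", 1)] * n_singles
    )
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    # PTU clusters hosting an internal duplicate pair: first n_dup_in_ptu
    # clusters in layout order
    ptu_seen = 0

    chrom = config.chrom
    parts: list[str] = []
    pos = 0
    genes: list[Gene] = []
    ptus: dict[str, list[str]] = {}
    gidx = 0
    pidx = 0

    def gap(lo=None, hi=None) -> None:
        nonlocal pos
        g = _rand_seq(rng, int(rng.integers(*(config.intergenic_len_range
                                              if lo is None else (lo, hi)))))
        parts.append(g)
        pos += len(g)

    gap()
    for kind, size in units:
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "single":
            gidx += 1
            d = _design_gene(rng, config)
            seg, chain, cds = _realize_gene(d, strand, pos, chrom)
            parts.append(seg)
            pos += len(seg)
            genes.append(Gene(f"g{gidx:03d}", chain, cds))
            gap()
        elif kind == "pair":
            gidx += 1
            src_id = f"g{gidx:03d}"
            d = _design_gene(rng, config)
            d2 = _mutate_design(rng, d, config.tandem_divergence, config)
            seg, chain, cds = _realize_gene(d, strand, pos, chrom)
            parts.append(seg)
            pos += len(seg)
            genes.append(Gene(src_id, chain, cds))
            gap(200, 500)
            gidx += 1
            seg2, chain2, cds2 = _realize_gene(d2, strand, pos, chrom)
            parts.append(seg2)
            pos += len(seg2)
            genes.append(Gene(f"g{gidx:03d}", chain2, cds2, dup_of=src_id))
            gap()
        else:  # ptu cluster
            pidx += 1
            ptu_seen += 1
            ptu_id = f"ptu{pidx:02d}"
            with_dup = ptu_seen <= n_dup_in_ptu
            designs = [_design_gene(rng, config)]
            for j in range(1, size):
                if with_dup and j == 1:
                    designs.append(_mutate_design(
                        rng, designs[0], config.tandem_divergence, config))
                else:
                    designs.append(_design_gene(rng, config))
            gaps = [_ptu_gap(rng, config) for _ in range(size - 1)]
            # layout left->right follows transcription order on '+', the
            # reverse on '-'; gap sequence is written in transcript sense
            layout = list(range(size)) if strand == "+" else list(range(size))[::-1]
            member: dict[int, Gene] = {}
            for li, j in enumerate(layout):
                gidx += 1
                d = designs[j]
                seg, chain, cds = _realize_gene(d, strand, pos, chrom)
                parts.append(seg)
                pos += len(seg)
                gene = Gene(
                    f"g{gidx:03d}",
                    chain,
                    cds,
                    dup_of=None,
                    ptu_id=ptu_id,
                    ptu_index=j + 1,
                )
                if with_dup and j == 1:
                    gene.dup_of = member[0].id if 0 in member else "pending"
                member[j] = gene
                genes.append(gene)
                if li < size - 1:
                    nxt = layout[li + 1]
                    gseq = gaps[min(j, nxt)]
                    parts.append(gseq if strand == "+" else revcomp(gseq))
                    pos += len(gseq)
            if with_dup and member[1].dup_of == "pending":
                member[1].dup_of = member[0].id
            for j in range(size):
                member[j].is_final_ptu_member = j == size - 1
            ptus[ptu_id] = [member[j].id for j in range(size)]
            gap()

    genome = {chrom: "".join(parts)}
    genes.sort(key=lambda g: g.chain.start)
    ann = Annotation(genome=genome, genes=genes, ptus=ptus)
    _implant_pas_signals(rng, ann, config)
    return ann


def _implant_pas_signals(
    rng: np.random.Generator, ann: Annotation, cfg: SimConfig
) -> None:
    """Write A-rich NUE (-30..-10) and U-rich FUE (-60..-30) upstream of
    every terminal cleavage site (canonical and APA-shifted); internal
    (pORF1-class) sites of readthrough clusters get neither."""
    chrom = cfg.chrom
    g = list(ann.genome[chrom])

    def implant(pas: int, strand: str) -> None:
        # sense offset j in 1..60 upstream of the cleavage site; the
        # last 12 nt stay A-free so the NUE cannot mimic a polyA tail
        for j in range(1, 61):
            if 30 < j <= 60:
                base = "T" if rng.random() < 0.70 else _rand_seq(rng, 1)
            elif 12 < j <= 30:
                base = "A" if rng.random() < 0.60 else _rand_seq(rng, 1)
            else:
                base = _rand_seq(rng, 1, "CGT")
            if strand == "+":
                g[pas - j] = base
            else:
                g[pas + j - 1] = revcomp(base)

    for gene in ann.genes:
        if gene.is_internal_ptu_member:
            continue
        pas = gene.chain.three_prime_pos()
        shift = cfg.apa_offset if gene.strand == "+" else -cfg.apa_offset
        implant(pas - shift, gene.strand)  # APA site first
        implant(pas, gene.strand)  # canonical site wins on overlap

    ann.genome[chrom] = "".join(g)


# ------------------------------------------------------------------ isoforms


def _shift_exon(
    exons: tuple[tuple[int, int], ...], idx: int, dstart: int = 0, dend: int = 0
) -> tuple[tuple[int, int], ...]:
    out = list(exons)
    s, e = out[idx]
    out[idx] = (s + dstart, e + dend)
    return tuple(out)


def _variant_chain(chain: ExonChain, kind: str, cfg: SimConfig,
                   rng: np.random.Generator) -> ExonChain | None:
    exons = chain.exons
    n = len(exons)
    plus = chain.strand == "+"
    if kind == "exon_skip":
        if n < 3:
            return None
        idx = int(rng.integers(1, n - 1))
        return ExonChain(chain.chrom, chain.strand, exons[:idx] + exons[idx + 1 :])
    if kind == "alt_acceptor":
        if n < 2:
            return None
        j = int(rng.integers(0, n - 1))  # intron index, genomic order
        # acceptor side = transcript-downstream exon of that intron
        new = (
            _shift_exon(exons, j + 1, dstart=-ALT_SHIFT)
            if plus
            else _shift_exon(exons, j, dend=ALT_SHIFT)
        )
        return ExonChain(chain.chrom, chain.strand, new)
    if kind == "alt_donor":
        if n < 2:
            return None
        j = int(rng.integers(0, n - 1))
        new = (
            _shift_exon(exons, j, dend=ALT_SHIFT)
            if plus
            else _shift_exon(exons, j + 1, dstart=-ALT_SHIFT)
        )
        return ExonChain(chain.chrom, chain.strand, new)
    if kind == "apa":
        new = (
            _shift_exon(exons, n - 1, dend=-cfg.apa_offset)
            if plus
            else _shift_exon(exons, 0, dstart=cfg.apa_offset)
        )
        return ExonChain(chain.chrom, chain.strand, new)
    if kind == "alt_tss":
        new = (
            _shift_exon(exons, 0, dstart=cfg.alt_tss_offset)
            if plus
            else _shift_exon(exons, n - 1, dend=-cfg.alt_tss_offset)
        )
        return ExonChain(chain.chrom, chain.strand, new)
    raise ValueError(kind)


def _merge_readthrough(chains: list[ExonChain]) -> ExonChain:
    """Join member chains in transcription order into one readthrough
    chain: the gap between consecutive genes stays exonic."""
    strand = chains[0].strand
    ordered = chains if strand == "+" else chains[::-1]  # genomic left->right
    exons: list[tuple[int, int]] = list(ordered[0].exons)
    for ch in ordered[1:]:
        nxt = list(ch.exons)
        exons[-1] = (exons[-1][0], nxt[0][1])  # bridge across the gap
        exons.extend(nxt[1:])
    return ExonChain(chains[0].chrom, strand, tuple(exons))


def simulate_isoforms(
    annotation: Annotation, config: SimConfig
) -> tuple[list[Isoform], GroundTruth]:
    """Draw per-locus isoform sets plus one readthrough isoform per PTU
    cluster, with abundances (downstream cluster members are expressed at
    ``downstream_tier_factor`` per tier)."""
    rng = np.random.default_rng([config.seed, 1])
    isoforms: list[Isoform] = []
    skipped: list[str] = []

    for gene in annotation.genes:
        tier = (
            config.downstream_tier_factor ** (gene.ptu_index - 1)
            if gene.ptu_index
            else 1.0
        )
        base_ab = max(config.fl_coverage_per_isoform * tier,
                      config.min_isoform_coverage)
        pas_class = "pORF1" if gene.is_internal_ptu_member else "nORF"
        iso_id = f"{gene.id}.i1"
        isoforms.append(
            Isoform(iso_id, (gene.id,), gene.chain, "canonical", pas_class, base_ab)
        )
        if gene.ptu_id:
            # readthrough-cluster members get exactly two isoforms each
            # (canonical + one always-feasible variant): a deterministic
            # count keeps the locus-level expression tiers set by the
            # tier factor alone, not by how many variants a locus drew
            kinds = ["alt_acceptor", "alt_donor", "apa", "alt_tss"]
            n_extra = 1
        else:
            kinds = ["exon_skip", "alt_acceptor", "alt_donor", "apa", "alt_tss"]
            n_extra = int(
                min(rng.poisson(config.isoform_mean_extra),
                    config.max_isoforms_per_locus - 1, len(kinds))
            )
        # sample event kinds without replacement: two draws of the same
        # kind would yield indistinguishable (duplicate) isoforms
        drawn = [kinds[i] for i in rng.permutation(len(kinds))[:n_extra]]
        for j, kind in enumerate(drawn):
            var = _variant_chain(gene.chain, kind, config, rng)
            if var is None:
                skipped.append(f"{gene.id}:{kind}")
                continue
            isoforms.append(
                Isoform(
                    f"{gene.id}.i{j + 2}",
                    (gene.id,),
                    var,
                    kind,
                    pas_class,
                    base_ab,
                )
            )

    gene_by_id = {g.id: g for g in annotation.genes}
    for ptu_id, gids in sorted(annotation.ptus.items()):
        chains = [gene_by_id[g].chain for g in gids]
        chain = _merge_readthrough(chains)
        isoforms.append(
            Isoform(
                f"{ptu_id}.rt",
                tuple(gids),
                chain,
                "ptu",
                "pORF2",
                config.fl_coverage_per_isoform * config.ptu_isoform_rel_abundance,
            )
        )

    truth = GroundTruth(
        config=config,
        genome=annotation.genome,
        genes=annotation.genes,
        isoforms=isoforms,
    )
    return isoforms, truth


# --------------------------------------------------------------------- reads


def _corrupt(
    rng: np.random.Generator, seq: str, rates: tuple[float, float, float]
) -> str:
    sub, ins, dele = rates
    if sub == ins == dele == 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    for ch in seq:
        if rng.random() < ins:
            out.append(bases[int(rng.integers(0, 4))])
        r = rng.random()
        if r < dele:
            continue
        if r < dele + sub:
            out.append("ACGT".replace(ch, "")[int(rng.integers(0, 3))])
        else:
            out.append(ch)
    if rng.random() < ins:
        out.append(bases[int(rng.integers(0, 4))])
    return "".join(out)


def simulate_reads(
    isoforms: list[Isoform],
    abundances: dict[str, float],
    config: SimConfig,
    genome: dict[str, str],
) -> tuple[list[tuple[str, str, list[int]]], list[ReadRecord]]:
    """Emit reads-of-insert and their manifest records.

    A full-length read is primer5 + transcript + polyA + revcomp(primer3)
    on a random strand; a non-FL read additionally loses its 5' primer
    and a uniform 5' fraction of the transcript. Counts per isoform are
    the rounded expectation (FL) and its nonfl_fraction complement.
    """
    rng = np.random.default_rng([config.seed, 2])
    if not isoforms:
        import warnings

        warnings.warn("empty isoform set: emitting no reads")
        return [], []
    q = 40 if config.total_error == 0 else max(
        2, int(round(-10 * math.log10(config.total_error)))
    )
    reads: list[tuple[str, str, list[int]]] = []
    records: list[ReadRecord] = []
    f = config.nonfl_fraction
    n_read = 0
    for iso in isoforms:
        ab = abundances.get(iso.id, 0.0)
        if f >= 1.0:
            n_fl, n_nfl = 0, int(round(ab))
        else:
            n_fl = int(round(ab))
            n_nfl = int(round(ab * f / (1.0 - f)))
        t = iso.seq(genome)
        for is_fl in [True] * n_fl + [False] * n_nfl:
            polyA = "A" * int(rng.integers(*config.polyA_len_range))
            if is_fl and f < 1.0:
                insert = config.primer5 + t + polyA + revcomp(config.primer3)
                trunc = 0
            else:
                trunc = int(rng.integers(0, max(1, len(t) // 2)))
                insert = t[trunc:] + polyA + revcomp(config.primer3)
                is_fl = False
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                insert = revcomp(insert)
            obs = _corrupt(rng, insert, config.error_rates)
            n_read += 1
            rid = f"read{n_read:06d}"
            reads.append((rid, obs, [q] * len(obs)))
            records.append(ReadRecord(rid, iso.id, is_fl, trunc, strand))
    return reads, records


# -------------------------------------------------------- short-read support


def simulate_short_read_support(
    isoforms: list[Isoform],
    abundances: dict[str, float],
    config: SimConfig,
):
    """Per-base genomic coverage and junction-support tables.

    Coverage at a genomic base = scale x sum of abundances of isoforms
    whose exons contain it (optionally Poisson-noised); junction support
    = scale x summed abundance of isoforms using that junction.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 3])
    cov: dict[tuple[str, int], float] = {}
    junc: dict[tuple[str, int, int, str], float] = {}
    for iso in isoforms:
        ab = abundances.get(iso.id, 0.0) * config.shortread_scale
        for s, e in iso.chain.exons:
            for p in range(s, e):
                key = (iso.chain.chrom, p)
                cov[key] = cov.get(key, 0.0) + ab
        for a, b in iso.chain.junctions:
            key = (iso.chain.chrom, a, b, iso.chain.strand)
            junc[key] = junc.get(key, 0.0) + ab
    cov_items = sorted(cov.items())
    cov_vals = np.array([v for _, v in cov_items])
    if config.shortread_noise:
        cov_vals = rng.poisson(cov_vals).astype(float)
    coverage = pd.DataFrame(
        {
            "chrom": [k[0] for k, _ in cov_items],
            "pos": [k[1] for k, _ in cov_items],
            "coverage": cov_vals,
        }
    )
    junc_items = sorted(junc.items())
    junctions = pd.DataFrame(
        {
            "chrom": [k[0] for k, _ in junc_items],
            "donor": [k[1] for k, _ in junc_items],
            "acceptor": [k[2] for k, _ in junc_items],
            "strand": [k[3] for k, _ in junc_items],
            "support": [round(v) for _, v in junc_items],
        }
    )
    return coverage, junctions


def simulate_all(config: SimConfig) -> GroundTruth:
    """Convenience driver: genome -> isoforms -> reads, returning the
    populated ground truth; read sequences are regenerated on demand by
    :func:`simulate_reads` (same seed, same bytes)."""
    ann = simulate_genome(config)
    isoforms, truth = simulate_isoforms(ann, config)
    reads, records = simulate_reads(isoforms, truth.abundances, config, ann.genome)
    truth.reads = records
    truth._read_seqs = reads  # cached for in-process pipelines
    return truth
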