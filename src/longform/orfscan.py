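"""ORF prediction on transcripts and polycistronic transcription-unit calls.

A polycistronic transcription unit (PTU) is a transcript carrying two or
more substantial, non-overlapping ORFs that correspond to independently
annotated same-strand genes. Calls are validated by inter-ORF stop
codons in all three reading frames (ruling out a single misannotated
ORF), by continuous short-read coverage across the inter-ORF regions,
and by junction support; downstream analyses quantify the independent
expression tiers of member ORFs and the enrichment of tandem gene
duplicates among PTU members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.special import logsumexp

from .chains import ExonChain
from .sim import STOP_CODONS, Gene
from .splicemap import SplicedAlignment

START = "ATG"


@dataclass(frozen=True)
class ORF:
    transcript_id: str
    start: int  # transcript coordinates, 0-based half-open, includes stop
    end: int
    frame: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass
class PolycistronicCall:
    transcript_id: str
    orfs: list[ORF]
    contained_genes: list[str]
    overlapped_genes: list[str]
    inter_orf_gaps: list[int]
    stops_all_frames: list[bool]  # one flag per inter-ORF gap
    category: str  # contained_2_4 | readthrough_partial
    shortread_validated: bool | None = None


def _all_orfs(seq: str, min_aa: int, transcript_id: str) -> list[ORF]:
    out = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == START:
                starts.append(pos)
            elif codon in STOP_CODONS:
                for s in starts:
                    orf = ORF(transcript_id, s, pos + 3, frame)
                    if orf.aa_length >= min_aa:
                        out.append(orf)
                starts = []
    return out


def find_orfs(seq: str, min_aa: int = 100, transcript_id: str = "t") -> list[ORF]:
    """Complete forward-frame ORFs (ATG..stop, stop included) of at
    least ``min_aa`` amino acids, reduced to a non-overlapping subset
    greedily by descending length (ties: leftmost), reported 5'->3'."""
    candidates = sorted(
        _all_orfs(seq, min_aa, transcript_id), key=lambda o: (-o.aa_length, o.start)
    )
    chosen: list[ORF] = []
    for orf in candidates:
        if all(orf.end <= c.start or orf.start >= c.end for c in chosen):
            chosen.append(orf)
    return sorted(chosen, key=lambda o: o.start)


def check_inter_orf_stops(
    seq: str, orf_a: ORF, orf_b: ORF
) -> tuple[tuple[bool, bool, bool], bool]:
    """Is there a stop codon in each of the three frames of the gap
    between two ORFs? Gaps shorter than one codon are degenerate (all
    False)."""
    if orf_a.end > orf_b.start:
        raise ValueError("orf_a must lie upstream of orf_b")
    gap = seq[orf_a.end : orf_b.start]
    if len(gap) < 3:
        return (False, False, False), False
    flags = tuple(
        any(
            gap[pos : pos + 3] in STOP_CODONS
            for pos in range(f, len(gap) - 2, 3)
        )
        for f in range(3)
    )
    return flags, all(flags)


def call_polycistronic(
    transcript_id: str,
    seq: str,
    orfs: list[ORF],
    alignment: SplicedAlignment | None,
    genes: list[Gene],
) -> PolycistronicCall | None:
    """Call a PTU on a transcript with >=2 qualifying ORFs.

    With an annotation, the call requires >=2 same-strand annotated
    genes at least overlapped by the alignment span; 2-4 fully contained
    genes give category ``contained_2_4``, otherwise
    ``readthrough_partial``. With an empty annotation (annotation-free
    mode) the >=2-ORF criterion alone makes the call.
    """
    if len(orfs) < 2:
        return None
    contained: list[str] = []
    overlapped: list[str] = []
    if alignment is not None and genes:
        ch = alignment.chain
        for gene in genes:
            gch = gene.chain
            if gch.chrom != ch.chrom or gch.strand != ch.strand:
                continue
            if gch.start < ch.end and ch.start < gch.end:
                overlapped.append(gene.id)
                if gch.start >= ch.start and gch.end <= ch.end:
                    contained.append(gene.id)
        if len(overlapped) < 2:
            return None
        category = "contained_2_4" if 2 <= len(contained) <= 4 else "readthrough_partial"
    else:
        category = "readthrough_partial"
    gaps = []
    stops = []
    for a, b in zip(orfs, orfs[1:]):
        gaps.append(b.start - a.end)
        stops.append(check_inter_orf_stops(seq, a, b)[1])
    return PolycistronicCall(
        transcript_id=transcript_id,
        orfs=list(orfs),
        contained_genes=contained,
        overlapped_genes=overlapped,
        inter_orf_gaps=gaps,
        stops_all_frames=stops,
        category=category,
    )


def scan_transcripts(
    transcripts: dict[str, str],
    alignments: dict[str, SplicedAlignment],
    genes: list[Gene],
    min_aa: int = 100,
) -> tuple[dict[str, list[ORF]], list[PolycistronicCall]]:
    """ORF-scan every transcript and collect PTU calls."""
    orfs_by_tx: dict[str, list[ORF]] = {}
    calls: list[PolycistronicCall] = []
    for tid in sorted(transcripts):
        orfs = find_orfs(transcripts[tid], min_aa, tid)
        orfs_by_tx[tid] = orfs
        call = call_polycistronic(
            tid, transcripts[tid], orfs, alignments.get(tid), genes
        )
        if call is not None:
            calls.append(call)
    return orfs_by_tx, calls


def validate_shortread(
    call: PolycistronicCall,
    chain: ExonChain,
    coverage: pd.DataFrame,
    junctions: pd.DataFrame,
    min_cov: float = 10.0,
) -> bool:
    """Continuous short-read support: every genomic base under the
    transcript's inter-ORF regions must have coverage >= ``min_cov``
    and every junction of the transcript must have support >= 1.
    Missing coverage rows count as zero coverage."""
    cov = {
        (c, p): v
        for c, p, v in zip(coverage["chrom"], coverage["pos"], coverage["coverage"])
    }
    positions = chain.genomic_positions()
    for a, b in zip(call.orfs, call.orfs[1:]):
        for tpos in range(a.end, b.start):
            if cov.get((chain.chrom, positions[tpos]), 0.0) < min_cov:
                return False
    sup = {
        (c, d, a): s
        for c, d, a, s in zip(
            junctions["chrom"], junctions["donor"], junctions["acceptor"],
            junctions["support"],
        )
    }
    for d, a in chain.junctions:
        if sup.get((chain.chrom, d, a), 0) < 1:
            return False
    return True


def expression_tiers(
    calls: list[PolycistronicCall],
    alignments: dict[str, SplicedAlignment],
    fl_counts: dict[str, int],
    genes: list[Gene],
) -> pd.DataFrame:
    """Independent per-ORF expression within each PTU.

    The independent expression of member ORF_k is the summed
    full-length read count of *monocistronic* transcripts of its locus
    — transcripts overlapping that gene and no other — excluding reads
    supporting the polycistronic isoform itself. Rows preserve ORF order
    5'->3'; loci without any independent transcript get expression 0 and
    a flag.
    """
    gene_by_id = {g.id: g for g in genes}
    ptu_tx = {c.transcript_id for c in calls}
    overlaps: dict[str, list[str]] = {}
    for tid, aln in alignments.items():
        ch = aln.chain
        hits = [
            g.id
            for g in genes
            if g.chain.chrom == ch.chrom
            and g.chain.strand == ch.strand
            and g.chain.start < ch.end
            and ch.start < g.chain.end
        ]
        overlaps[tid] = hits
    rows = []
    for call in calls:
        member_genes = call.contained_genes or call.overlapped_genes
        ordered = sorted(
            member_genes,
            key=lambda gid: gene_by_id[gid].chain.start,
            reverse=gene_by_id[member_genes[0]].chain.strand == "-",
        )
        for k, gid in enumerate(ordered, start=1):
            count = sum(
                fl_counts.get(tid, 0)
                for tid, hits in overlaps.items()
                if hits == [gid] and tid not in ptu_tx
            )
            rows.append(
                {
                    "ptu_transcript": call.transcript_id,
                    "orf_index": k,
                    "gene_id": gid,
                    "independent_fl_count": count,
                    "no_independent_transcript": count == 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ptu_transcript",
            "orf_index",
            "gene_id",
            "independent_fl_count",
            "no_independent_transcript",
        ],
    )


def tandem_enrichment(n_genes: int, tandem_genes: int, ptu_genes: int,
                      ptu_tandem_genes: int) -> float:
    """Upper-tail hypergeometric probability of seeing >= k tandem-
    duplicate genes among the PTU-involved genes, computed in log space.

    p = sum_{i=k..min(K,n)} C(K,i) C(N-K, n-i) / C(N,n)
    """
    N, K, n, k = n_genes, tandem_genes, ptu_genes, ptu_tandem_genes
    if not (0 <= k <= min(K, n) <= N and n <= N and K <= N):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0

    def logC(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = logC(N, n)
    terms = [
        logC(K, i) + logC(N - K, n - i) - denom
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ]
    return float(min(1.0, math.exp(logsumexp(terms))))
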