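"""Exact splice-chain evaluation of transcript sets.

A query transcript is an exact match of a reference transcript when it
has the same chromosome, strand, exon count and the identical ordered
list of donor-acceptor coordinates; terminal exon outer boundaries are
deliberately not compared (5'/3' end slack), and single-exon
transcripts match by >=50% reciprocal overlap. Scoring restricts to
loci detected by both sets, reports sensitivity (references recovered)
and specificity (queries validated), stratifies both by per-locus
isoform complexity, and tallies how many of several query sets recover
each reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chains import ExonChain


def exact_match(
    query: ExonChain, reference: ExonChain, single_exon_overlap: float = 0.5
) -> bool:
    if query.chrom != reference.chrom or query.strand != reference.strand:
        return False
    if query.n_exons != reference.n_exons:
        return False
    if query.n_exons > 1:
        return query.junctions == reference.junctions
    (qs, qe), (rs, re_) = query.exons[0], reference.exons[0]
    ov = min(qe, re_) - max(qs, rs)
    if ov <= 0:
        return False
    return ov >= single_exon_overlap * (qe - qs) and ov >= single_exon_overlap * (
        re_ - rs
    )


@dataclass
class ScoreReport:
    sensitivity: float
    specificity: float
    n_reference: int
    n_query: int
    per_bin: pd.DataFrame  # complexity bin -> sensitivity/specificity
    shared_loci: int


def score_sets(
    query: dict[str, ExonChain],
    reference: dict[str, ExonChain],
    loci: dict[str, str],
    complexity_cap: int = 5,
) -> ScoreReport:
    """Score a query transcript set against a reference set.

    ``loci`` maps every transcript id (both sets) to a locus id; only
    loci present in both sets are scored. Bins are keyed by the number
    of reference isoforms at the locus, capped at ``complexity_cap``.
    """
    q_loci = {loci[q] for q in query if q in loci}
    r_loci = {loci[r] for r in reference if r in loci}
    shared = q_loci & r_loci
    if not shared:
        import warnings

        warnings.warn("no loci shared between query and reference sets")
        empty = pd.DataFrame(
            columns=["complexity", "sensitivity", "specificity", "n_ref", "n_query"]
        )
        return ScoreReport(0.0, 0.0, 0, 0, empty, 0)
    qs = {q: ch for q, ch in query.items() if loci.get(q) in shared}
    rs = {r: ch for r, ch in reference.items() if loci.get(r) in shared}

    ref_complex: dict[str, int] = {}
    for r in rs:
        ref_complex[loci[r]] = ref_complex.get(loci[r], 0) + 1

    def matched_ref(r: str) -> bool:
        return any(exact_match(qch, rs[r]) for qch in qs.values())

    def matched_query(q: str) -> bool:
        return any(exact_match(qs[q], rch) for rch in rs.values())

    ref_hit = {r: matched_ref(r) for r in rs}
    q_hit = {q: matched_query(q) for q in qs}

    rows = []
    for b in range(1, complexity_cap + 1):
        rsel = [r for r in rs if min(ref_complex[loci[r]], complexity_cap) == b]
        qsel = [
            q
            for q in qs
            if min(ref_complex.get(loci[q], 0), complexity_cap) == b
        ]
        rows.append(
            {
                "complexity": b,
                "sensitivity": (
                    sum(ref_hit[r] for r in rsel) / len(rsel) if rsel else float("nan")
                ),
                "specificity": (
                    sum(q_hit[q] for q in qsel) / len(qsel) if qsel else float("nan")
                ),
                "n_ref": len(rsel),
                "n_query": len(qsel),
            }
        )
    return ScoreReport(
        sensitivity=sum(ref_hit.values()) / len(rs),
        specificity=sum(q_hit.values()) / len(qs),
        n_reference=len(rs),
        n_query=len(qs),
        per_bin=pd.DataFrame(rows),
        shared_loci=len(shared),
    )


def recovery_frequency(
    query_sets: dict[str, dict[str, ExonChain]],
    reference: dict[str, ExonChain],
) -> pd.DataFrame:
    """For each reference transcript, by how many of the query sets is
    it exactly recovered? Returns one row per reference with the count
    and per-set flags."""
    rows = []
    for r, rch in sorted(reference.items()):
        flags = {
            name: any(exact_match(qch, rch) for qch in qset.values())
            for name, qset in sorted(query_sets.items())
        }
        rows.append({"reference": r, "n_sets": sum(flags.values()), **flags})
    return pd.DataFrame(rows)
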