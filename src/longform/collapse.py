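"""Merge transcripts that differ only at the 5' start of their first exon.

Redundancy in full-length cDNA sets comes from 5'-degraded molecules:
the same isoform sequenced from different start points. Transcripts are
grouped when they share the identical junction chain and (to within a
tolerance absorbing polyA-trimming jitter) the same 3' end; only the
longest survives. Alternative splicing and alternative polyadenylation
are never merged; alternative transcription starts are, by design, and
the merge audit records what was absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chains import ExonChain
from .cluster import ClusterParams, same_isoform
from .splicemap import SplicedAlignment

TOL3P = 30  # 3'-end tolerance, nt


@dataclass
class CollapseResult:
    survivors: list[str]
    merged_into: dict[str, str]  # absorbed id -> survivor id
    groups: list[list[str]]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def mergeable_mapped(a: ExonChain, b: ExonChain, tol3p: int = TOL3P) -> bool:
    """Pairwise 5'-redundancy rule for mapped transcripts."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if abs(a.three_prime_pos() - b.three_prime_pos()) > tol3p:
        return False
    if a.n_exons > 1 or b.n_exons > 1:
        return a.junctions == b.junctions
    # single-exon: shorter interval contained in the longer's
    (s1, e1), (s2, e2) = a.exons[0], b.exons[0]
    if e1 - s1 <= e2 - s2:
        return s1 >= s2 and e1 <= e2
    return s2 >= s1 and e2 <= e1


def collapse_mapped(
    alignments: list[SplicedAlignment], tol3p: int = TOL3P
) -> CollapseResult:
    """Transitive closure of the pairwise rule; within each group the
    transcript with the longest aligned (exonic) span survives."""
    ids = sorted(a.query_id for a in alignments)
    by_id = {a.query_id: a for a in alignments}
    uf = _UnionFind(ids)
    for i, qa in enumerate(ids):
        for qb in ids[i + 1 :]:
            if mergeable_mapped(by_id[qa].chain, by_id[qb].chain, tol3p):
                uf.union(qa, qb)
    return _resolve(uf, ids, key=lambda q: (by_id[q].chain.exonic_length(), q))


def collapse_unmapped(
    transcripts: dict[str, str],
    tol3p: int = TOL3P,
    min_cov: float = 0.99,
    min_ident: float = 0.99,
) -> CollapseResult:
    """Reference-free collapse: the shorter transcript merges into the
    longer when an overlap alignment with a free gap only at the 5' end
    covers >= ``min_cov`` of the shorter at identity >= ``min_ident``
    and the 3' ends agree within ``tol3p``."""
    params = ClusterParams(
        tol3=tol3p,
        tol5=10**9,  # 5' start is exactly what may differ here
        min_cov=min_cov,
        min_ident=min_ident,
        max_internal_gap=10,
    )
    ids = sorted(transcripts)
    uf = _UnionFind(ids)
    for i, qa in enumerate(ids):
        for qb in ids[i + 1 :]:
            ok, _ = same_isoform(transcripts[qa], transcripts[qb], params)
            if ok:
                uf.union(qa, qb)
    return _resolve(uf, ids, key=lambda q: (len(transcripts[q]), q))


def _resolve(uf: _UnionFind, ids: list[str], key) -> CollapseResult:
    groups: dict[str, list[str]] = {}
    for q in ids:
        groups.setdefault(uf.find(q), []).append(q)
    survivors: list[str] = []
    merged_into: dict[str, str] = {}
    out_groups: list[list[str]] = []
    for root in sorted(groups):
        members = sorted(groups[root])
        keep = max(members, key=key)
        survivors.append(keep)
        out_groups.append(members)
        for m in members:
            if m != keep:
                merged_into[m] = keep
    return CollapseResult(sorted(survivors), merged_into, out_groups)
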