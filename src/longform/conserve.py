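"""Conservation of adjacent gene configurations across annotated genomes.

For each adjacent ORF pair from a polycistronic transcript, the pair is
conserved in another species when both proteins have best hits there
that lie directly adjacent (consecutive gene ranks on one contig) on
the same strand. Best hits are one-way by default (a reciprocal mode is
available); scoring is local protein alignment with BLOSUM62 and affine
gap penalties 11/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class GeneOrderEntry:
    contig: str
    rank: int
    gene_id: str
    strand: str


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def best_hits(
    query: dict[str, str], subject: dict[str, str], min_score: float = 50.0
) -> dict[str, str]:
    """Best-scoring subject per query (ties: lexicographically smallest
    subject id); queries with no subject at ``min_score`` are absent."""
    if not subject:
        return {}
    aligner = _aligner()
    out: dict[str, str] = {}
    for qid in sorted(query):
        best: tuple[float, str] | None = None
        for sid in sorted(subject):
            try:
                score = aligner.score(query[qid], subject[sid])
            except ValueError:  # non-standard residue
                continue
            if score >= min_score and (best is None or score > best[0]):
                best = (score, sid)
        if best is not None:
            out[qid] = best[1]
    return out


def pair_conservation(
    orf_pairs: list[tuple[str, str]],
    source_proteome: dict[str, str],
    species: dict[str, tuple[dict[str, str], list[GeneOrderEntry]]],
    min_score: float = 50.0,
    reciprocal: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Conservation matrix (pair x species) plus per-species totals.

    ``species`` maps a species name to (proteome, gene order). Pair
    (A, B) is conserved in species S iff best_hit(A) and best_hit(B)
    exist, sit at consecutive ranks on one contig of S, and share
    strand. Genes missing from the order table are not conserved.
    """
    needed = sorted({g for pair in orf_pairs for g in pair})
    queries = {g: source_proteome[g] for g in needed}
    matrix: dict[str, list[bool]] = {}
    for name in sorted(species):
        proteome, order = species[name]
        hits = best_hits(queries, proteome, min_score)
        if reciprocal:
            back = best_hits(proteome, queries, min_score)
            hits = {q: s for q, s in hits.items() if back.get(s) == q}
        pos = {e.gene_id: e for e in order}
        col = []
        for a, b in orf_pairs:
            ha, hb = hits.get(a), hits.get(b)
            ok = False
            if ha and hb and ha in pos and hb in pos:
                ea, eb = pos[ha], pos[hb]
                ok = (
                    ea.contig == eb.contig
                    and abs(ea.rank - eb.rank) == 1
                    and ea.strand == eb.strand
                )
            col.append(ok)
        matrix[name] = col
    index = [f"{a}--{b}" for a, b in orf_pairs]
    df = pd.DataFrame(matrix, index=index)
    return df, df.sum(axis=0)
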