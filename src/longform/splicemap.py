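"""Spliced alignment of transcripts to a genome and exon-chain extraction.

A desk-scale seed-and-chain spliced aligner: unique k-mer anchors are
collapsed into diagonal segments, chained co-linearly, small gaps are
closed by global alignment, larger genomic gaps become introns whose
boundaries are refined to prefer GT..AG donors/acceptors. The output is
an :class:`ExonChain` plus alignment coverage and identity, feeding the
coverage/identity acceptance filter and locus assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import stats_from_cigar
from .chains import ExonChain, revcomp


@dataclass(frozen=True)
class SpliceMapParams:
    k: int = 15
    intron_min: int = 40  # smaller genomic gaps are closed as indels
    min_chain_bases: int = 50  # anchors required to accept a mapping
    gtag_bonus: int = 4  # refinement bonus for canonical splice sites
    end_slack: int = 12  # extra genomic bases allowed at end extension


@dataclass
class SplicedAlignment:
    query_id: str
    chain: ExonChain
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.coverage <= 1 and 0 <= self.identity <= 1):
            raise ValueError("coverage/identity out of range")


class GenomeIndex:
    """Unique-k-mer index over the forward strand of a genome."""

    def __init__(self, genome: dict[str, str], k: int = 15):
        self.genome = genome
        self.k = k
        index: dict[str, tuple[str, int] | None] = {}
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                index[km] = None if km in index else (chrom, i)
        self.index = {km: loc for km, loc in index.items() if loc is not None}


def _segments(seq: str, gidx: GenomeIndex) -> dict[str, list[list[int]]]:
    """Anchor unique k-mers and merge same-diagonal contiguous runs into
    segments [qstart, qend, gstart, gend] per chromosome."""
    k = gidx.k
    by_chrom: dict[str, list[list[int]]] = {}
    last: dict[str, list[int]] = {}
    for q in range(len(seq) - k + 1):
        loc = gidx.index.get(seq[q : q + k])
        if loc is None:
            continue
        chrom, g = loc
        seg = last.get(chrom)
        # extend only on overlapping continuation of the same diagonal, so
        # every merged base is covered by an exact-matching k-mer
        if seg is not None and g - seg[3] == q - seg[1] and q < seg[1]:
            seg[1] = q + k
            seg[3] = g + k
        else:
            seg = [q, q + k, g, g + k]
            by_chrom.setdefault(chrom, []).append(seg)
            last[chrom] = seg
    return by_chrom


def _best_chain(segments: list[list[int]], k: int) -> list[list[int]]:
    """Maximum-weight co-linear chain (weight = anchored bases).

    Segments may overlap by up to one k-mer (anchors can coincidentally
    run a few bases past an exon junction); the overlap is charged
    against the weight and trimmed from the later segment afterwards."""
    segs = sorted(segments, key=lambda s: (s[0], s[2]))
    n = len(segs)
    score = [0.0] * n
    prev = [-1] * n
    for i, s in enumerate(segs):
        w = s[1] - s[0]
        score[i] = w
        for j in range(i):
            p = segs[j]
            ov = max(p[1] - s[0], p[3] - s[2], 0)
            if (
                s[0] > p[0]
                and s[2] > p[2]
                and ov < k
                and 0 <= s[2] - p[3] + ov < 500_000
            ):
                cand = score[j] + w - ov
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = max(range(n), key=lambda i: (score[i], -segs[i][0]))
    chain = []
    i = best
    while i != -1:
        chain.append([*segs[i]])
        i = prev[i]
    chain = chain[::-1]
    out = [chain[0]]
    for seg in chain[1:]:
        p = out[-1]
        trim = max(p[1] - seg[0], p[3] - seg[2], 0)
        seg[0] += trim
        seg[2] += trim
        if seg[0] < seg[1]:
            out.append(seg)
    return out


def _refine_intron(
    seq: str, g: str, qe1: int, qs2: int, ge1: int, gs2: int,
    sense_plus: bool, params: SpliceMapParams,
) -> tuple[int, int, int, int]:
    """Place an intron inside the gap between two chained segments.

    Returns (left_exonic, right_exonic, matches, columns): the split of
    the transcript gap into left/right exonic pieces maximising exact
    matches with a bonus for canonical donor/acceptor dinucleotides
    (GT..AG in transcription direction; CT..AC on the forward genome for
    minus-strand transcripts)."""
    qgap = qs2 - qe1
    don, acc = ("GT", "AG") if sense_plus else ("CT", "AC")
    qpiece = seq[qe1:qs2]
    # donor/acceptor offsets are searched independently (indels in the
    # query make the two exonic flank lengths sum to != qgap); the query
    # gap is aligned against the concatenated genomic flanks
    slack = 3 + qgap // 10
    best = None
    for left in range(qgap + slack + 1):
        if ge1 + left > gs2:
            break
        lo = max(0, qgap - left - slack)
        hi = min(qgap + slack - left, gs2 - ge1 - left)
        for right in range(lo, hi + 1):
            flanks = g[ge1 : ge1 + left] + g[gs2 - right : gs2]
            d = (
                edlib.align(qpiece, flanks, mode="NW")["editDistance"]
                if qpiece or flanks
                else 0
            )
            istart, iend = ge1 + left, gs2 - right
            canon = g[istart : istart + 2] == don and g[iend - 2 : iend] == acc
            key = (
                -d + (params.gtag_bonus if canon else 0),
                -abs(left + right - qgap),
                -left,
            )
            if best is None or key > best[0]:
                best = (key, left, right, d)
    _, left, right, edits = best
    return left, right, max(qgap - edits, 0), qgap


def _extend_end(
    tail: str, flank: str, at_start: bool
) -> tuple[int, int, int]:
    """Align a query tail against an adjacent genomic flank anchored at
    the segment boundary; returns (genomic bases consumed, matches,
    columns)."""
    if not tail:
        return 0, 0, 0
    if not flank:
        return 0, 0, len(tail)
    if at_start:  # 5' tail: anchor at flank end
        q, t = tail[::-1], flank[::-1]
    else:
        q, t = tail, flank
    res = edlib.align(q, t, mode="SHW", task="path")
    st = stats_from_cigar(res["cigar"], clip_terminal_gaps=False)
    end = res["locations"][0][1]
    consumed = (end + 1) if end is not None else len(tail)
    return consumed, st.matches, st.columns


def spliced_align(
    transcript: str,
    gidx: GenomeIndex,
    params: SpliceMapParams = SpliceMapParams(),
    query_id: str = "query",
) -> SplicedAlignment | None:
    """Map one transcript; tries both orientations and keeps the better
    chain. Returns None when no sufficient anchor chain exists."""
    best = None
    for strand, seq in (("+", transcript), ("-", revcomp(transcript))):
        by_chrom = _segments(seq, gidx)
        for chrom, segs in sorted(by_chrom.items()):
            chain = _best_chain(segs, gidx.k)
            bases = sum(s[1] - s[0] for s in chain)
            if bases < params.min_chain_bases:
                continue
            if best is None or bases > best[0]:
                best = (bases, strand, seq, chrom, chain)
    if best is None:
        return None
    _, strand, seq, chrom, chain = best
    g = gidx.genome[chrom]
    sense_plus = strand == "+"

    # classify the inter-segment gaps, then back segment ends off around
    # introns: an anchor may coincidentally extend past the true junction,
    # so the refinement scan must be allowed to move it back
    is_intron = []
    for prev_seg, seg in zip(chain, chain[1:]):
        qgap = seg[0] - prev_seg[1]
        ggap = seg[2] - prev_seg[3]
        is_intron.append(ggap - qgap >= params.intron_min)
    backoff = 6
    for i, intron in enumerate(is_intron):
        if not intron:
            continue
        left, right = chain[i], chain[i + 1]
        b1 = min(backoff, (left[1] - left[0]) // 2)
        left[1] -= b1
        left[3] -= b1
        b2 = min(backoff, (right[1] - right[0]) // 2)
        right[0] += b2
        right[2] += b2

    matches = columns = aligned_q = 0
    for s in chain:
        matches += s[1] - s[0]
        columns += s[1] - s[0]
        aligned_q += s[1] - s[0]
    exons: list[list[int]] = [[chain[0][2], chain[0][3]]]
    for (prev_seg, seg), intron in zip(zip(chain, chain[1:]), is_intron):
        qe1, ge1 = prev_seg[1], prev_seg[3]
        qs2, gs2 = seg[0], seg[2]
        qgap = qs2 - qe1
        if intron:
            left, right, m, cols = _refine_intron(
                seq, g, qe1, qs2, ge1, gs2, sense_plus, params
            )
            exons[-1][1] = ge1 + left
            exons.append([gs2 - right, seg[3]])
            matches += m
            columns += cols
            aligned_q += qgap
        else:
            ggap = gs2 - ge1
            if qgap and ggap:
                res = edlib.align(seq[qe1:qs2], g[ge1:gs2], mode="NW", task="path")
                st = stats_from_cigar(res["cigar"], clip_terminal_gaps=False)
                matches += st.matches
                columns += st.columns
            else:
                columns += max(qgap, ggap)  # pure indel gap
            exons[-1][1] = seg[3]
            aligned_q += qgap

    # extend alignment to the query ends
    q0, g0 = chain[0][0], chain[0][2]
    tail5 = seq[:q0]
    flank = g[max(0, g0 - q0 - params.end_slack) : g0]
    consumed, m, cols = _extend_end(tail5, flank, at_start=True)
    exons[0][0] = g0 - consumed
    matches += m
    columns += cols
    aligned_q += len(tail5)

    qn, gn = chain[-1][1], chain[-1][3]
    tail3 = seq[qn:]
    flank = g[gn : gn + len(tail3) + params.end_slack]
    consumed, m, cols = _extend_end(tail3, flank, at_start=False)
    exons[-1][1] = gn + consumed
    matches += m
    columns += cols
    aligned_q += len(tail3)

    merged: list[tuple[int, int]] = []
    for s, e in exons:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        elif e > s:
            merged.append((s, e))
    chain_out = ExonChain(chrom, strand, tuple(merged))
    coverage = min(aligned_q / len(transcript), 1.0)
    identity = min(matches / columns, 1.0) if columns else 0.0
    return SplicedAlignment(query_id, chain_out, coverage, identity)


def map_transcripts(
    transcripts: dict[str, str],
    genome: dict[str, str],
    params: SpliceMapParams = SpliceMapParams(),
) -> list[SplicedAlignment]:
    gidx = GenomeIndex(genome, params.k)
    out = []
    for name in sorted(transcripts):
        aln = spliced_align(transcripts[name], gidx, params, query_id=name)
        if aln is not None:
            out.append(aln)
    return out


def filter_alignments(
    alignments: list[SplicedAlignment],
    min_cov: float = 0.99,
    min_ident: float = 0.85,
) -> list[SplicedAlignment]:
    """The acceptance filter: keep alignments with coverage >= min_cov
    AND identity >= min_ident (boundary values accepted)."""
    return [a for a in alignments if a.coverage >= min_cov and a.identity >= min_ident]


def assign_loci(alignments: list[SplicedAlignment]) -> dict[str, str]:
    """Group transcripts into loci: same strand + >=1 bp exonic overlap,
    closed transitively; locus ids ordered by leftmost coordinate."""
    parent = {a.query_id: a.query_id for a in alignments}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    events: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for a in alignments:
        for s, e in a.chain.exons:
            events.setdefault((a.chain.chrom, a.chain.strand), []).append(
                (s, e, a.query_id)
            )
    for key in events:
        ivs = sorted(events[key])
        active: list[tuple[int, str]] = []  # (end, id)
        for s, e, qid in ivs:
            active = [(en, qi) for en, qi in active if en > s]
            for _, qi in active:
                union(qid, qi)
            active.append((e, qid))

    groups: dict[str, list[str]] = {}
    for a in alignments:
        groups.setdefault(find(a.query_id), []).append(a.query_id)
    start_of = {a.query_id: (a.chain.chrom, a.chain.start) for a in alignments}
    ordered = sorted(groups.values(), key=lambda g: start_of[min(g)])
    out: dict[str, str] = {}
    for i, members in enumerate(
        sorted(ordered, key=lambda ms: min(start_of[m] for m in ms))
    ):
        for m in members:
            out[m] = f"locus{i + 1:04d}"
    return out
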