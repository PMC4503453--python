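"""Full-length cDNA read identification, orientation and trimming.

A read-of-insert is called *full-length* when the 5' cDNA primer is
found at its 5' end, the 3' primer at its 3' end, and a polyA tract
immediately precedes the 3' primer. Reads with an additional primer
occurrence in their interior are flagged as chimeric artifacts; all
other reads are non-full-length (usable for polishing only).

Classification is orientation-invariant: both strands are tried and the
reported ``trimmed_seq`` is always transcript-sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import best_infix_hit
from .chains import revcomp

FULL_LENGTH = "full_length"
NON_FULL_LENGTH = "non_full_length"
ARTIFACT_CHIMERA = "artifact_chimera"


@dataclass(frozen=True)
class RawRead:
    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty read sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality length mismatch")


@dataclass(frozen=True)
class ClassifyParams:
    end_window: int = 100
    max_edit_fraction: float = 0.3
    # stricter threshold for the whole-read chimera scan: at 0.3 a scan
    # across ~kb of sequence false-fires on random DNA
    internal_edit_fraction: float = 0.2
    polyA_window: int = 100
    polyA_min_len: int = 15
    polyA_min_A_fraction: float = 0.8


@dataclass
class FLRead:
    id: str
    strand: str  # orientation of the transcript relative to the input read
    trimmed_seq: str
    trimmed_qual: tuple[int, ...] | None
    classification: str
    primer5_hit: tuple[int, int, int] | None  # (start, end, edits)
    primer3_hit: tuple[int, int, int] | None
    polyA_len: int
    reason: str = ""


def find_primer(
    seq: str,
    primer: str,
    end_window: int = 100,
    max_edit_fraction: float = 0.3,
    end: str = "5p",
) -> tuple[int, int, int] | None:
    """Best semi-global primer occurrence whose start (5' search) or end
    (3' search) lies within ``end_window`` of the respective read end.
    Returns (start, end, edit distance) in read coordinates, or None.
    """
    if len(primer) < 10:
        raise ValueError("primer must be >= 10 nt")
    window = min(end_window, len(seq))
    span = min(len(seq), window + len(primer))
    if end == "5p":
        hit = best_infix_hit(primer, seq[:span], max_edit_fraction)
        if hit is None or hit[0] >= window:
            return None
        return hit
    hit = best_infix_hit(primer, seq[len(seq) - span :], max_edit_fraction)
    if hit is None:
        return None
    off = len(seq) - span
    s, e, d = hit[0] + off, hit[1] + off, hit[2]
    if e <= len(seq) - window:
        return None
    return (s, e, d)


def detect_polyA(
    seq: str,
    search_window: int = 100,
    min_len: int = 15,
    min_A_fraction: float = 0.8,
) -> tuple[tuple[int, int], int] | None:
    """Longest trailing polyA tract of ``seq``.

    Scans 3'->5' keeping the running A-fraction of the scanned suffix at
    or above ``min_A_fraction`` (short suffixes below ``min_len`` get a
    grace period so a single terminal miscall cannot abort the scan).
    The reported interval is trimmed to its outermost A bases.
    """
    n = len(seq)
    window = min(search_window, n)
    best = 0
    a_count = 0
    for ell in range(1, window + 1):
        if seq[n - ell] == "A":
            a_count += 1
        frac = a_count / ell
        if frac >= min_A_fraction:
            best = ell
        elif ell >= min_len:
            break
    if best == 0:
        return None
    s, e = n - best, n
    while s < e and seq[s] != "A":
        s += 1
    while e > s and seq[e - 1] != "A":
        e -= 1
    if e - s < min_len:
        return None
    return (s, e), e - s


def _chimera_scan(seq: str, primers: list[str], params: ClassifyParams) -> bool:
    """True if any primer (either orientation) occurs in the read
    interior, outside both end windows."""
    margin = params.end_window + 5
    interior = seq[margin : len(seq) - margin]
    if len(interior) < 20:
        return False
    for p in primers:
        for pat in (p, revcomp(p)):
            if best_infix_hit(pat, interior, params.internal_edit_fraction):
                return True
    return False


def _try_orientation(
    seq: str, primer5: str, primer3: str, params: ClassifyParams
):
    """Evaluate one orientation; returns a dict of findings."""
    p5 = find_primer(seq, primer5, params.end_window, params.max_edit_fraction, "5p")
    p3 = find_primer(
        seq, revcomp(primer3), params.end_window, params.max_edit_fraction, "3p"
    )
    pa = None
    pa_len = 0
    body_end = p3[0] if p3 else len(seq)
    res = detect_polyA(
        seq[:body_end],
        params.polyA_window,
        params.polyA_min_len,
        params.polyA_min_A_fraction,
    )
    if res:
        pa, pa_len = res
    return {"p5": p5, "p3": p3, "polyA": pa, "polyA_len": pa_len}


def classify_read(
    read: RawRead,
    primer5: str,
    primer3: str,
    params: ClassifyParams = ClassifyParams(),
) -> FLRead:
    """Classify one read; see module docstring for the decision rule.

    Orientation ties are broken by lower summed primer edit distance,
    then by the + strand.
    """
    if not primer5 or not primer3:
        raise ValueError("primers must be non-empty")
    min_fl = len(primer5) + len(primer3) + params.polyA_min_len
    if len(read.seq) < min_fl:
        return FLRead(
            read.id, "+", read.seq, read.qual, NON_FULL_LENGTH,
            None, None, 0, reason="read_too_short",
        )

    candidates = []
    for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
        r = _try_orientation(seq, primer5, primer3, params)
        is_fl = r["p5"] is not None and r["p3"] is not None and r["polyA"] is not None
        edits = (r["p5"][2] if r["p5"] else len(primer5)) + (
            r["p3"][2] if r["p3"] else len(primer3)
        )
        score = (
            0 if is_fl else 1,
            edits,
            0 if r["polyA"] else 1,
            0 if strand == "+" else 1,
        )
        candidates.append((score, strand, seq, r))
    candidates.sort(key=lambda c: c[0])
    _, strand, seq, r = candidates[0]

    if _chimera_scan(read.seq, [primer5, primer3], params):
        return FLRead(
            read.id, strand, "", None, ARTIFACT_CHIMERA,
            r["p5"], r["p3"], r["polyA_len"], reason="internal_primer",
        )

    start = r["p5"][1] if r["p5"] else 0
    end = r["polyA"][0] if r["polyA"] else (r["p3"][0] if r["p3"] else len(seq))
    trimmed = seq[start:end]
    qual = read.qual
    if qual is not None:
        q = qual if strand == "+" else qual[::-1]
        qual = tuple(q[start:end])

    if r["p5"] and r["p3"] and r["polyA"]:
        cls, reason = FULL_LENGTH, ""
    else:
        missing = []
        if not r["p5"]:
            missing.append("primer5")
        if not r["p3"]:
            missing.append("primer3")
        if not r["polyA"]:
            missing.append("polyA")
        cls, reason = NON_FULL_LENGTH, "missing_" + "+".join(missing)
    return FLRead(
        read.id, strand, trimmed, qual, cls,
        r["p5"], r["p3"], r["polyA_len"],
        reason=reason,
    )


def classify_reads(
    reads,
    primer5: str,
    primer3: str,
    params: ClassifyParams = ClassifyParams(),
) -> list[FLRead]:
    return [classify_read(r, primer5, primer3, params) for r in reads]
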