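"""Thin edlib-based alignment utilities shared across pipeline stages.

edlib extended CIGARs use '=' (match), 'X' (mismatch), 'I' (query
insertion, consumes query only) and 'D' (deletion, consumes target
only). ``HW`` mode is infix alignment (free gaps at both target ends),
``NW`` is global.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


@dataclass
class AlnStats:
    matches: int = 0
    mismatches: int = 0
    q_gap: int = 0  # bases of target skipped (D runs)
    t_gap: int = 0  # bases of query inserted (I runs)
    columns: int = 0
    max_internal_gap: int = 0

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _gap_excess(ops: list[tuple[int, str]], gap_sym: str, decay: float = 0.1) -> float:
    """Largest local run of net ``gap_sym`` bases (Kadane over runs):
    opposite gaps cancel and matched columns decay the score, so an
    unbroken block indel scores ~its length while scattered sequencing
    indels stay near zero. Unit-cost tracebacks (edlib) may fragment a
    real block gap with short coincidental match runs; this measure is
    robust to that."""
    other = "D" if gap_sym == "I" else "I"
    best = cur = 0.0
    for n, op in ops:
        if op == gap_sym:
            cur += n
        elif op == other:
            cur -= n
        else:
            cur -= decay * n
        cur = max(cur, 0.0)
        best = max(best, cur)
    return best


def stats_from_cigar(cigar: str, clip_terminal_gaps: bool = True) -> AlnStats:
    """Summarise an extended CIGAR; terminal indel runs may be clipped
    so that end-free overhangs do not count as internal gaps."""
    ops = cigar_ops(cigar)
    if clip_terminal_gaps:
        while ops and ops[0][1] in "ID":
            ops.pop(0)
        while ops and ops[-1][1] in "ID":
            ops.pop()
    st = AlnStats()
    for n, op in ops:
        st.columns += n
        if op == "=":
            st.matches += n
        elif op == "X":
            st.mismatches += n
        elif op == "D":
            st.q_gap += n
        elif op == "I":
            st.t_gap += n
    st.max_internal_gap = int(
        max(_gap_excess(ops, "D"), _gap_excess(ops, "I"))
    )
    return st


def infix_align(query: str, target: str, max_dist: int = -1) -> dict:
    return edlib.align(query, target, mode="HW", task="path", k=max_dist)


def best_infix_hit(
    pattern: str, text: str, max_edit_fraction: float
) -> tuple[int, int, int] | None:
    """Best semi-global occurrence of ``pattern`` in ``text``.

    Returns (start, end, edit_distance) with end exclusive, or None if
    the minimum edit distance exceeds max_edit_fraction * len(pattern).
    Among equal-distance hits edlib reports the leftmost end; the start
    is taken from the first reported location (deterministic).
    """
    if not text or not pattern:
        return None
    limit = int(math.floor(max_edit_fraction * len(pattern)))
    res = edlib.align(pattern, text, mode="HW", task="locations", k=limit)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return (s if s is not None else 0, e + 1, res["editDistance"])


def log_likelihood(
    query: str, target: str, sub: float, ins: float, dele: float
) -> float:
    """Alignment log-likelihood of observing ``query`` given ``target``
    under an i.i.d. per-base error model (infix alignment, free target
    ends)."""
    sub = max(sub, 1e-6)
    ins = max(ins, 1e-6)
    dele = max(dele, 1e-6)
    p_match = max(1.0 - sub - ins - dele, 1e-6)
    res = infix_align(query, target)
    st = stats_from_cigar(res["cigar"])
    return (
        st.matches * math.log(p_match)
        + st.mismatches * math.log(sub / 3.0)
        + st.t_gap * math.log(ins / 4.0)
        + st.q_gap * math.log(dele)
    )
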