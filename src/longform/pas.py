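"""Poly(A)-site location, classification and upstream composition profiles.

Transcription-termination signals in fungi (as in plants and animals)
comprise an A-rich near upstream element (NUE, roughly -30..-10 from
the cleavage site) and a U-rich far upstream element (FUE, roughly
-60..-30). Sites are classified into three groups: nORF (termini of
monocistronic transcripts), pORF2 (termini of polycistronic
transcripts) and pORF1 (the internal site of a polycistronic unit,
located via independent monocistronic transcripts of its upstream ORF).
Comparing per-position A/U frequencies across classes tests whether
readthrough correlates with weak termination signals at the internal
site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chains import revcomp
from .orfscan import PolycistronicCall
from .sim import Gene
from .splicemap import SplicedAlignment

BASES = "ACGU"


@dataclass(frozen=True)
class PASite:
    chrom: str
    pos: int  # cleavage site: transcript 3'-end genomic coordinate
    strand: str
    site_class: str  # nORF | pORF1 | pORF2
    transcript_id: str


@dataclass
class PASProfile:
    site_class: str
    window: int  # positions -window..-1 upstream of the cleavage site
    freq: np.ndarray  # (window, 4) frequencies over A,C,G,U
    n_sites: int
    n_skipped: int
    seed: int

    def mean_freq(self, base: str, lo: int, hi: int) -> float:
        """Mean frequency of ``base`` over positions lo..hi (negative,
        inclusive), e.g. mean_freq('A', -30, -10)."""
        col = BASES.index(base)
        return float(self.freq[self.window + lo : self.window + hi + 1, col].mean())


def locate_pas(
    alignments: dict[str, SplicedAlignment],
    ptu_calls: list[PolycistronicCall],
    genes: list[Gene],
) -> list[PASite]:
    """Classify the terminal cleavage site of every aligned transcript.

    Polycistronic termini are pORF2. A monocistronic transcript whose
    gene is a non-final member of some PTU provides that PTU's internal
    pORF1 site; all other monocistronic termini are nORF.
    """
    ptu_tx = {c.transcript_id for c in ptu_calls}
    upstream_genes: set[str] = set()
    gene_by_id = {g.id: g for g in genes}
    for call in ptu_calls:
        members = call.contained_genes or call.overlapped_genes
        if not members:
            continue
        minus = gene_by_id[members[0]].chain.strand == "-"
        ordered = sorted(
            members, key=lambda gid: gene_by_id[gid].chain.start, reverse=minus
        )
        upstream_genes.update(ordered[:-1])
    sites: list[PASite] = []
    for tid in sorted(alignments):
        ch = alignments[tid].chain
        pos = ch.three_prime_pos()
        if tid in ptu_tx:
            cls = "pORF2"
        else:
            hits = [
                g.id
                for g in genes
                if g.chain.chrom == ch.chrom
                and g.chain.strand == ch.strand
                and g.chain.start < ch.end
                and ch.start < g.chain.end
            ]
            cls = "pORF1" if any(h in upstream_genes for h in hits) else "nORF"
        sites.append(PASite(ch.chrom, pos, ch.strand, cls, tid))
    return sites


def composition_profile(
    sites: list[PASite],
    genome: dict[str, str],
    site_class: str,
    window: int = 100,
    n_sample: int = 200,
    seed: int = 0,
) -> PASProfile:
    """Per-position base frequencies over -window..-1 upstream of
    ``n_sample`` randomly chosen (without replacement) sites of one
    class, on the transcript strand; DNA T is reported as U. Sites whose
    window would run off the contig are skipped and counted.

    A cleavage site is a genomic feature: transcripts of one locus that
    end at the same position contribute a single site, so no upstream
    window is double-counted."""
    unique: dict[tuple[str, int, str], PASite] = {}
    for s in sorted(
        (s for s in sites if s.site_class == site_class),
        key=lambda s: (s.chrom, s.pos, s.transcript_id),
    ):
        unique.setdefault((s.chrom, s.pos, s.strand), s)
    pool = list(unique.values())
    if not pool:
        raise ValueError(f"no sites of class {site_class}")
    rng = np.random.default_rng(seed)
    take = min(n_sample, len(pool))
    chosen = [pool[i] for i in sorted(rng.choice(len(pool), take, replace=False))]
    counts = np.zeros((window, 4))
    used = 0
    skipped = 0
    for s in chosen:
        contig = genome[s.chrom]
        if s.strand == "+":
            if s.pos - window < 0:
                skipped += 1
                continue
            seq = contig[s.pos - window : s.pos]
        else:
            if s.pos + window > len(contig):
                skipped += 1
                continue
            seq = revcomp(contig[s.pos : s.pos + window])
        for i, base in enumerate(seq):
            j = "ACGT".find(base)
            if j >= 0:
                counts[i, j] += 1
        used += 1
    if used == 0:
        raise ValueError("every sampled site fell off a contig edge")
    return PASProfile(site_class, window, counts / used, used, skipped, seed)


def detect_elements(
    profile: PASProfile,
    nue_range: tuple[int, int] = (-35, -5),
    fue_range: tuple[int, int] = (-70, -25),
    span: int = 6,
    margin: float = 0.15,
    baseline: float = 0.25,
) -> dict[str, dict | None]:
    """Detect NUE/FUE: the max ``span``-nt sliding-window mean A (NUE)
    or U (FUE) frequency within the search range must exceed baseline +
    margin. Reports the window position (5' edge, negative coordinates)
    and the excess over baseline, or None when absent."""

    def scan(base: str, lo: int, hi: int) -> dict | None:
        col = BASES.index(base)
        w = profile.window
        best_pos, best_mean = None, -1.0
        for start in range(max(lo, -w), hi - span + 2):
            i = w + start
            window_mean = float(profile.freq[i : i + span, col].mean())
            if window_mean > best_mean:
                best_mean, best_pos = window_mean, start
        if best_mean >= baseline + margin:
            return {"position": best_pos, "mean": best_mean,
                    "excess": best_mean - baseline}
        return None

    return {
        "nue": scan("A", *nue_range),
        "fue": scan("U", *fue_range),
    }
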