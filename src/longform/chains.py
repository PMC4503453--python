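"""Exon chains: the strand-aware unit of transcript identity.

An :class:`ExonChain` is an ordered list of genomic exon intervals
(0-based, half-open, ascending) on one strand of one chromosome. The
junction chain -- the ordered list of intron (start, end) coordinate
pairs -- is the identity key used for isoform comparison and collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ExonChain:
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # ascending genomic order

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
            if s < prev_end:
                raise ValueError("exons overlap or are not ascending")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron intervals (donor..acceptor, half-open genomic)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def three_prime_pos(self) -> int:
        """Genomic coordinate of the transcript 3' end (cleavage side)."""
        return self.end if self.strand == "+" else self.start

    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    def transcript_seq(self, genome: dict[str, str]) -> str:
        """Spliced transcript-sense sequence from a {chrom: seq} genome."""
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def genomic_positions(self) -> list[int]:
        """Genomic coordinate of every transcript base, 5'->3' order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def junction_dinucleotides(self, genome: dict[str, str]) -> list[tuple[str, str]]:
        """(donor, acceptor) dinucleotides in transcription direction."""
        out = []
        g = genome[self.chrom]
        juncs = self.junctions if self.strand == "+" else self.junctions[::-1]
        for a, b in juncs:
            if self.strand == "+":
                out.append((g[a : a + 2], g[b - 2 : b]))
            else:
                out.append((revcomp(g[b - 2 : b]), revcomp(g[a : a + 2])))
        return out


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
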