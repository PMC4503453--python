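"""I/O for the standard formats the pipeline consumes and emits.

Internal coordinates are 0-based half-open everywhere. GFF3 is written
1-based inclusive, BED12 0-based half-open, per each format's dialect.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chains import ExonChain


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(recs, path, "fasta-2line")


def read_fastq(path: str) -> Iterator[tuple[str, str, list[int]]]:
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(path: str, records: Iterable[tuple[str, str, list[int]]]) -> None:
    def gen():
        for name, seq, quals in records:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            yield rec

    SeqIO.write(gen(), path, "fastq")


# --------------------------------------------------------------------- BED12

def write_bed12(path: str, chains: Iterable[tuple[str, ExonChain]]) -> None:
    with open(path, "w") as fh:
        for name, ch in chains:
            sizes = ",".join(str(e - s) for s, e in ch.exons) + ","
            starts = ",".join(str(s - ch.start) for s, e in ch.exons) + ","
            fh.write(
                "\t".join(
                    (
                        ch.chrom,
                        str(ch.start),
                        str(ch.end),
                        name,
                        "0",
                        ch.strand,
                        str(ch.start),
                        str(ch.end),
                        "0,0,0",
                        str(ch.n_exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


def read_bed12(path: str) -> list[tuple[str, ExonChain]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(starts, sizes)
            )
            out.append((name, ExonChain(chrom, strand, exons)))
    return out


# ---------------------------------------------------------------------- GFF3

def write_gff3(path: str, genes) -> None:
    """Write gene/mRNA/exon/CDS features for simulator Gene records."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.dup_of:
                attrs += f";dup_of={g.dup_of}"
            if g.ptu_id:
                attrs += f";ptu={g.ptu_id};ptu_index={g.ptu_index}"
            fh.write(
                f"{g.chain.chrom}\tlongform-sim\tgene\t{g.chain.start + 1}\t"
                f"{g.chain.end}\t.\t{g.chain.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chain.chrom}\tlongform-sim\tmRNA\t{g.chain.start + 1}\t"
                f"{g.chain.end}\t.\t{g.chain.strand}\t.\tID={g.id}.t1;Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.chain.exons, 1):
                fh.write(
                    f"{g.chain.chrom}\tlongform-sim\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.chain.strand}\t.\tID={g.id}.e{i};Parent={g.id}.t1\n"
                )
            for s, e in g.cds_genomic:
                fh.write(
                    f"{g.chain.chrom}\tlongform-sim\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{g.chain.strand}\t0\tID={g.id}.cds;Parent={g.id}.t1\n"
                )


def read_gff3_genes(path: str):
    """Read gene annotation back into lightweight records via gffutils."""
    import gffutils

    from .sim import Gene  # local import to avoid a cycle

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        cds = []
        for mrna in db.children(g, featuretype="mRNA"):
            exons = [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            cds = [(c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")]
        exons.sort()
        cds.sort()
        genes.append(
            Gene(
                id=g.id,
                chain=ExonChain(g.seqid, g.strand, tuple(exons)),
                cds_genomic=tuple(cds),
                dup_of=g.attributes.get("dup_of", [None])[0],
                ptu_id=g.attributes.get("ptu", [None])[0],
                ptu_index=int(g.attributes["ptu_index"][0])
                if "ptu_index" in g.attributes
                else None,
            )
        )
    return genes


# ---------------------------------------------------------------------- JSON

def write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
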