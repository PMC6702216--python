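"""Readers and writers for the standard formats at the pipeline boundary.

GFF3 carries gene and pseudogene annotation (1-based inclusive on disk,
converted to the internal 0-based half-open convention), BED6 carries
transcript fragments and regions, FASTA the genome sequence, and TSV the
FPKM matrices, similarity tables, and feature tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import MatchRecord
from .regions import AnnotationSet, Gene, GenomicInterval

__all__ = [
    "write_gff3",
    "read_gff3",
    "write_bed",
    "read_bed",
    "write_fasta",
    "read_fasta",
    "read_blast_table",
    "write_tsv",
]


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in annotation.genes:
            span = gene.span
            fh.write(
                f"{gene.chrom}\titrpred\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, exon in enumerate(gene.exons, 1):
                fh.write(
                    f"{gene.chrom}\titrpred\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )
        for i, p in enumerate(annotation.pseudogenes, 1):
            fh.write(
                f"{p.chrom}\titrpred\tpseudogene\t{p.start + 1}\t{p.end}\t.\t.\t.\t"
                f"ID=pseudogene_{i}\n"
            )


def read_gff3(
    path: str | Path,
    pseudogene_feature: str = "pseudogene",
    unmappable: Sequence[GenomicInterval] = (),
) -> AnnotationSet:
    """Read genes (via exon features grouped by Parent) and pseudogenes from
    GFF3.  Chromosome lengths come from ##sequence-region directives."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            _, chrom, _start, end = directive.split()[:4]
            chrom_lengths[chrom] = int(end)
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID", [""])
        strand = feat.strand if feat.strand in "+-" else "."
        exons_by_gene.setdefault(parents[0], []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        )
    pseudogenes = [
        GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        for feat in db.features_of_type(pseudogene_feature)
    ]
    genes = [
        Gene(gene_id, tuple(sorted(exons, key=lambda e: e.start)))
        for gene_id, exons in exons_by_gene.items()
    ]
    if not chrom_lengths:
        # fall back to the furthest annotated coordinate per chromosome
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.span.end)
        for p in pseudogenes:
            chrom_lengths[p.chrom] = max(chrom_lengths.get(p.chrom, 0), p.end)
    return AnnotationSet(chrom_lengths, genes, pseudogenes, unmappable)


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> tuple[list[GenomicInterval], list[str]]:
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"region_{i + 1}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
            names.append(name)
    return intervals, names


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


#: BLAST tabular (outfmt 6) column names, with an optional trailing K column.
BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_table(path: str | Path) -> list[MatchRecord]:
    """Read a 12-column BLAST tabular file (optional 13th column: per-base
    substitution rate K).  Subject coordinates are 1-based inclusive and may
    be reversed on the minus strand; both are normalized."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] not in (12, 13):
        raise ValueError("expected 12 or 13 tab-separated columns")
    frame.columns = BLAST6_COLUMNS + (["k"] if frame.shape[1] == 13 else [])
    records = []
    for row in frame.itertuples(index=False):
        lo, hi = sorted((int(row.sstart), int(row.send)))
        records.append(
            MatchRecord(
                query=str(row.qseqid),
                subject_chrom=str(row.sseqid),
                subject_start=lo - 1,
                subject_end=hi,
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
                k=float(row.k) if frame.shape[1] == 13 else None,
            )
        )
    return records


def write_tsv(frame: pd.DataFrame, path: str | Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", **kwargs)
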