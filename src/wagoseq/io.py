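"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through Biopython, GFF3 through gffutils; BED3/BED6 and the
TSV tables are plain columnar text written so that read->write round-trips
are byte exact.
"""

from __future__ import annotations

import os
from collections import Counter, OrderedDict

import gffutils
from Bio import SeqIO

from .core import AnnotationBundle, GeneModel, GenomeIndex, Interval, Library, ReadRecord

VALID_READ_CHARS = frozenset("ACGT")


def read_fasta_genome(path: str | os.PathLike, mito_contigs=()) -> GenomeIndex:
    """Load a genome FASTA into memory, upper-casing sequences.

    Raises on empty files and duplicate contig names.
    """
    seqs: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate contig {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeIndex(seqs, mito_contigs=mito_contigs)


def read_gff3_genes(path: str | os.PathLike, genome: GenomeIndex) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from GFF3 into GeneModels.

    GFF3 is 1-based inclusive; exons are converted to 0-based half-open.
    One GeneModel per mRNA; mRNAs without exons are skipped (counted via
    the returned models' complement, a warning is printed).
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    skipped = 0
    for mrna in db.features_of_type("mRNA"):
        exons = []
        for ex in db.children(mrna, featuretype="exon", order_by="start"):
            if ex.seqid not in genome.lengths:
                raise ValueError(f"exon of {mrna.id} on unknown contig {ex.seqid}")
            if ex.end > genome.lengths[ex.seqid]:
                raise ValueError(
                    f"exon of {mrna.id} ends at {ex.end} beyond contig "
                    f"{ex.seqid} length {genome.lengths[ex.seqid]}"
                )
            exons.append(Interval(ex.seqid, ex.start - 1, ex.end, mrna.strand))
        if not exons:
            skipped += 1
            continue
        models.append(GeneModel(gene_id=mrna.id, strand=mrna.strand, exons=exons))
    if skipped:
        print(f"read_gff3_genes: skipped {skipped} mRNA(s) without exons")
    return models


def read_bed(path: str | os.PathLike, class_label: str = "") -> list[Interval]:
    """Read BED3/BED6 intervals; strand '.' when the column is absent."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(f[1]), int(f[2])
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid BED coordinates {start}..{end}"
                )
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(Interval(f[0], start, end, strand))
    out.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    return out


def write_bed(
    intervals: list[Interval],
    path: str | os.PathLike,
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write BED3 (or BED6 when names are given), sorted by contig, start."""
    order = sorted(range(len(intervals)), key=lambda i: (
        intervals[i].contig, intervals[i].start, intervals[i].end))
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            if names is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0 if scores is None else scores[i]
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{names[i]}\t"
                    f"{score:g}\t{iv.strand}\n"
                )


def _collapse(seq_counts: "Counter[str]", library_id: str, stage: str,
              argonaute: str, dropped: int) -> Library:
    reads = [ReadRecord(s, c) for s, c in sorted(seq_counts.items())]
    return Library(
        library_id=library_id, reads=reads, stage=stage, argonaute=argonaute,
        dropped_reads=dropped,
    )


def _parse_collapsed_count(header_id: str) -> int:
    """Collapsed-FASTA count dialect: '_x<int>' suffix; absent means 1."""
    if "_x" in header_id:
        tail = header_id.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def read_small_rna_library(
    path: str | os.PathLike,
    library_id: str | None = None,
    stage: str = "",
    argonaute: str = "input",
    fmt: str | None = None,
) -> Library:
    """Load an adapter-trimmed small-RNA library from FASTA/FASTQ.

    Identical sequences are merged with summed counts; reads with N or other
    non-ACGT characters are dropped and tallied in Library.dropped_reads.
    Pre-collapsed FASTA headers may carry counts as a ``_x<int>`` suffix.
    """
    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    counts: Counter[str] = Counter()
    dropped = 0
    for rec in SeqIO.parse(path, fmt):
        seq = str(rec.seq).upper()
        if not seq or set(seq) - VALID_READ_CHARS:
            dropped += 1
            continue
        counts[seq] += _parse_collapsed_count(rec.id) if fmt == "fasta" else 1
    if library_id is None:
        library_id = os.path.splitext(os.path.basename(path))[0]
    return _collapse(counts, library_id, stage, argonaute, dropped)


def write_fastq(library: Library, path: str | os.PathLike) -> None:
    """Write a library as FASTQ, one record per copy, constant quality."""
    with open(path, "w") as fh:
        i = 0
        for rec in library.reads:
            for _ in range(rec.count):
                fh.write(f"@r{i}\n{rec.sequence}\n+\n{'I' * rec.length}\n")
                i += 1


def write_collapsed_fasta(library: Library, path: str | os.PathLike) -> None:
    """Write a collapsed library as FASTA with the '_x<count>' dialect."""
    with open(path, "w") as fh:
        for i, rec in enumerate(library.reads):
            fh.write(f">r{i}_x{rec.count}\n{rec.sequence}\n")


def write_genome_fasta(genome: GenomeIndex, path: str | os.PathLike,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3_genes(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.contig}\twagoseq\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID=gene:{g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\twagoseq\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};Parent=gene:{g.gene_id}\n"
            )
            for j, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\twagoseq\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{j};Parent={g.gene_id}\n"
                )
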