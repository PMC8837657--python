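"""Domain types shared across the pipeline.

Coordinate convention: everything in memory is 0-based half-open on the
forward genome strand (BED style). GFF3 input is converted at the boundary.
Small-RNA sequences are stored as DNA (ACGT); the first nucleotide is
reported as A/C/G/U in profiles, mapping T to U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(COMPLEMENT)[::-1]


def first_nt_rna(seq: str) -> str:
    """First nucleotide of a read reported in RNA alphabet (T -> U)."""
    c = seq[0]
    return "U" if c == "T" else c


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        """Overlap in bp with another interval (0 if different contig)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeIndex:
    """Genome sequences with contig lengths and the mitochondrial contig set.

    Houses the genome length G used by coverage normalization (mito contigs
    are excluded from mean-coverage denominators).
    """

    def __init__(self, sequences: Mapping[str, str], mito_contigs: Iterable[str] = ()):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate contig name {name!r}")
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} has zero length")
            self.sequences[name] = seq.upper()
        if not self.sequences:
            raise ValueError("no sequences")
        self.lengths: dict[str, int] = {n: len(s) for n, s in self.sequences.items()}
        self.mito_contigs = set(mito_contigs)
        missing = self.mito_contigs - set(self.lengths)
        if missing:
            raise ValueError(f"mito contigs not in genome: {sorted(missing)}")

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    def nuclear_length(self) -> int:
        """Total non-mitochondrial genome length in bp."""
        return sum(
            l for n, l in self.lengths.items() if n not in self.mito_contigs
        )

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][start:end]


@dataclass
class GeneModel:
    """A spliced gene model: exons on one contig/strand plus derived introns.

    The mature-transcript coordinate system runs 5'->3' along the mRNA, i.e.
    exons concatenated left-to-right for '+' genes and right-to-left,
    reverse-complemented, for '-' genes.
    """

    gene_id: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        contigs = {e.contig for e in self.exons}
        if len(contigs) != 1:
            raise ValueError(f"gene {self.gene_id}: exons on multiple contigs")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if self.mature_length == 0:
            raise ValueError(f"gene {self.gene_id}: mature length 0")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def span(self) -> Interval:
        return Interval(self.contig, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [
            Interval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def spliced_sequence(self, genome: GenomeIndex) -> str:
        """Mature mRNA sequence, 5'->3', as DNA."""
        s = "".join(genome.fetch(e.contig, e.start, e.end) for e in self.exons)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class AnnotationBundle:
    """Stranded interval sets per feature class plus gene models."""

    rrna: list[Interval] = field(default_factory=list)
    trna: list[Interval] = field(default_factory=list)
    mirna: list[Interval] = field(default_factory=list)
    repeats: list[Interval] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    mito_contigs: set[str] = field(default_factory=set)

    def classes(self) -> dict[str, list[Interval]]:
        return {
            "rRNA": self.rrna,
            "tRNA": self.trna,
            "miRNA": self.mirna,
            "repeat": self.repeats,
        }

    def validate(self, genome: GenomeIndex) -> None:
        for label, ivs in self.classes().items():
            for iv in ivs:
                if iv.contig not in genome.lengths:
                    raise ValueError(f"{label} interval on unknown contig {iv.contig}")
                if iv.end > genome.lengths[iv.contig]:
                    raise ValueError(
                        f"{label} interval {iv.contig}:{iv.start}-{iv.end} "
                        "extends past contig end"
                    )
        for g in self.genes:
            if g.span.end > genome.lengths[g.contig]:
                raise ValueError(f"gene {g.gene_id} extends past contig end")


@dataclass
class ReadRecord:
    """A distinct small-RNA sequence with its copy number in a library."""

    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.sequence:
            raise ValueError("empty read sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return first_nt_rna(self.sequence)

    @property
    def in_size_range(self) -> bool:
        """Inside the 18-30 nt window the classification figures use."""
        return 18 <= self.length <= 30


@dataclass
class Library:
    """A collapsed small-RNA library: unique sequences with counts."""

    library_id: str
    reads: list[ReadRecord]
    stage: str = ""
    argonaute: str = "input"
    total_mapped_reads: int = 0  # set after placement
    dropped_reads: int = 0       # raw reads removed at load (N / bad chars)

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.reads]
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"library {self.library_id}: duplicate sequences")

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.reads)
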