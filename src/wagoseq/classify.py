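"""Nine-category small-RNA classification and size/first-nucleotide profiles.

Every read gets exactly one label from a strict priority cascade:

    1 rRNA > 2 tRNA > 3 miRNA > 4 WAGO_repeats > 5 antisense_mRNA >
    6 intron > 7 intergenic > 8 no_match > 9 sense_mRNA

Interval classes (1-4, 6) fire when any genome hit overlaps a class
interval by at least half the read length; sense/antisense mRNA labels come
from full-length exact matches to mature transcripts, so junction-spanning
reads with no genomic placement still classify as (anti)sense mRNA rather
than no-match. "Intergenic" fires only for genome-mapped reads where some
hit lands substantially outside every annotated class. Multimapping reads
take the best (lowest-rank) label over all of their hits.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import AnnotationBundle, Interval, Library
from .placement import PlacementSet

DEFAULT_MIN_OVERLAP_FRAC = 0.5
SIZE_RANGE = range(18, 31)
NT_COLUMNS = ("A", "C", "G", "U")


class Category(Enum):
    """The nine target categories, in priority order (rank = value)."""

    rRNA = 1
    tRNA = 2
    miRNA = 3
    WAGO_repeats = 4
    antisense_mRNA = 5
    intron = 6
    intergenic = 7
    no_match = 8
    sense_mRNA = 9

    @property
    def rank(self) -> int:
        return self.value


CATEGORY_ORDER = [c.name for c in sorted(Category, key=lambda c: c.rank)]


class AnnotationOverlaps:
    """Per-class overlap queries over merged, sorted interval lists.

    Intervals within a class are merged at build time, so the per-contig
    lists are disjoint and sorted; a short read can then overlap at most a
    few of them and bisection finds the best overlap in O(log n).
    """

    def __init__(self, annotations: AnnotationBundle,
                 wago_repeats: list[Interval] | None = None):
        if wago_repeats is None:
            wago_repeats = annotations.repeats
        self._index: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
        exons = [e for g in annotations.genes for e in g.exons]
        introns = [iv for g in annotations.genes for iv in g.introns]
        for label, ivs in [
            ("rRNA", annotations.rrna),
            ("tRNA", annotations.trna),
            ("miRNA", annotations.mirna),
            ("WAGO_repeats", wago_repeats),
            ("exon", exons),
            ("intron", introns),
        ]:
            per_contig: dict[str, list[tuple[int, int]]] = {}
            for iv in ivs:
                per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
            merged: dict[str, tuple[list[int], list[int]]] = {}
            for contig, pairs in per_contig.items():
                pairs.sort()
                starts, ends = [], []
                for s, e in pairs:
                    if ends and s <= ends[-1]:
                        ends[-1] = max(ends[-1], e)
                    else:
                        starts.append(s)
                        ends.append(e)
                merged[contig] = (starts, ends)
            self._index[label] = merged

    def overlap_bp(self, label: str, hit: Interval) -> int:
        entry = self._index[label].get(hit.contig)
        if not entry:
            return 0
        starts, ends = entry
        # rightmost merged interval starting at or before the hit start,
        # plus any following ones that still begin before the hit end
        i = max(bisect_right(starts, hit.start) - 1, 0)
        best = 0
        while i < len(starts) and starts[i] < hit.end:
            bp = min(ends[i], hit.end) - max(starts[i], hit.start)
            if bp > best:
                best = bp
            i += 1
        return best

    def fires(self, label: str, hit: Interval, min_bp: float) -> bool:
        return self.overlap_bp(label, hit) >= min_bp


def classify_read(
    placement: PlacementSet,
    overlaps: AnnotationOverlaps,
    read_length: int,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> Category:
    """Assign one read to the highest-priority satisfiable category."""
    if not placement.mapped:
        return Category.no_match
    min_bp = min_overlap_frac * read_length
    genome_hits = [iv for iv, _ in placement.genome_hits]

    for label in ("rRNA", "tRNA", "miRNA", "WAGO_repeats"):
        if any(overlaps.fires(label, h, min_bp) for h in genome_hits):
            return Category[label]
    if placement.antisense_transcript_hits():
        return Category.antisense_mRNA
    if any(overlaps.fires("intron", h, min_bp) for h in genome_hits):
        return Category.intron
    blocking = ("rRNA", "tRNA", "miRNA", "WAGO_repeats", "exon", "intron")
    for h in genome_hits:
        if not any(overlaps.fires(label, h, min_bp) for label in blocking):
            return Category.intergenic
    if any(h[2] == "sense" for h in placement.transcript_hits):
        return Category.sense_mRNA
    # mapped, near annotation but below every overlap threshold and with no
    # transcript match: genomic background
    return Category.intergenic


def classify_library(
    library: Library,
    placements: list[PlacementSet],
    annotations: AnnotationBundle,
    wago_repeats: list[Interval] | None = None,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> list[Category]:
    """Category per unique read, aligned with library.reads."""
    overlaps = AnnotationOverlaps(annotations, wago_repeats)
    return [
        classify_read(ps, overlaps, library.reads[ps.read_index].length,
                      min_overlap_frac)
        for ps in placements
    ]


@dataclass
class SizeProfile:
    """Counts by (read length 18-30) x (first nucleotide A/C/G/U)."""

    library_id: str
    matrix: pd.DataFrame          # index: lengths, columns: A/C/G/U
    out_of_range: int             # copies outside the 18-30 nt window

    @property
    def modal_length(self) -> int:
        return int(self.matrix.sum(axis=1).idxmax())

    def first_nt_fraction(self, nt: str, length: int | None = None) -> float:
        m = self.matrix if length is None else self.matrix.loc[[length]]
        total = float(m.to_numpy().sum())
        return float(m[nt].sum()) / total if total else 0.0


def size_profile(library: Library) -> SizeProfile:
    """Raw copy-number counts per (length, first nt), T reported as U."""
    mat = pd.DataFrame(
        0, index=list(SIZE_RANGE), columns=list(NT_COLUMNS), dtype=np.int64
    )
    out_of_range = 0
    for rec in library.reads:
        if rec.in_size_range:
            mat.loc[rec.length, rec.first_nt] += rec.count
        else:
            out_of_range += rec.count
    return SizeProfile(library.library_id, mat, out_of_range)


def category_profile(
    library: Library, categories: list[Category]
) -> pd.DataFrame:
    """Per-category copy counts and fractions for reads in the 18-30 window.

    Returns a frame indexed by the nine category names with columns
    'count' and 'fraction'; fractions sum to 1.
    """
    counts = dict.fromkeys(CATEGORY_ORDER, 0)
    for rec, cat in zip(library.reads, categories):
        if rec.in_size_range:
            counts[cat.name] += rec.count
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"library {library.library_id}: no classified reads")
    df = pd.DataFrame({"count": pd.Series(counts, dtype=np.int64)})
    df["fraction"] = df["count"] / total
    return df.loc[CATEGORY_ORDER]


def category_profile_table(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fractions matrix: categories x libraries."""
    return pd.DataFrame({lib: df["fraction"] for lib, df in profiles.items()})
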