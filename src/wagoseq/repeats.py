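"""Calling of small-RNA-enriched repeat loci ("WAGO-repeats").

The procedure, applied to normalized WAGO-class coverage tracks:

1. seed: maximal runs of bases with coverage >= F_seed x genome mean
   (20-fold over a ~2.5x mean gives the ~50x absolute cutoff), pooled over
   all libraries;
2. merge seeds within D = 2,000 bp (mergeBed -d semantics);
3. drop merged loci shorter than L_min = 50 bp;
4. keep loci with >= F_enr = 10-fold coverage enrichment over the genome
   mean in at least one library;
5. drop loci overlapping the rRNA/tRNA/miRNA blacklist (any overlap) or on
   mitochondrial contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationBundle, GenomeIndex, Interval, Library
from .placement import (
    FULL_SCALE_NORM_TARGET,
    CoverageTrack,
    PlacementSet,
    mean_genome_coverage,
)


@dataclass
class CallerParams:
    """Thresholds of the locus-calling procedure (full-scale defaults)."""

    norm_target: float = FULL_SCALE_NORM_TARGET
    seed_fold: float = 20.0     # F_seed, x genome-mean coverage
    merge_distance: int = 2000  # D, bp
    min_length: int = 50        # L_min, bp
    enrichment_fold: float = 10.0  # F_enr, x genome mean, in >= 1 library

    def __post_init__(self) -> None:
        if min(self.norm_target, self.seed_fold, self.min_length,
               self.enrichment_fold) <= 0 or self.merge_distance < 0:
            raise ValueError("caller thresholds must be positive (D >= 0)")


@dataclass
class EnrichedLocus:
    """A called WAGO-repeat region with per-library rpkm and fold enrichment."""

    interval: Interval
    rpkm: dict[str, float] = field(default_factory=dict)
    fold: dict[str, float] = field(default_factory=dict)
    seed_windows: list[Interval] = field(default_factory=list)

    @property
    def max_fold(self) -> float:
        return max(self.fold.values()) if self.fold else 0.0


def seed_windows(
    track: CoverageTrack, mean: float, seed_fold: float,
    mito_contigs: set[str] = frozenset(),
) -> list[Interval]:
    """Maximal runs of consecutive bases with coverage >= seed_fold x mean."""
    if mean <= 0:
        raise ValueError("genome mean coverage is zero")
    cutoff = seed_fold * mean
    out: list[Interval] = []
    for contig in sorted(track.arrays):
        if contig in mito_contigs:
            continue
        above = track.arrays[contig] >= cutoff
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            out.append(Interval(contig, int(s), int(e)))
    return out


def merge_within(intervals: list[Interval], distance: int) -> list[Interval]:
    """Merge intervals whose gap is <= distance, per contig (mergeBed -d).

    Transitive: chains of near intervals collapse into one. Strand ignored.
    """
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[Interval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= distance:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(contig, cur_s, cur_e))
    return merged


def locus_mean_coverage(locus: Interval, track: CoverageTrack) -> float:
    if len(locus) == 0:
        raise ValueError("zero-length locus")
    return float(track.arrays[locus.contig][locus.start:locus.end].mean())


def enrichment_fold(locus: Interval, track: CoverageTrack, mean: float) -> float:
    """Mean coverage within the locus over the genome-wide mean."""
    if mean <= 0:
        raise ValueError("genome mean coverage is zero")
    return locus_mean_coverage(locus, track) / mean


def locus_rpkm(
    locus: Interval,
    placements: list[PlacementSet],
    library: Library,
) -> float:
    """Reads per kb per million mapped reads within a locus.

    Multimappers contribute count/n_genome_hits per overlapping hit.
    """
    if len(locus) == 0:
        raise ValueError("zero-length locus")
    weighted = 0.0
    for ps in placements:
        if not ps.genome_hits:
            continue
        w = library.reads[ps.read_index].count / ps.n_genome_hits
        for iv, _ in ps.genome_hits:
            if iv.contig == locus.contig and iv.start < locus.end and iv.end > locus.start:
                weighted += w
    return weighted / (len(locus) / 1000 * library.total_mapped_reads / 1e6)


def weighted_reads_per_locus(
    loci: list[Interval],
    placements: list[PlacementSet],
    library: Library,
) -> list[float]:
    """Single-pass fractional read counts for many loci at once."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(loci):
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, i)
    totals = [0.0] * len(loci)
    for ps in placements:
        if not ps.genome_hits:
            continue
        w = library.reads[ps.read_index].count / ps.n_genome_hits
        for hit, _ in ps.genome_hits:
            tree = trees.get(hit.contig)
            if tree is None:
                continue
            for node in tree.overlap(hit.start, hit.end):
                totals[node.data] += w
    return totals


def _overlaps_any(locus: Interval, intervals: list[Interval]) -> bool:
    return any(locus.overlap_bp(iv) > 0 for iv in intervals)


def call_wago_repeats(
    tracks: dict[str, CoverageTrack],
    genome: GenomeIndex,
    annotations: AnnotationBundle,
    params: CallerParams = CallerParams(),
    placements: dict[str, list[PlacementSet]] | None = None,
    libraries: dict[str, Library] | None = None,
) -> tuple[list[EnrichedLocus], list[Interval]]:
    """Run the full locus-calling procedure over WAGO-class libraries.

    tracks map library id -> normalized CoverageTrack. Optional placements
    and libraries (same keys) add per-library rpkm values to each locus.
    Returns (called loci, blacklisted loci that were removed).
    """
    if not tracks:
        raise ValueError("no libraries given")
    means = {lib: mean_genome_coverage(t, genome) for lib, t in tracks.items()}
    seeds: list[Interval] = []
    for lib, track in tracks.items():
        seeds.extend(seed_windows(track, means[lib], params.seed_fold))
    if not seeds:
        return [], []
    merged = merge_within(seeds, params.merge_distance)
    merged = [iv for iv in merged if len(iv) >= params.min_length]

    blacklist = annotations.rrna + annotations.trna + annotations.mirna
    called: list[EnrichedLocus] = []
    removed: list[Interval] = []
    for iv in merged:
        folds = {
            lib: enrichment_fold(iv, track, means[lib])
            for lib, track in tracks.items()
        }
        if max(folds.values()) < params.enrichment_fold:
            continue
        if iv.contig in genome.mito_contigs or _overlaps_any(iv, blacklist):
            removed.append(iv)
            continue
        locus = EnrichedLocus(
            interval=iv, fold=folds,
            seed_windows=[s for s in seeds if s.overlap_bp(iv) > 0],
        )
        called.append(locus)
    if placements is not None and libraries is not None:
        loci_iv = [l.interval for l in called]
        for lib in tracks:
            counts = weighted_reads_per_locus(loci_iv, placements[lib], libraries[lib])
            m = libraries[lib].total_mapped_reads / 1e6
            for locus, n in zip(called, counts):
                locus.rpkm[lib] = n / (len(locus.interval) / 1000 * m)
    called.sort(key=lambda l: (l.interval.contig, l.interval.start))
    return called, removed


def target_overlap(
    query: list[Interval], subject: list[Interval]
) -> tuple[float, list[Interval]]:
    """Fraction of query bp covered by subject, plus intersected intervals."""
    total_q = sum(len(iv) for iv in query)
    if total_q == 0:
        return 0.0, []
    pieces: list[Interval] = []
    by_contig: dict[str, list[Interval]] = {}
    for iv in subject:
        by_contig.setdefault(iv.contig, []).append(iv)
    covered = 0
    for q in query:
        for s in sorted(by_contig.get(q.contig, []), key=lambda v: v.start):
            lo, hi = max(q.start, s.start), min(q.end, s.end)
            if lo < hi:
                pieces.append(Interval(q.contig, lo, hi))
                covered += hi - lo
    return covered / total_q, pieces
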