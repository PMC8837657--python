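"""WAGO-repeat locus calling: seeding, merging, enrichment, blacklist."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wagoseq import (
    CallerParams,
    call_wago_repeats,
    enrichment_fold,
    locus_rpkm,
    merge_within,
    seed_windows,
    target_overlap,
)
from wagoseq.core import AnnotationBundle, GenomeIndex, Interval, Library, ReadRecord
from wagoseq.placement import CoverageTrack, PlacementSet


def brute_force_merge(intervals, d):
    """O(n^2) transitive-closure merge oracle."""
    groups = [[iv] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = groups[i]
                b = groups[j]
                if any(
                    x.contig == y.contig
                    and max(x.start, y.start) - min(x.end, y.end) <= d
                    for x in a for y in b
                ):
                    groups[i] = a + b
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    out = [
        Interval(g[0].contig, min(x.start for x in g), max(x.end for x in g))
        for g in groups
    ]
    return sorted(out, key=lambda v: (v.contig, v.start))


class TestMergeWithin:
    def test_gap_within_distance_merges(self):
        got = merge_within([Interval("c", 100, 200), Interval("c", 1500, 1600)], 2000)
        assert got == [Interval("c", 100, 1600)]

    def test_gap_beyond_distance_unmerged(self):
        got = merge_within([Interval("c", 100, 200), Interval("c", 2701, 2800)], 2000)
        assert len(got) == 2

    def test_single_interval_unchanged(self):
        assert merge_within([Interval("c", 5, 10)], 2000) == [Interval("c", 5, 10)]

    def test_never_crosses_contigs(self):
        got = merge_within([Interval("a", 0, 10), Interval("b", 5, 15)], 1_000_000)
        assert len(got) == 2

    @settings(max_examples=150, deadline=None)
    @given(
        raw=st.lists(
            st.tuples(st.sampled_from(["c1", "c2"]),
                      st.integers(0, 5000), st.integers(1, 300)),
            min_size=1, max_size=60),
        d=st.integers(0, 1500),
    )
    def test_matches_transitive_closure_oracle(self, raw, d):
        intervals = [Interval(c, s, s + l) for c, s, l in raw]
        assert merge_within(intervals, d) == brute_force_merge(intervals, d)


class TestSeedWindows:
    def _track(self, arr):
        return CoverageTrack("t", {"c": np.asarray(arr, float)}, 1.0, 1.0)

    def test_absolute_cutoff_from_fold_and_mean(self):
        # 20-fold over a 2.5x mean is an absolute cutoff of 50x
        track = self._track([49.9] * 10 + [50.0] * 5 + [0.0] * 5)
        got = seed_windows(track, mean=2.5, seed_fold=20.0)
        assert got == [Interval("c", 10, 15)]

    def test_uniform_track_at_mean_yields_nothing(self):
        track = self._track([2.5] * 100)
        assert seed_windows(track, 2.5, 20.0) == []

    def test_step_track_exact_run(self):
        arr = np.zeros(300)
        arr[100:200] = 60 * 2.5
        got = seed_windows(self._track(arr), 2.5, 20.0)
        assert got == [Interval("c", 100, 200)]

    def test_zero_mean_fatal(self):
        with pytest.raises(ValueError):
            seed_windows(self._track([0.0]), 0.0, 20.0)


class TestEnrichmentAndRpkm:
    def test_fold_is_ratio_to_genome_mean(self):
        track = CoverageTrack("t", {"c": np.full(1000, 60.0)}, 1.0, 1.0)
        assert enrichment_fold(Interval("c", 0, 100), track, 2.4) == pytest.approx(25.0)

    def test_rpkm_hand_arithmetic(self):
        # 250 weighted reads / (0.5 kb x 30 M reads) = 16.667
        lib = Library("l", [ReadRecord("A" * 25, count=250)])
        lib.total_mapped_reads = 30_000_000
        pl = [PlacementSet(0, genome_hits=[(Interval("c", 100, 125, "+"), "+")])]
        got = locus_rpkm(Interval("c", 0, 500), pl, lib)
        assert got == pytest.approx(250 / (0.5 * 30))

    def test_empty_locus_zero(self):
        lib = Library("l", [ReadRecord("A" * 25, count=250)])
        lib.total_mapped_reads = 1_000_000
        pl = [PlacementSet(0, genome_hits=[(Interval("c", 5000, 5025, "+"), "+")])]
        assert locus_rpkm(Interval("c", 0, 500), pl, lib) == 0.0


class TestTargetOverlap:
    def test_identical_sets(self):
        ivs = [Interval("c", 0, 100), Interval("c", 500, 600)]
        frac, _ = target_overlap(ivs, ivs)
        assert frac == 1.0

    def test_disjoint_sets(self):
        frac, pieces = target_overlap([Interval("c", 0, 100)],
                                      [Interval("c", 200, 300)])
        assert frac == 0.0 and pieces == []

    def test_half_overlap(self):
        frac, pieces = target_overlap([Interval("c", 0, 100)],
                                      [Interval("c", 50, 150)])
        assert frac == pytest.approx(0.5)
        assert pieces == [Interval("c", 50, 100)]


def _synthetic_caller_setup(locus_cov=60.0, locus=(1000, 2000),
                            rrna=None, genome_len=100_000):
    genome = GenomeIndex({"c": "A" * genome_len})
    arr = np.full(genome_len, 1.0)
    arr[locus[0]:locus[1]] = locus_cov
    tracks = {"lib": CoverageTrack("lib", {"c": arr}, 1.0, 1.0)}
    ann = AnnotationBundle(rrna=[Interval("c", *rrna)] if rrna else [])
    return genome, tracks, ann


class TestCallWagoRepeats:
    def test_step_locus_called(self):
        genome, tracks, ann = _synthetic_caller_setup()
        loci, removed = call_wago_repeats(tracks, genome, ann)
        assert len(loci) == 1 and removed == []
        assert loci[0].interval == Interval("c", 1000, 2000)
        assert loci[0].max_fold > 10

    def test_blacklisted_locus_removed_but_logged(self):
        genome, tracks, ann = _synthetic_caller_setup(rrna=(1500, 1600))
        loci, removed = call_wago_repeats(tracks, genome, ann)
        assert loci == []
        assert removed == [Interval("c", 1000, 2000)]

    def test_mito_locus_removed(self):
        genome = GenomeIndex({"c": "A" * 50_000, "m": "C" * 10_000},
                             mito_contigs=["m"])
        arr_c = np.full(50_000, 1.0)
        arr_m = np.full(10_000, 1.0)
        arr_m[100:400] = 500.0
        tracks = {"lib": CoverageTrack("lib", {"c": arr_c, "m": arr_m}, 1.0, 1.0)}
        loci, removed = call_wago_repeats(tracks, genome, AnnotationBundle())
        assert loci == [] and removed == [Interval("m", 100, 400)]

    def test_short_locus_dropped(self):
        genome, tracks, ann = _synthetic_caller_setup(locus=(1000, 1030))
        loci, _ = call_wago_repeats(tracks, genome, ann)
        assert loci == []

    def test_threshold_monotonicity(self):
        genome = GenomeIndex({"c": "A" * 100_000})
        rng = np.random.default_rng(0)
        arr = np.full(100_000, 1.0)
        for start in range(2000, 90_000, 9000):
            arr[start:start + int(rng.integers(60, 400))] = float(rng.integers(15, 120))
        tracks = {"lib": CoverageTrack("lib", {"c": arr}, 1.0, 1.0)}
        ann = AnnotationBundle()
        base, _ = call_wago_repeats(tracks, genome, ann)
        stricter, _ = call_wago_repeats(
            tracks, genome, ann, CallerParams(enrichment_fold=40.0))
        assert {l.interval for l in stricter} <= {l.interval for l in base}
        longer_min, _ = call_wago_repeats(
            tracks, genome, ann, CallerParams(min_length=200))
        assert {l.interval for l in longer_min} <= {l.interval for l in base}

    def test_no_libraries_fatal(self):
        genome = GenomeIndex({"c": "A" * 1000})
        with pytest.raises(ValueError):
            call_wago_repeats({}, genome, AnnotationBundle())
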