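"""Exact-match placement, coverage weighting and normalization."""

import numpy as np
import pytest

from wagoseq import (
    CoverageTrack,
    build_index,
    build_transcript_index,
    coverage,
    mean_genome_coverage,
    place_reads,
)
from wagoseq.core import GeneModel, GenomeIndex, Interval, Library, ReadRecord, revcomp
from wagoseq.placement import KmerIndex, scaled_norm_target


def naive_hits(genome: GenomeIndex, read: str):
    """Brute-force scan of both strands (the placement oracle)."""
    out = []
    for strand, q in (("+", read), ("-", revcomp(read))):
        for name, seq in genome.sequences.items():
            start = 0
            while True:
                i = seq.find(q, start)
                if i < 0:
                    break
                out.append((name, i, strand))
                start = i + 1
    return sorted(out)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return GenomeIndex({
        "c1": rng.choice(bases, 30_000).tobytes().decode(),
        "c2": rng.choice(bases, 20_000).tobytes().decode(),
    })


class TestKmerIndex:
    def test_planted_substring_single_hit(self, toy_genome):
        idx = build_index(toy_genome)
        read = toy_genome.sequences["c1"][1000:1022]
        hits = idx.find_both_strands(read)
        assert ("c1", 1000, "+") in hits

    def test_absent_read_no_hits(self, toy_genome):
        idx = build_index(toy_genome)
        assert idx.find_both_strands("A" * 25) == naive_hits(toy_genome, "A" * 25)

    def test_duplicated_substring_two_hits(self):
        rng = np.random.default_rng(3)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        core = rng.choice(bases, 5_000).tobytes().decode()
        word = core[100:122]
        genome = GenomeIndex({"c": core + word + core[200:400]})
        idx = build_index(genome)
        got = sorted((n, p, s) for n, p, s in idx.find_both_strands(word))
        assert got == naive_hits(genome, word)
        assert sum(1 for _, _, s in got if s == "+") == 2

    def test_small_k_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            build_index(toy_genome, k=4)

    def test_oracle_equivalence_random_reads(self, toy_genome):
        """Index hit sets equal the naive substring scan of both strands."""
        idx = build_index(toy_genome)
        rng = np.random.default_rng(7)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for _ in range(300):
            length = int(rng.integers(18, 31))
            if rng.random() < 0.7:  # planted read (possibly revcomp)
                contig = "c1" if rng.random() < 0.5 else "c2"
                seq = toy_genome.sequences[contig]
                p = int(rng.integers(0, len(seq) - length))
                read = seq[p:p + length]
                if rng.random() < 0.5:
                    read = revcomp(read)
            else:
                read = rng.choice(bases, length).tobytes().decode()
            assert sorted(idx.find_both_strands(read)) == naive_hits(toy_genome, read)


class TestPlaceReads:
    def test_antisense_exonic_read_hits_genome_and_transcript(self, toy_genome):
        gene = GeneModel("g", "+", [Interval("c1", 1000, 1300, "+"),
                                    Interval("c1", 1500, 1800, "+")])
        idx = build_index(toy_genome)
        tidx = build_transcript_index([gene], toy_genome)
        inner = toy_genome.sequences["c1"][1550:1572]  # inside exon 2
        lib = Library("t", [ReadRecord(revcomp(inner))])
        ps = place_reads(lib, idx, tidx)[0]
        assert any(iv.start == 1550 and strand == "-" for iv, strand in ps.genome_hits)
        assert ("g", 350, "antisense") in ps.transcript_hits

    def test_junction_read_maps_only_to_transcript(self, toy_genome):
        gene = GeneModel("g", "+", [Interval("c1", 1000, 1300, "+"),
                                    Interval("c1", 1500, 1800, "+")])
        tx = gene.spliced_sequence(toy_genome)
        junction = tx[290:312]  # spans the exon1/exon2 boundary at offset 300
        lib = Library("t", [ReadRecord(revcomp(junction))])
        idx = build_index(toy_genome)
        tidx = build_transcript_index([gene], toy_genome)
        ps = place_reads(lib, idx, tidx)[0]
        assert ps.genome_hits == []
        assert ps.transcript_hits == [("g", 290, "antisense")]
        assert lib.total_mapped_reads == 1  # transcript-only reads count as mapped

    def test_unmapped_read_retained_with_empty_hits(self, toy_genome):
        idx = build_index(toy_genome)
        lib = Library("t", [ReadRecord("A" * 24)])
        ps = place_reads(lib, idx)[0]
        assert not ps.mapped and lib.total_mapped_reads == 0


class TestCoverage:
    def _single_hit_genome(self):
        return GenomeIndex({"c": "ACGT" * 2000})

    def test_multimapper_fractional_weight(self, toy_genome):
        idx = build_index(toy_genome)
        word = toy_genome.sequences["c1"][5000:5022]
        # synthesize a two-hit read by building a genome with a duplication
        genome = GenomeIndex({"c": toy_genome.sequences["c1"][:6000]
                              + toy_genome.sequences["c1"][4500:5500]})
        idx = build_index(genome)
        lib = Library("t", [ReadRecord(word, count=10)])
        pl = place_reads(lib, idx)
        assert pl[0].n_genome_hits == 2
        track = coverage(pl, lib, genome, norm_target=lib.total_mapped_reads)
        assert track.arrays["c"][5000] == pytest.approx(5.0)

    def test_normalization_scaling(self):
        # raw per-base 4.0 with 15 M mapped and N0 = 30 M -> 8.0
        genome = GenomeIndex({"c": "A" * 100})
        track = CoverageTrack("t", {"c": np.full(100, 4.0)}, 1.0, 1.0)
        track.arrays["c"] *= 30e6 / 15e6
        assert track.arrays["c"][0] == pytest.approx(8.0)

    def test_mass_conservation(self, sim_small, small_indexes):
        from wagoseq import simulate_library
        from wagoseq.simulate import default_archetypes

        idx, tidx = small_indexes
        sl = simulate_library(sim_small, default_archetypes()["input"], "M1",
                              depth=3000)
        pl = place_reads(sl.library, idx, tidx)
        lib = sl.library
        track = coverage(pl, lib, sim_small.genome,
                         norm_target=lib.total_mapped_reads)
        expected = sum(
            lib.reads[ps.read_index].count * lib.reads[ps.read_index].length
            for ps in pl if ps.genome_hits
        )
        assert track.total() == pytest.approx(expected, rel=1e-9)

    def test_count_doubling_leaves_normalized_track_identical(
            self, sim_small, small_indexes):
        from wagoseq import simulate_library
        from wagoseq.simulate import default_archetypes

        idx, tidx = small_indexes
        sl = simulate_library(sim_small, default_archetypes()["input"], "M2",
                              depth=3000)
        pl = place_reads(sl.library, idx, tidx)
        t1 = coverage(pl, sl.library, sim_small.genome, norm_target=1e6)
        doubled = Library("d", [ReadRecord(r.sequence, r.count * 2)
                                for r in sl.library.reads])
        pl2 = place_reads(doubled, idx, tidx)
        t2 = coverage(pl2, doubled, sim_small.genome, norm_target=1e6)
        for cname in t1.arrays:
            np.testing.assert_allclose(t1.arrays[cname], t2.arrays[cname],
                                       atol=1e-9)

    def test_zero_mapped_reads_fatal(self, toy_genome):
        idx = build_index(toy_genome)
        lib = Library("t", [ReadRecord("A" * 24)])
        pl = place_reads(lib, idx)
        with pytest.raises(ValueError):
            coverage(pl, lib, toy_genome)


class TestMeanCoverage:
    def test_two_contig_mean(self):
        genome = GenomeIndex({"a": "A" * 100, "b": "C" * 100})
        track = CoverageTrack("t", {"a": np.full(100, 1.0),
                                    "b": np.full(100, 3.0)}, 1.0, 1.0)
        assert mean_genome_coverage(track, genome) == pytest.approx(2.0)

    def test_mito_excluded(self):
        genome = GenomeIndex({"a": "A" * 100, "m": "C" * 100},
                             mito_contigs=["m"])
        track = CoverageTrack("t", {"a": np.full(100, 1.0),
                                    "m": np.full(100, 99.0)}, 1.0, 1.0)
        assert mean_genome_coverage(track, genome) == pytest.approx(1.0)

    def test_scaled_norm_target_keeps_mean_coverage(self):
        # 30 M reads of ~22 nt on 280 Mb ~ 2.36x; the scaled target keeps
        # that density on a small genome
        genome = GenomeIndex({"a": "A" * 2_000_000})
        n0 = scaled_norm_target(genome)
        assert n0 == round(30e6 * 2e6 / 280e6)
        assert 22 * n0 / 2e6 == pytest.approx(2.357, abs=0.01)
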