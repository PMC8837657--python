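"""Domain types, coordinate conventions and format round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from wagoseq import (
    GeneModel,
    Interval,
    ReadRecord,
    read_bed,
    read_fasta_genome,
    read_gff3_genes,
    read_small_rna_library,
    write_bed,
)
from wagoseq.core import GenomeIndex, Library, revcomp
from wagoseq.io import write_gff3_genes


class TestInterval:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("chr1", -1, 5)

    def test_length_and_overlap(self):
        a = Interval("chr1", 0, 100)
        assert len(a) == 100
        assert a.overlap_bp(Interval("chr1", 50, 150)) == 50
        assert a.overlap_bp(Interval("chr2", 50, 150)) == 0


class TestGeneModel:
    def test_introns_are_exon_gaps(self):
        # 1-based GFF exons [101,200] and [301,400] -> 0-based [100,200),[300,400)
        g = GeneModel("g1", "+", [Interval("c", 100, 200, "+"),
                                  Interval("c", 300, 400, "+")])
        assert g.mature_length == 200
        assert g.introns == [Interval("c", 200, 300, "+")]

    def test_single_exon_has_no_introns(self):
        g = GeneModel("g1", "-", [Interval("c", 0, 150, "-")])
        assert g.introns == []

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g1", "+", [Interval("c", 0, 100), Interval("c", 50, 150)])

    def test_minus_strand_spliced_sequence_is_revcomp(self):
        genome = GenomeIndex({"c": "AACCGGTTAACC"})
        g = GeneModel("g1", "-", [Interval("c", 0, 4, "-"), Interval("c", 8, 12, "-")])
        assert g.spliced_sequence(genome) == revcomp("AACC" + "AACC")


class TestFastaGenome:
    def test_two_contig_lengths(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\n" + "A" * 1000 + "\n>mito\n" + "C" * 100 + "\n")
        g = read_fasta_genome(p, mito_contigs=["mito"])
        assert g.lengths == {"chr1": 1000, "mito": 100}
        assert g.nuclear_length() == 1000

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_fasta_genome(p)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nacgtacgt\n")
        assert read_fasta_genome(p).sequences["c"] == "ACGTACGT"

    def test_duplicate_contig_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nACGT\n>c\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta_genome(p)


class TestGff3:
    def test_coordinate_conversion(self, tmp_path):
        genome = GenomeIndex({"c": "A" * 1000})
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t101\t400\t.\t+\t.\tID=gene:g1\n"
            "c\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g1;Parent=gene:g1\n"
            "c\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "c\tsrc\texon\t301\t400\t.\t+\t.\tID=g1.e2;Parent=g1\n"
        )
        models = read_gff3_genes(gff, genome)
        assert len(models) == 1
        g = models[0]
        assert g.exons == [Interval("c", 100, 200, "+"), Interval("c", 300, 400, "+")]
        assert g.mature_length == 200
        assert g.introns == [Interval("c", 200, 300, "+")]

    def test_exon_beyond_contig_rejected(self, tmp_path):
        genome = GenomeIndex({"c": "A" * 300})
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=g1\n"
            "c\tsrc\texon\t101\t400\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        with pytest.raises(ValueError, match="g1"):
            read_gff3_genes(gff, genome)

    def test_writer_reader_round_trip(self, sim_small, tmp_path):
        path = tmp_path / "genes.gff3"
        write_gff3_genes(sim_small.annotations.genes, path)
        models = read_gff3_genes(path, sim_small.genome)
        orig = {g.gene_id: g.exons for g in sim_small.annotations.genes}
        assert {g.gene_id: g.exons for g in models} == orig


class TestBed:
    def test_bed6_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t60\tr1\t0\t+\n")
        assert read_bed(p) == [Interval("chr1", 10, 60, "+")]

    def test_bed3_dot_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t60\n")
        assert read_bed(p)[0].strand == "."

    def test_negative_start_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t-5\t60\n")
        with pytest.raises(ValueError, match="1"):
            read_bed(p)

    @settings(max_examples=25, deadline=None)
    @given(raw=st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]),
                  st.integers(0, 10_000), st.integers(1, 500)),
        min_size=1, max_size=40))
    def test_round_trip_bit_exact(self, raw, tmp_path_factory):
        intervals = [Interval(c, s, s + l) for c, s, l in raw]
        d = tmp_path_factory.mktemp("bed")
        write_bed(intervals, d / "a.bed")
        again = read_bed(d / "a.bed")
        write_bed(again, d / "b.bed")
        assert (d / "a.bed").read_bytes() == (d / "b.bed").read_bytes()
        assert sorted(intervals, key=lambda v: (v.contig, v.start, v.end)) == again


class TestSmallRnaLibrary:
    def test_fastq_collapse(self, tmp_path):
        p = tmp_path / "r.fastq"
        seq1, seq2 = "G" * 22, "A" * 22
        recs = [seq1, seq1, seq1, seq2]
        p.write_text("".join(f"@r{i}\n{s}\n+\n{'I' * 22}\n" for i, s in enumerate(recs)))
        lib = read_small_rna_library(p)
        assert {r.sequence: r.count for r in lib.reads} == {seq1: 3, seq2: 1}

    def test_collapsed_fasta_count_dialect(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">r1_x57\n" + "G" * 22 + "\n")
        assert read_small_rna_library(p).reads[0].count == 57

    def test_reads_with_n_dropped_and_counted(self, tmp_path):
        p = tmp_path / "r.fa"
        p.write_text(">a\nACGTNACGTACGTACGTACGT\n>b\n" + "C" * 20 + "\n")
        lib = read_small_rna_library(p)
        assert len(lib.reads) == 1 and lib.dropped_reads == 1

    def test_collapsing_conserves_mass(self, tmp_path):
        p = tmp_path / "r.fastq"
        seqs = ["ACGT" * 5, "ACGT" * 5, "TTTTGGGGCCCCAAAA", "NNNNNNNNNNNNNNNN"]
        p.write_text("".join(
            f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs)))
        lib = read_small_rna_library(p)
        assert lib.total_reads + lib.dropped_reads == len(seqs)

    def test_sub_range_read_retained_but_flagged(self):
        rec = ReadRecord("ACGTACGTACGTACGTA", 1)  # 17 nt
        assert not rec.in_size_range
        lib = Library("l", [rec])
        assert lib.total_reads == 1
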