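"""Exact-match placement of 18-30 nt reads on genome and spliced transcriptome.

Alignment is exact and full-length: a hit exists iff the read (or its
reverse complement) is a substring of a contig or of a mature transcript.
The matcher seeds on the read's first k bases against a k-mer position table
and verifies by string comparison, so its hit set equals a naive scan of
both strands — a property the test suite checks directly.

Multimappers are fractionally weighted (1/n hits) in coverage so read mass
is conserved; tracks are then scaled to a fixed normalization target N0
(30 M reads at full scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GeneModel, GenomeIndex, Interval, Library, revcomp

DEFAULT_K = 18
MIN_K = 8
#: Full-scale normalization target from the study design: libraries are
#: scaled to 30 million reads, ~2.5x coverage of a 280 Mb genome at ~22 nt.
FULL_SCALE_NORM_TARGET = 30_000_000


_BASE_CODE = np.zeros(256, dtype=np.uint64)
_BASE_CODE[ord("C")] = 1
_BASE_CODE[ord("G")] = 2
_BASE_CODE[ord("T")] = 3


class KmerIndex:
    """Exact substring lookup over a set of named sequences.

    Every k-mer start position is encoded as a 2-bit-per-base integer and
    kept in one sorted array; a query seeds by binary search on its first k
    bases and candidates are verified by direct string comparison, so every
    reported hit is an exact full-length match. Non-ACGT genome characters
    collide in the encoding but are eliminated at verification.
    """

    def __init__(self, sequences: dict[str, str], k: int = DEFAULT_K):
        if k < MIN_K:
            raise ValueError(f"k={k} below minimum {MIN_K} (memory guard)")
        if k > 32:
            raise ValueError("k must be <= 32 (64-bit k-mer codes)")
        self.k = k
        self.sequences = sequences
        self._names = list(sequences)
        codes, seq_ids, positions = [], [], []
        for si, name in enumerate(self._names):
            seq = sequences[name]
            n = len(seq) - k + 1
            if n <= 0:
                continue
            arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            code = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                code = (code << np.uint64(2)) | arr[j:j + n]
            codes.append(code)
            seq_ids.append(np.full(n, si, dtype=np.int32))
            positions.append(np.arange(n, dtype=np.int32))
        if codes:
            allc = np.concatenate(codes)
            order = np.argsort(allc, kind="stable")
            self._codes = allc[order]
            self._seq_ids = np.concatenate(seq_ids)[order]
            self._positions = np.concatenate(positions)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._seq_ids = np.empty(0, dtype=np.int32)
            self._positions = np.empty(0, dtype=np.int32)

    _QUERY_TR = str.maketrans("ACGT", "0123")

    def _encode(self, query: str) -> int:
        """Base-4 integer of the first k bases; ValueError on non-ACGT."""
        return int(query[: self.k].translate(self._QUERY_TR), 4)

    def find(self, query: str) -> list[tuple[str, int]]:
        """All (name, start) exact full-length occurrences of query (sense)."""
        if len(query) < self.k:
            return []
        try:
            q = np.uint64(self._encode(query))
        except ValueError:  # non-ACGT characters cannot match the genome
            return []
        codes = self._codes
        lo = int(codes.searchsorted(q, side="left"))
        hits = []
        n = codes.size
        while lo < n and codes[lo] == q:
            name = self._names[self._seq_ids[lo]]
            pos = int(self._positions[lo])
            if self.sequences[name].startswith(query, pos):
                hits.append((name, pos))
            lo += 1
        hits.sort()
        return hits

    def find_both_strands(self, query: str) -> list[tuple[str, int, str]]:
        """Occurrences of query on either strand as (name, start, strand).

        Strand '+' means the read matches the stored sequence directly;
        '-' means its reverse complement does (the read is antisense).
        """
        out = [(n, p, "+") for n, p in self.find(query)]
        out += [(n, p, "-") for n, p in self.find(revcomp(query))]
        return out


def build_index(genome: GenomeIndex, k: int = DEFAULT_K) -> KmerIndex:
    """k-mer index over genome contigs (forward strand; both strands at query)."""
    return KmerIndex(genome.sequences, k=k)


def build_transcript_index(
    genes: list[GeneModel], genome: GenomeIndex, k: int = DEFAULT_K
) -> KmerIndex:
    """k-mer index over mature (spliced) transcript sequences."""
    return KmerIndex({g.gene_id: g.spliced_sequence(genome) for g in genes}, k=k)


@dataclass
class PlacementSet:
    """All exact placements of one read: genome hits and transcript hits.

    genome_hits: (interval on forward genome coords, read strand) —
    strand '+' if the read equals the genomic substring, '-' if it is its
    reverse complement. transcript_hits: (gene id, offset on the mature
    transcript, 'sense'|'antisense').
    """

    read_index: int
    genome_hits: list[tuple[Interval, str]] = field(default_factory=list)
    transcript_hits: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_genome_hits(self) -> int:
        return len(self.genome_hits)

    @property
    def mapped(self) -> bool:
        return bool(self.genome_hits or self.transcript_hits)

    def antisense_transcript_hits(self) -> list[tuple[str, int, str]]:
        return [h for h in self.transcript_hits if h[2] == "antisense"]


def place_reads(
    library: Library,
    index: KmerIndex,
    transcript_index: KmerIndex | None = None,
) -> list[PlacementSet]:
    """Place every read in a library on the genome and spliced transcriptome.

    Sets library.total_mapped_reads to the summed counts of reads with at
    least one genome OR transcript hit (junction-spanning reads map only to
    transcripts but still count as mapped).
    """
    placements: list[PlacementSet] = []
    total_mapped = 0
    for i, rec in enumerate(library.reads):
        ps = PlacementSet(read_index=i)
        for name, pos, strand in index.find_both_strands(rec.sequence):
            ps.genome_hits.append(
                (Interval(name, pos, pos + rec.length, strand), strand)
            )
        if transcript_index is not None:
            for name, pos, strand in transcript_index.find_both_strands(rec.sequence):
                orientation = "sense" if strand == "+" else "antisense"
                ps.transcript_hits.append((name, pos, orientation))
        if ps.mapped:
            total_mapped += rec.count
        placements.append(ps)
    library.total_mapped_reads = total_mapped
    return placements


@dataclass
class CoverageTrack:
    """Per-contig per-base weighted coverage for one library, normalized to N0."""

    library_id: str
    arrays: dict[str, np.ndarray]
    norm_factor: float
    norm_target: float

    def value_at(self, contig: str, pos: int) -> float:
        return float(self.arrays[contig][pos])

    def total(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))


def coverage(
    placements: list[PlacementSet],
    library: Library,
    genome: GenomeIndex,
    norm_target: float = FULL_SCALE_NORM_TARGET,
) -> CoverageTrack:
    """Strand-combined coverage track with fractional multimapper weighting.

    Each read adds count/n_genome_hits to every base of each of its genome
    hits; the track is then scaled by norm_target / total mapped reads.
    """
    if library.total_mapped_reads == 0:
        raise ValueError(f"library {library.library_id}: no mapped reads")
    arrays = {n: np.zeros(l, dtype=np.float64) for n, l in genome.lengths.items()}
    for ps in placements:
        if not ps.genome_hits:
            continue
        w = library.reads[ps.read_index].count / ps.n_genome_hits
        for iv, _strand in ps.genome_hits:
            arrays[iv.contig][iv.start:iv.end] += w
    factor = norm_target / library.total_mapped_reads
    for a in arrays.values():
        a *= factor
    return CoverageTrack(
        library_id=library.library_id, arrays=arrays,
        norm_factor=factor, norm_target=norm_target,
    )


def mean_genome_coverage(track: CoverageTrack, genome: GenomeIndex) -> float:
    """Mean per-base normalized coverage over non-mitochondrial contigs."""
    total = 0.0
    length = 0
    for name, arr in track.arrays.items():
        if name in genome.mito_contigs:
            continue
        total += float(arr.sum())
        length += arr.size
    if length == 0:
        raise ValueError("genome has no non-mitochondrial contigs")
    return total / length


def scaled_norm_target(genome: GenomeIndex, full_genome_bp: float = 280e6,
                       full_target: float = FULL_SCALE_NORM_TARGET) -> float:
    """Normalization target proportional to genome size.

    Keeps genome-mean coverage (and hence the absolute seed cutoff implied
    by a fold-over-mean threshold) at full-scale values on small genomes.
    """
    g = genome.nuclear_length() + sum(
        genome.lengths[c] for c in genome.mito_contigs)
    return round(full_target * g / full_genome_bp)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Export a coverage track as bedGraph (runs of equal value)."""
    with open(path, "w") as fh:
        for contig in sorted(track.arrays):
            arr = track.arrays[contig]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:.6g}\n")
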