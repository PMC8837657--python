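"""Synthetic genome, annotations and Argonaute-archetype small-RNA libraries.

The generator emulates the structure of a nematode germline small-RNA
study at desk scale: a ~2 Mb genome (two nuclear contigs plus one
mitochondrial contig) carrying non-overlapping gene models, repeat loci of
a dispersed TE-like family and a 120 bp tandem family, and miRNA/rRNA/tRNA
loci. Libraries of 18-30 nt reads are sampled with archetype-specific
length modes (22/23/24/26 nt), first-nucleotide bias (G for WAGO-class
archetypes, U for the miRNA-class archetype), and target mixtures over
{miRNA, repeat-antisense, mRNA-antisense, mRNA-sense, intergenic, rRNA,
tRNA}; two archetypes switch mixtures in late stages, emulating target
plasticity. Everything is deterministic under the config seed, and ground
truth (planted enriched loci, planted per-gene antisense rpkm, per-read
category labels) is returned alongside.

Dispersed repeats are windows into a 6 kb family consensus with 2 %
per-base mutation, so multi-mapping reads exist and exercise the
fractional-weight policy. The planted (small-RNA-producing) subset and the
cold dispersed subset use separate consensus sequences; tandem loci are
never planted (satellite-like tandem repeats are not small-RNA targets).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnnotationBundle, GeneModel, GenomeIndex, Interval, Library, ReadRecord, revcomp

STAGES = ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8")
MEIOSIS_STAGES = ("M5", "M6", "M7")
NOISE_STAGE = "M8"
MIX_CATEGORIES = (
    "repeat", "mRNA_antisense", "mRNA_sense", "miRNA", "rRNA", "tRNA",
    "intergenic",
)
#: simulation mixture component -> classification category name
TRUTH_LABELS = {
    "repeat": "WAGO_repeats",
    "mRNA_antisense": "antisense_mRNA",
    "mRNA_sense": "sense_mRNA",
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intergenic": "intergenic",
    "random": "no_match",
}
BASES = np.frombuffer(b"ACGT", dtype="S1")
DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


@dataclass
class ArchetypeSpec:
    """Sampling recipe for one Argonaute-IP archetype."""

    name: str
    mode_length: int
    first_nt: str               # 'G' or 'U' (RNA alphabet)
    first_nt_bias: float = 0.85
    mixture: dict[str, float] = field(default_factory=dict)
    mixture_late: dict[str, float] | None = None
    late_stages: frozenset[str] = frozenset()
    depth_factors: dict[str, float] = field(default_factory=dict)
    five_prime_bias_late: bool = False  # 5'-weighted antisense sampling late

    def __post_init__(self) -> None:
        for mix in (self.mixture, self.mixture_late):
            if mix is not None and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: mixture must sum to 1")

    def mixture_for(self, stage: str) -> dict[str, float]:
        if self.mixture_late is not None and stage in self.late_stages:
            return self.mixture_late
        return self.mixture

    def phase_of(self, stage: str) -> str:
        return "late" if stage in self.late_stages else "early"


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """Archetype table: length modes, 5' bias and target mixtures."""
    late = frozenset(MEIOSIS_STAGES)
    return {
        "ALG1_like": ArchetypeSpec(
            "ALG1_like", 22, "U",
            mixture={"miRNA": 0.70, "mRNA_sense": 0.10, "mRNA_antisense": 0.05,
                     "repeat": 0.05, "rRNA": 0.04, "tRNA": 0.03,
                     "intergenic": 0.03},
        ),
        "ALG4_like": ArchetypeSpec(
            "ALG4_like", 26, "G",
            mixture={"mRNA_antisense": 0.80, "mRNA_sense": 0.05,
                     "repeat": 0.05, "intergenic": 0.04, "rRNA": 0.02,
                     "tRNA": 0.02, "miRNA": 0.02},
            late_stages=frozenset({"M6", "M7"}),
            # 26G-RNAs only appear in late meiosis; earlier stages are
            # background-level IPs
            depth_factors={s: 0.005 for s in ("M1", "M2", "M3", "M4", "M5")},
        ),
        "WAGO12_like": ArchetypeSpec(
            "WAGO12_like", 22, "G",
            mixture={"repeat": 0.80, "mRNA_antisense": 0.08,
                     "intergenic": 0.05, "rRNA": 0.03, "tRNA": 0.02,
                     "miRNA": 0.01, "mRNA_sense": 0.01},
        ),
        "CSR1_like": ArchetypeSpec(
            "CSR1_like", 24, "G",
            mixture={"mRNA_antisense": 0.75, "repeat": 0.10,
                     "mRNA_sense": 0.05, "intergenic": 0.05, "rRNA": 0.02,
                     "tRNA": 0.02, "miRNA": 0.01},
        ),
        "NRDE3_like": ArchetypeSpec(
            "NRDE3_like", 22, "G",
            mixture={"repeat": 0.70, "mRNA_antisense": 0.10,
                     "intergenic": 0.08, "rRNA": 0.04, "tRNA": 0.03,
                     "miRNA": 0.02, "mRNA_sense": 0.03},
            mixture_late={"repeat": 0.25, "mRNA_antisense": 0.55,
                          "intergenic": 0.08, "rRNA": 0.04, "tRNA": 0.03,
                          "miRNA": 0.02, "mRNA_sense": 0.03},
            late_stages=late,
            five_prime_bias_late=True,
        ),
        "WAGO3_like": ArchetypeSpec(
            "WAGO3_like", 23, "G",
            mixture={"repeat": 0.75, "mRNA_antisense": 0.08,
                     "intergenic": 0.07, "rRNA": 0.04, "tRNA": 0.03,
                     "miRNA": 0.02, "mRNA_sense": 0.01},
            mixture_late={"mRNA_antisense": 0.65, "repeat": 0.15,
                          "intergenic": 0.08, "rRNA": 0.04, "tRNA": 0.04,
                          "miRNA": 0.02, "mRNA_sense": 0.02},
            late_stages=frozenset({"4cell"}),
        ),
        "input": ArchetypeSpec(
            "input", 22, "G",
            mixture={"repeat": 0.85, "mRNA_antisense": 0.04, "miRNA": 0.02,
                     "rRNA": 0.03, "tRNA": 0.02, "intergenic": 0.03,
                     "mRNA_sense": 0.01},
        ),
    }


#: configured NRDE-3-like switch stage (first stage on the late mixture)
NRDE3_SWITCH_STAGE = "M5"


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset (defaults are the conditions)."""

    seed: int = 1
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 980_000})
    mito_name: str = "mito"
    mito_length: int = 20_000
    n_genes: int = 300
    n_dispersed_planted: int = 40   # family A, the planted enriched subset
    n_dispersed_cold: int = 40      # family B, never planted
    n_tandem: int = 40              # 120 bp tandem family, never planted
    n_mirna: int = 30
    n_rrna: int = 8
    n_trna: int = 20
    depth: int = 200_000
    repeat_mutation: float = 0.02
    consensus_length: int = 6_000
    tandem_unit: int = 120
    expression_mu: float = np.log(50.0)  # log-normal expression (rpkm)
    expression_sigma: float = 1.0
    expression_cap: float = 150.0        # rpkm ceiling for expressed genes

    def __post_init__(self) -> None:
        if self.depth < 1_000:
            raise ValueError("depth must be >= 1,000")

    @property
    def n_repeats(self) -> int:
        return self.n_dispersed_planted + self.n_dispersed_cold + self.n_tandem


@dataclass
class TruthTables:
    """Ground truth planted by the generator."""

    planted_loci: list[Interval]
    expected_fold: float
    target_genes: dict[tuple[str, str], list[str]]  # (archetype, phase) -> ids


@dataclass
class SimulatedData:
    """Genome, annotations, expression and truth for one simulated study."""

    config: SimConfig
    genome: GenomeIndex
    annotations: AnnotationBundle
    expression: pd.DataFrame        # genes x stages, rpkm
    groups: pd.Series               # gene -> expression group
    truth: TruthTables
    intergenic: list[Interval]
    _tx_cache: dict[str, str] = field(default_factory=dict, repr=False)

    def transcript_sequence(self, gene_id: str) -> str:
        if gene_id not in self._tx_cache:
            gene = next(g for g in self.annotations.genes if g.gene_id == gene_id)
            self._tx_cache[gene_id] = gene.spliced_sequence(self.genome)
        return self._tx_cache[gene_id]

    def gene_by_id(self, gene_id: str) -> GeneModel:
        return next(g for g in self.annotations.genes if g.gene_id == gene_id)

    def planted_target_rpkm(self, archetype: ArchetypeSpec, stage: str) -> pd.Series:
        """Analytic antisense rpkm per gene implied by the configured mixture.

        rpkm_i = f * 1e6 * p_i / (mature length_i in kb), where f is the
        mRNA-antisense mixture mass and p_i the gene's allocation share.
        This is depth-free: realized libraries fluctuate multinomially
        around it.
        """
        f = self.mixture_for_stage(archetype, stage).get("mRNA_antisense", 0.0)
        shares = self.target_allocation(archetype, stage)
        lengths = {g.gene_id: g.mature_length for g in self.annotations.genes}
        rpkm = pd.Series(0.0, index=[g.gene_id for g in self.annotations.genes])
        for gid, p in shares.items():
            rpkm[gid] = f * 1e6 * p / (lengths[gid] / 1000)
        return rpkm

    def mixture_for_stage(self, archetype: ArchetypeSpec, stage: str) -> dict:
        if stage == NOISE_STAGE:
            return {}
        return archetype.mixture_for(stage)

    def target_allocation(self, archetype: ArchetypeSpec, stage: str) -> dict[str, float]:
        """Allocation shares of mRNA-antisense mass over planted target genes,
        proportional to stage expression (uniform fallback when no target is
        expressed in that stage)."""
        genes = self.truth.target_genes.get(
            (archetype.name, archetype.phase_of(stage)), [])
        if not genes:
            return {}
        lengths = {g.gene_id: g.mature_length for g in self.annotations.genes}
        if stage in self.expression.columns:
            # reads scale with molar abundance x transcript length
            w = np.array(
                [self.expression.loc[g, stage] * lengths[g] for g in genes],
                float,
            )
        else:
            w = np.ones(len(genes))
        if w.sum() <= 0:
            w = np.ones(len(genes))
        w = w / w.sum()
        return dict(zip(genes, w))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        cur = arr[i]
        choices = BASES[BASES != cur]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _child_rng(seed: int, *tokens) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens]
    return np.random.default_rng(parts)


def generate_genome(cfg: SimConfig) -> SimulatedData:
    """Generate the genome, annotations, expression table and truth tables."""
    rng = _child_rng(cfg.seed, "genome")
    sequences = {
        name: bytearray(_random_seq(rng, length), "ascii")
        for name, length in cfg.contig_lengths.items()
    }
    sequences[cfg.mito_name] = bytearray(_random_seq(rng, cfg.mito_length), "ascii")
    contigs = list(cfg.contig_lengths)

    # family consensus sequences
    consensus_a = _random_seq(rng, cfg.consensus_length)  # planted family
    consensus_b = _random_seq(rng, cfg.consensus_length)  # cold family
    tandem_unit = _random_seq(rng, cfg.tandem_unit)

    features: list[tuple[str, int]] = (
        [("gene", i) for i in range(cfg.n_genes)]
        + [("repA", i) for i in range(cfg.n_dispersed_planted)]
        + [("repB", i) for i in range(cfg.n_dispersed_cold)]
        + [("tandem", i) for i in range(cfg.n_tandem)]
        + [("mirna", i) for i in range(cfg.n_mirna)]
        + [("rrna", i) for i in range(cfg.n_rrna)]
        + [("trna", i) for i in range(cfg.n_trna)]
    )
    by_contig: dict[str, list[tuple[str, int]]] = {c: [] for c in contigs}
    for j, feat in enumerate(features):
        by_contig[contigs[j % len(contigs)]].append(feat)

    genes: list[GeneModel] = []
    mirna, rrna, trna = [], [], []
    planted: list[Interval] = []
    cold: list[Interval] = []
    for contig in contigs:
        order = rng.permutation(len(by_contig[contig]))
        cursor = int(rng.integers(500, 1500))
        last_repeat_end = -10_000
        last_feature_end = -10_000
        length = cfg.contig_lengths[contig]
        for oi in order:
            kind, idx = by_contig[contig][oi]
            cursor += int(rng.integers(350, 1000))
            # buffer repeat loci by more than the 2 kb merge distance from
            # every other feature, so locus merging cannot chain a repeat to
            # a gene or blacklist locus that also carries read coverage
            if kind in ("repA", "repB", "tandem"):
                cursor = max(cursor, last_feature_end + 2600 + int(rng.integers(0, 400)))
            else:
                cursor = max(cursor, last_repeat_end + 2600 + int(rng.integers(0, 400)))
            if kind == "gene":
                n_ex = int(rng.integers(1, 9))
                strand = "+" if rng.random() < 0.5 else "-"
                exons = []
                pos = cursor
                for e in range(n_ex):
                    elen = int(rng.integers(120, 401))
                    exons.append(Interval(contig, pos, pos + elen, strand))
                    pos += elen
                    if e < n_ex - 1:
                        pos += int(rng.integers(60, 301))
                cursor = pos
                genes.append(GeneModel(f"g{len(genes):04d}", strand, exons))
            elif kind in ("repA", "repB"):
                if kind == "repA":
                    llen = int(rng.integers(500, 2001))
                    consensus = consensus_a
                else:
                    llen = int(rng.integers(500, 3001))
                    consensus = consensus_b
                off = int(rng.integers(0, cfg.consensus_length - llen + 1))
                seq = _mutate(rng, consensus[off:off + llen], cfg.repeat_mutation)
                sequences[contig][cursor:cursor + llen] = seq.encode()
                iv = Interval(contig, cursor, cursor + llen)
                (planted if kind == "repA" else cold).append(iv)
                cursor += llen
                last_repeat_end = cursor
            elif kind == "tandem":
                copies = int(rng.integers(5, 21))
                seq = "".join(
                    _mutate(rng, tandem_unit, cfg.repeat_mutation)
                    for _ in range(copies)
                )
                sequences[contig][cursor:cursor + len(seq)] = seq.encode()
                cold.append(Interval(contig, cursor, cursor + len(seq)))
                cursor += len(seq)
                last_repeat_end = cursor
            elif kind == "mirna":
                mirna.append(Interval(contig, cursor, cursor + 60, "+"))
                cursor += 60
            elif kind == "rrna":
                rrna.append(Interval(contig, cursor, cursor + 1500, "+"))
                cursor += 1500
            elif kind == "trna":
                trna.append(Interval(contig, cursor, cursor + 80, "+"))
                cursor += 80
            last_feature_end = cursor
            if cursor > length - 1200:
                raise ValueError(
                    f"genome too small: contig {contig} needs > {cursor + 1200} bp"
                )

    genome = GenomeIndex(
        {n: bytes(s).decode() for n, s in sequences.items()},
        mito_contigs={cfg.mito_name},
    )
    catalog = sorted(planted + cold, key=lambda iv: (iv.contig, iv.start))
    annotations = AnnotationBundle(
        rrna=sorted(rrna), trna=sorted(trna), mirna=sorted(mirna),
        repeats=catalog, genes=genes, mito_contigs={cfg.mito_name},
    )
    annotations.validate(genome)

    # stage expression: constitutive (M1-M7), meiosis-specific (M5-M7), other
    gids = [g.gene_id for g in genes]
    n = len(gids)
    group_draw = rng.random(n)
    groups = np.where(group_draw < 0.6, "constitutive",
                      np.where(group_draw < 0.8, "meiosis_specific", "other"))
    expr = pd.DataFrame(0.0, index=gids, columns=list(STAGES))
    for i, gid in enumerate(gids):
        if groups[i] == "constitutive":
            vals = np.clip(
                rng.lognormal(cfg.expression_mu, cfg.expression_sigma, 7),
                8.0, cfg.expression_cap)
            expr.loc[gid, list(STAGES[:7])] = vals
        elif groups[i] == "meiosis_specific":
            vals = np.clip(
                rng.lognormal(cfg.expression_mu, cfg.expression_sigma, 3),
                8.0, cfg.expression_cap)
            expr.loc[gid, list(MEIOSIS_STAGES)] = vals
        else:
            stage = STAGES[int(rng.integers(0, 7))]
            expr.loc[gid, stage] = float(rng.uniform(5.5, 9.0))
    # spermatids: background levels everywhere
    expr["M8"] = 0.0

    const_ids = [g for g, k in zip(gids, groups) if k == "constitutive"]
    meio_ids = [g for g, k in zip(gids, groups) if k == "meiosis_specific"]

    def pick(pool, k):
        k = min(k, len(pool))
        return sorted(rng.choice(pool, size=k, replace=False).tolist())

    csr_targets = pick(const_ids, 45) + pick(meio_ids, 15)
    target_genes = {
        ("CSR1_like", "early"): csr_targets,
        ("ALG4_like", "late"): pick(meio_ids, 40),
        ("NRDE3_like", "early"): pick(const_ids, 30),
        ("NRDE3_like", "late"): pick(const_ids, 35) + pick(meio_ids, 15),
        # WAGO-class and input mRNA-antisense mass is spread over the broad
        # licensed set, keeping per-gene coverage below the locus seed cutoff
        ("WAGO12_like", "early"): csr_targets,
        ("WAGO3_like", "early"): csr_targets,
        ("WAGO3_like", "late"): pick(const_ids, 40),
        ("ALG1_like", "early"): pick(const_ids, 20),
        ("input", "early"): csr_targets,
    }
    # ALG4 mixtures are phase-independent; reuse the same planted set
    target_genes[("ALG4_like", "early")] = target_genes[("ALG4_like", "late")]
    # single-phase archetypes use the same set in both phases
    for name in ("CSR1_like", "WAGO12_like", "ALG1_like", "input"):
        target_genes[(name, "late")] = target_genes[(name, "early")]

    sum_planted = sum(len(iv) for iv in planted)
    expected_fold = 0.80 * genome.nuclear_length() / sum_planted

    # intergenic complement on nuclear contigs
    occupied: dict[str, list[Interval]] = {c: [] for c in contigs}
    for iv in catalog + rrna + trna + mirna:
        occupied[iv.contig].append(iv)
    for g in genes:
        occupied[g.contig].append(g.span)
    intergenic: list[Interval] = []
    for contig in contigs:
        ivs = sorted(occupied[contig], key=lambda v: v.start)
        pos = 0
        for iv in ivs:
            if iv.start - pos >= 60:
                intergenic.append(Interval(contig, pos, iv.start))
            pos = max(pos, iv.end)
        if cfg.contig_lengths[contig] - pos >= 60:
            intergenic.append(Interval(contig, pos, cfg.contig_lengths[contig]))

    return SimulatedData(
        config=cfg, genome=genome, annotations=annotations, expression=expr,
        groups=pd.Series(groups, index=gids, name="group"),
        truth=TruthTables(
            planted_loci=sorted(planted, key=lambda v: (v.contig, v.start)),
            expected_fold=expected_fold, target_genes=target_genes,
        ),
        intergenic=intergenic,
    )


@dataclass
class SimulatedLibrary:
    """A simulated library plus its per-read ground truth."""

    library: Library
    labels: list[str]               # truth category per unique read
    planted_rpkm: pd.Series | None  # analytic antisense rpkm per gene


def _sample_lengths(rng, n: int, mode: int, noise: bool) -> np.ndarray:
    if noise:
        return rng.integers(18, 31, size=n)
    return np.clip(np.rint(rng.normal(mode, 1.0, size=n)), 18, 30).astype(int)


def _biased_window(rng, seq: str, length: int, want_last: str | None,
                   positions=None, tries: int = 40) -> int:
    """Uniform start position, optionally requiring seq[p+length-1]==want_last."""
    hi = len(seq) - length
    if hi < 0:
        raise ValueError("feature shorter than read")
    for _ in range(tries if want_last else 1):
        p = int(rng.integers(0, hi + 1))
        if want_last is None or seq[p + length - 1] == want_last:
            return p
    return p


def simulate_library(
    sim: SimulatedData,
    archetype: ArchetypeSpec,
    stage: str,
    depth: int | None = None,
    library_id: str | None = None,
) -> SimulatedLibrary:
    """Simulate one IP (or input) library for one stage, with truth labels."""
    cfg = sim.config
    if depth is None:
        depth = cfg.depth
    depth = int(round(depth * archetype.depth_factors.get(stage, 1.0)))
    if depth <= 0:
        raise ValueError(f"{archetype.name}/{stage}: zero depth requested")
    rng = _child_rng(cfg.seed, "library", archetype.name, stage)
    noise = stage == NOISE_STAGE
    # for antisense sampling we constrain the *last* genomic base of the
    # window: the read 5' nt is the complement of that base
    anti_last = DNA_COMPLEMENT[archetype.first_nt]  # e.g. G-start -> window ends C
    sense_first = "T" if archetype.first_nt == "U" else archetype.first_nt

    if noise:
        cats = ["random"] + list(MIX_CATEGORIES)
        probs = np.full(len(cats), 1.0 / len(cats))
    else:
        mix = archetype.mixture_for(stage)
        cats = list(mix)
        probs = np.array([mix[c] for c in cats])
    counts = rng.multinomial(depth, probs)

    planted = sim.truth.planted_loci
    planted_seqs = [sim.genome.fetch(iv.contig, iv.start, iv.end) for iv in planted]
    planted_w = np.array([len(iv) for iv in planted], float)
    planted_w /= planted_w.sum()

    alloc = sim.target_allocation(archetype, stage)
    alloc_genes = list(alloc)
    alloc_p = np.array([alloc[g] for g in alloc_genes]) if alloc_genes else None

    expr_col = stage if stage in sim.expression.columns else sim.expression.columns[0]
    expr = sim.expression[expr_col]
    sense_w = expr.to_numpy(dtype=float) + 0.01
    sense_w /= sense_w.sum()
    all_gene_ids = list(expr.index)

    inter_w = np.array([len(iv) for iv in sim.intergenic], float)
    inter_w /= inter_w.sum()
    class_loci = {
        "rRNA": sim.annotations.rrna,
        "tRNA": sim.annotations.trna,
        "miRNA": sim.annotations.mirna,
    }
    use_5p_bias = (
        archetype.five_prime_bias_late and archetype.phase_of(stage) == "late"
    )

    seq_counts: dict[str, int] = {}
    seq_labels: dict[str, str] = {}

    def emit(seq: str, label: str) -> None:
        seq_counts[seq] = seq_counts.get(seq, 0) + 1
        seq_labels.setdefault(seq, label)

    for cat, n_cat in zip(cats, counts):
        if n_cat == 0:
            continue
        lens = _sample_lengths(rng, n_cat, archetype.mode_length, noise)
        label = TRUTH_LABELS[cat]
        if cat == "repeat" and not planted:
            raise ValueError("repeat mixture requested but no planted loci")
        if cat == "mRNA_antisense" and not alloc_genes:
            raise ValueError(
                f"{archetype.name}/{stage}: mRNA-antisense mixture requested "
                "but no planted target genes")
        for L in lens:
            L = int(L)
            biased = (not noise) and rng.random() < archetype.first_nt_bias
            if cat == "random":
                emit(_random_seq(rng, L), label)
            elif cat == "repeat":
                i = int(rng.choice(len(planted), p=planted_w))
                seq = planted_seqs[i]
                p = _biased_window(rng, seq, L, anti_last if biased else None)
                emit(revcomp(seq[p:p + L]), label)
            elif cat == "mRNA_antisense":
                gid = alloc_genes[int(rng.choice(len(alloc_genes), p=alloc_p))]
                tx = sim.transcript_sequence(gid)
                hi = len(tx) - L
                want = anti_last if biased else None
                for _ in range(40):
                    if use_5p_bias:
                        p = int(rng.beta(1.0, 4.0) * hi)
                    else:
                        p = int(rng.integers(0, hi + 1))
                    if want is None or tx[p + L - 1] == want:
                        break
                emit(revcomp(tx[p:p + L]), label)
            elif cat == "mRNA_sense":
                gid = all_gene_ids[int(rng.choice(len(all_gene_ids), p=sense_w))]
                tx = sim.transcript_sequence(gid)
                if len(tx) <= L:
                    emit(_random_seq(rng, L), "no_match")
                    continue
                want = sense_first if biased else None
                for _ in range(40):
                    p = int(rng.integers(0, len(tx) - L + 1))
                    if want is None or tx[p] == want:
                        break
                emit(tx[p:p + L], label)
            elif cat in ("miRNA", "rRNA", "tRNA"):
                loci = class_loci[cat]
                iv = loci[int(rng.integers(0, len(loci)))]
                seq = sim.genome.fetch(iv.contig, iv.start, iv.end)
                want = sense_first if biased else None
                for _ in range(40):
                    p = int(rng.integers(0, len(seq) - L + 1))
                    if want is None or seq[p] == want:
                        break
                emit(seq[p:p + L], label)
            elif cat == "intergenic":
                iv = sim.intergenic[int(rng.choice(len(sim.intergenic), p=inter_w))]
                seq = sim.genome.fetch(iv.contig, iv.start, iv.end)
                p = int(rng.integers(0, len(seq) - L + 1))
                w = seq[p:p + L]
                emit(w if rng.random() < 0.5 else revcomp(w), label)

    ordered = sorted(seq_counts)
    reads = [ReadRecord(s, seq_counts[s]) for s in ordered]
    labels = [seq_labels[s] for s in ordered]
    if library_id is None:
        library_id = f"{stage}_{archetype.name}"
    lib = Library(library_id=library_id, reads=reads, stage=stage,
                  argonaute=archetype.name)
    planted_rpkm = None
    if not noise and archetype.mixture_for(stage).get("mRNA_antisense", 0) > 0:
        planted_rpkm = sim.planted_target_rpkm(archetype, stage)
    return SimulatedLibrary(library=lib, labels=labels, planted_rpkm=planted_rpkm)


SERIES_ARCHETYPES = ("CSR1_like", "NRDE3_like", "ALG4_like", "WAGO12_like", "input")


def stage_series(
    sim: SimulatedData,
    archetype_names: tuple[str, ...] = SERIES_ARCHETYPES,
    stages: tuple[str, ...] = STAGES,
    depth: int | None = None,
) -> dict[tuple[str, str], SimulatedLibrary]:
    """Simulate the male-germline stage series for the given archetypes."""
    table = default_archetypes()
    out: dict[tuple[str, str], SimulatedLibrary] = {}
    for name in archetype_names:
        for stage in stages:
            out[(name, stage)] = simulate_library(sim, table[name], stage, depth)
    return out
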