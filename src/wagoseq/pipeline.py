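"""End-to-end orchestration: simulate/load -> place -> classify -> call loci
-> call targets -> comparative stats, with a run manifest.

The demo path generates the default synthetic study and runs every stage on
it; the file path loads a genome, gene models, annotation BEDs and a
library manifest TSV (columns: id, stage, argonaute, path).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as wio
from .classify import category_profile, category_profile_table, classify_library, size_profile
from .core import AnnotationBundle, GenomeIndex, Library
from .placement import (
    build_index,
    build_transcript_index,
    coverage,
    mean_genome_coverage,
    place_reads,
    scaled_norm_target,
)
from .repeats import CallerParams, call_wago_repeats
from .simulate import (
    SERIES_ARCHETYPES,
    STAGES,
    SimConfig,
    default_archetypes,
    generate_genome,
    simulate_library,
)
from .stats import pca_libraries, plasticity_summary, venn_counts, zscore_rows
from .targets import (
    antisense_gene_rpkm,
    call_targets,
    expression_groups,
    metagene,
)


@dataclass
class RunConfig:
    """Validated run configuration (paths, thresholds, seed)."""

    out_dir: str
    seed: int = 1
    demo: bool = False
    genome: str | None = None
    gff3: str | None = None
    rrna_bed: str | None = None
    trna_bed: str | None = None
    mirna_bed: str | None = None
    repeats_bed: str | None = None
    mito_contigs: list[str] = field(default_factory=list)
    libraries_manifest: str | None = None
    expression_table: str | None = None
    norm_target: float | None = None   # default: scaled to genome size
    caller: CallerParams = field(default_factory=CallerParams)
    rpkm_threshold: float = 10.0
    expr_threshold: float = 5.0
    depth: int | None = None           # demo only
    caller_archetype: str = "WAGO12_like"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        caller = CallerParams(**raw.pop("caller", {}))
        cfg = cls(caller=caller, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.demo:
            return
        for name in ("genome", "gff3", "libraries_manifest"):
            p = getattr(self, name)
            if p is None or not os.path.exists(p):
                raise FileNotFoundError(f"config path {name!r} missing: {p}")
        for name in ("rrna_bed", "trna_bed", "mirna_bed", "repeats_bed",
                     "expression_table"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"config path {name!r} missing: {p}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(cfg: RunConfig) -> tuple[GenomeIndex, AnnotationBundle, list[Library]]:
    genome = wio.read_fasta_genome(cfg.genome, mito_contigs=cfg.mito_contigs)
    genes = wio.read_gff3_genes(cfg.gff3, genome)
    ann = AnnotationBundle(
        rrna=wio.read_bed(cfg.rrna_bed) if cfg.rrna_bed else [],
        trna=wio.read_bed(cfg.trna_bed) if cfg.trna_bed else [],
        mirna=wio.read_bed(cfg.mirna_bed) if cfg.mirna_bed else [],
        repeats=wio.read_bed(cfg.repeats_bed) if cfg.repeats_bed else [],
        genes=genes, mito_contigs=set(cfg.mito_contigs),
    )
    ann.validate(genome)
    manifest = pd.read_csv(cfg.libraries_manifest, sep="\t")
    libraries = [
        wio.read_small_rna_library(
            row["path"], library_id=str(row["id"]), stage=str(row["stage"]),
            argonaute=str(row["argonaute"]),
        )
        for _, row in manifest.iterrows()
    ]
    return genome, ann, libraries


def run_all(cfg: RunConfig) -> dict:
    """Execute the whole pipeline; returns a summary dict (also written as
    manifest.json in the output directory)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    expression = None
    sim = None
    if cfg.demo:
        sim_cfg = SimConfig(seed=cfg.seed, **(
            {"depth": cfg.depth} if cfg.depth else {}))
        sim = generate_genome(sim_cfg)
        genome, ann = sim.genome, sim.annotations
        expression = sim.expression
        table = default_archetypes()
        lib_specs = [(a, s) for a in SERIES_ARCHETYPES for s in STAGES]
        wio.write_bed(sim.truth.planted_loci,
                      os.path.join(cfg.out_dir, "truth_enriched.bed"))
        expression.to_csv(os.path.join(cfg.out_dir, "expression.tsv"), sep="\t")
    else:
        genome, ann, libraries = load_inputs(cfg)
        if cfg.expression_table:
            expression = pd.read_csv(cfg.expression_table, sep="\t", index_col=0)

    norm_target = cfg.norm_target or scaled_norm_target(genome)
    index = build_index(genome)
    tindex = build_transcript_index(ann.genes, genome)

    profiles: dict[str, pd.DataFrame] = {}
    rpkm_cols: dict[str, pd.Series] = {}
    caller_tracks, caller_placements, caller_libs = {}, {}, {}
    stage_of: dict[str, str] = {}
    argonaute_of: dict[str, str] = {}

    def process(lib: Library):
        placements = place_reads(lib, index, tindex)
        cats = classify_library(lib, placements, ann)
        profiles[lib.library_id] = category_profile(lib, cats)
        size_profile(lib).matrix.to_csv(
            os.path.join(cfg.out_dir, f"size_profile_{lib.library_id}.tsv"),
            sep="\t")
        rpkm_cols[lib.library_id] = antisense_gene_rpkm(placements, lib, ann.genes)
        stage_of[lib.library_id] = lib.stage
        argonaute_of[lib.library_id] = lib.argonaute
        if lib.argonaute == cfg.caller_archetype and lib.total_mapped_reads:
            caller_tracks[lib.library_id] = coverage(
                placements, lib, genome, norm_target)
            caller_placements[lib.library_id] = placements
            caller_libs[lib.library_id] = lib

    if cfg.demo:
        for arch_name, stage in lib_specs:
            sl = simulate_library(sim, table[arch_name], stage)
            process(sl.library)
    else:
        for lib in libraries:
            process(lib)

    # category and size summaries
    cat_table = category_profile_table(profiles)
    cat_table.to_csv(os.path.join(cfg.out_dir, "category_profile.tsv"), sep="\t")

    # WAGO-repeat loci from the WAGO-class libraries
    loci = []
    if caller_tracks:
        params = CallerParams(
            norm_target=norm_target, seed_fold=cfg.caller.seed_fold,
            merge_distance=cfg.caller.merge_distance,
            min_length=cfg.caller.min_length,
            enrichment_fold=cfg.caller.enrichment_fold)
        loci, removed = call_wago_repeats(
            caller_tracks, genome, ann, params,
            caller_placements, caller_libs)
        wio.write_bed(
            [l.interval for l in loci],
            os.path.join(cfg.out_dir, "wago_repeats.bed"),
            names=[f"locus_{i}" for i in range(len(loci))],
            scores=[min(l.max_fold * 10, 1000) for l in loci])
        pd.DataFrame({lib: {f"locus_{i}": l.rpkm.get(lib, 0.0)
                            for i, l in enumerate(loci)}
                      for lib in caller_tracks}).to_csv(
            os.path.join(cfg.out_dir, "wago_repeats_rpkm.tsv"), sep="\t")

    # mRNA targets
    rpkm = pd.DataFrame(rpkm_cols)
    rpkm.to_csv(os.path.join(cfg.out_dir, "antisense_rpkm.tsv"), sep="\t")
    target_sets = call_targets(rpkm, cfg.rpkm_threshold)
    for lib_id, targets in target_sets.items():
        with open(os.path.join(cfg.out_dir, f"targets_{lib_id}.txt"), "w") as fh:
            fh.write("\n".join(sorted(targets)) + "\n")

    summary: dict = {
        "seed": cfg.seed,
        "norm_target": norm_target,
        "n_libraries": len(profiles),
        "n_wago_repeat_loci": len(loci),
        "thresholds": {
            "seed_fold": cfg.caller.seed_fold,
            "merge_distance": cfg.caller.merge_distance,
            "min_length": cfg.caller.min_length,
            "enrichment_fold": cfg.caller.enrichment_fold,
            "rpkm_target": cfg.rpkm_threshold,
            "rpkm_expressed": cfg.expr_threshold,
        },
    }

    if expression is not None and {"M1", "M7"} <= set(expression.columns):
        groups = expression_groups(expression, threshold=cfg.expr_threshold)
        groups.to_csv(os.path.join(cfg.out_dir, "expression_groups.tsv"), sep="\t")
        summary["expression_groups"] = groups.value_counts().to_dict()

    # comparative stats over libraries with any antisense signal
    active = rpkm.columns[(rpkm > 0).any()]
    if len(active) >= 3:
        pca = pca_libraries(rpkm[active])
        pca.coordinates.to_csv(os.path.join(cfg.out_dir, "pca_coords.tsv"), sep="\t")
        summary["pca_variance_pct"] = [round(float(v), 3)
                                       for v in pca.variance_explained[:2]]
    if rpkm.shape[1] >= 2:
        z, flagged = zscore_rows(rpkm)
        z.to_csv(os.path.join(cfg.out_dir, "zscore_antisense.tsv"), sep="\t")
        summary["zscore_flat_rows"] = len(flagged)

    # plasticity per Argonaute family over the stage series
    by_arch: dict[str, dict[str, pd.DataFrame]] = {}
    for lib_id, prof in profiles.items():
        by_arch.setdefault(argonaute_of[lib_id], {})[stage_of[lib_id]] = prof
    plasticity_rows = []
    for arch_name, stage_profiles in by_arch.items():
        stages = [s for s in STAGES if s in stage_profiles]
        if len(stages) >= 2:
            ps = plasticity_summary(stage_profiles, arch_name, stages)
            for s, r, m in zip(ps.stages, ps.repeat_fraction, ps.mrna_fraction):
                plasticity_rows.append(
                    {"argonaute": arch_name, "stage": s,
                     "repeat_fraction": r, "mrna_fraction": m})
            summary.setdefault("switch_stage", {})[arch_name] = ps.switch_stage
    if plasticity_rows:
        pd.DataFrame(plasticity_rows).to_csv(
            os.path.join(cfg.out_dir, "plasticity.tsv"), sep="\t", index=False)

    # M6 target overlap across mRNA-targeting archetypes
    m6 = {argonaute_of[l]: target_sets[l] for l in target_sets
          if stage_of[l] == "M6"
          and argonaute_of[l] in ("CSR1_like", "NRDE3_like", "ALG4_like")}
    if len(m6) == 3:
        venn = venn_counts(m6)
        with open(os.path.join(cfg.out_dir, "venn_M6.tsv"), "w") as fh:
            for k, v in venn.items():
                fh.write(f"{k}\t{v}\n")
        summary["venn_M6"] = venn

    manifest = dict(summary)
    manifest["outputs"] = {
        name: _sha256(os.path.join(cfg.out_dir, name))
        for name in sorted(os.listdir(cfg.out_dir))
        if os.path.isfile(os.path.join(cfg.out_dir, name))
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
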