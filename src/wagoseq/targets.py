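"""High-confidence mRNA target calling, expression groups and metagene profiles.

A gene is a high-confidence target of an Argonaute in a stage when the
antisense small-RNA signal on its mature mRNA exceeds 10 rpkm (strictly
"over"); gene expression below 5 rpkm is treated as background.

Metagene profiles aggregate antisense read 5'-end positions along
length-normalized mature transcripts (default 50 bins, 5'->3'); the 5'-bias
ratio compares first-quintile to last-quintile mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, Library
from .placement import PlacementSet

TARGET_RPKM_THRESHOLD = 10.0
EXPRESSION_RPKM_THRESHOLD = 5.0
DEFAULT_BINS = 50
#: sentinel for an all-5' profile with zero mass in the last quintile
BIAS_RATIO_CAP = 1000.0


def antisense_gene_rpkm(
    placements: list[PlacementSet],
    library: Library,
    genes: list[GeneModel],
) -> pd.Series:
    """Antisense small-RNA rpkm per gene on mature-transcript coordinates.

    rpkm = weighted antisense reads / (mature length in kb x total mapped
    reads in millions); multimappers split fractionally across their
    antisense transcript hits.
    """
    lengths = {}
    for g in genes:
        if g.mature_length == 0:
            raise ValueError(f"gene {g.gene_id}: mature length 0")
        lengths[g.gene_id] = g.mature_length
    weighted = dict.fromkeys(lengths, 0.0)
    for ps in placements:
        anti = ps.antisense_transcript_hits()
        if not anti:
            continue
        w = library.reads[ps.read_index].count / len(anti)
        for gene_id, _offset, _ in anti:
            if gene_id in weighted:
                weighted[gene_id] += w
    m = library.total_mapped_reads / 1e6
    rpkm = {
        gid: weighted[gid] / (lengths[gid] / 1000 * m) for gid in lengths
    }
    return pd.Series(rpkm, name=library.library_id)


def call_targets(
    rpkm: pd.DataFrame, threshold: float = TARGET_RPKM_THRESHOLD
) -> dict[str, set[str]]:
    """Per-library high-confidence target sets (strictly over threshold)."""
    return {
        lib: set(rpkm.index[rpkm[lib] > threshold]) for lib in rpkm.columns
    }


def targets_any_stage(target_sets: dict[str, set[str]]) -> set[str]:
    """Genes targeted in at least one library/stage."""
    out: set[str] = set()
    for s in target_sets.values():
        out |= s
    return out


def expression_groups(
    expression: pd.DataFrame,
    all_stages: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "M6", "M7"),
    meiosis_stages: tuple[str, ...] = ("M5", "M6", "M7"),
    threshold: float = EXPRESSION_RPKM_THRESHOLD,
) -> pd.Series:
    """Assign genes to {constitutive, meiosis_specific, other}.

    constitutive: expressed (>= threshold rpkm) in every stage M1-M7;
    meiosis_specific: expressed in >= 1 of M5-M7 and in none of M1-M4.
    """
    missing = [s for s in all_stages if s not in expression.columns]
    if missing:
        raise ValueError(f"expression table missing stages: {missing}")
    expressed = expression[list(all_stages)] >= threshold
    early = [s for s in all_stages if s not in meiosis_stages]
    groups = pd.Series("other", index=expression.index, name="group")
    groups[expressed.all(axis=1)] = "constitutive"
    meiosis = expressed[list(meiosis_stages)].any(axis=1) & ~expressed[early].any(axis=1)
    groups[meiosis] = "meiosis_specific"
    return groups


@dataclass
class MetageneProfile:
    """Aggregate antisense read 5'-end density over binned mature transcripts."""

    label: str
    densities: np.ndarray  # length B, sums to 1 when any read contributed
    n_reads: float         # weighted read mass aggregated
    bins: int

    @property
    def five_prime_bias(self) -> float:
        """First-quintile over last-quintile mass; capped when the tail is 0."""
        q = self.bins // 5
        head = float(self.densities[:q].sum())
        tail = float(self.densities[-q:].sum())
        if tail == 0.0:
            return BIAS_RATIO_CAP if head > 0 else 1.0
        return head / tail


def metagene(
    placements: list[PlacementSet],
    library: Library,
    genes: list[GeneModel],
    gene_ids: set[str] | None = None,
    bins: int = DEFAULT_BINS,
    label: str = "aggregate",
) -> MetageneProfile:
    """Metagene profile of antisense reads over a gene set.

    Each antisense read contributes (fractionally for multimappers) at the
    transcript-coordinate position of its 5' end: for a read antisense to
    the mRNA covering mature positions [p, p+L), the read's 5' end sits at
    p + L - 1.
    """
    lengths = {g.gene_id: g.mature_length for g in genes}
    if gene_ids is None:
        gene_ids = set(lengths)
    gene_ids = {g for g in gene_ids if lengths.get(g, 0) >= bins}
    if not gene_ids:
        raise ValueError("empty gene set (or all genes shorter than bin count)")
    dens = np.zeros(bins, dtype=np.float64)
    mass = 0.0
    for ps in placements:
        anti = [h for h in ps.antisense_transcript_hits() if h[0] in gene_ids]
        if not anti:
            continue
        rec = library.reads[ps.read_index]
        w = rec.count / len(ps.antisense_transcript_hits())
        for gene_id, offset, _ in anti:
            pos5 = offset + rec.length - 1
            b = min(int(pos5 / lengths[gene_id] * bins), bins - 1)
            dens[b] += w
            mass += w
    if mass > 0:
        dens /= dens.sum()
    return MetageneProfile(label=label, densities=dens, n_reads=mass, bins=bins)


def target_fraction(targets: set[str], universe: set[str]) -> tuple[float, int]:
    """Percentage of the universe that is targeted: (exact pct, rounded)."""
    if not universe:
        raise ValueError("empty universe")
    pct = 100.0 * len(targets & universe) / len(universe)
    return pct, round(pct)
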