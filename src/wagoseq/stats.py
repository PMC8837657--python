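"""Library-level comparative summaries: Z-scores, PCA, Venn sets, plasticity.

The PCA here is a deterministic re-specification of the usual count-matrix
library PCA: values are log2(rpkm+1), the top n most-variable features are
kept, features are centered, and the decomposition is a plain SVD with
component signs fixed so the largest-magnitude feature loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import Category


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Standardize each feature row across libraries (population sd).

    Rows with zero variance are set to all-zero and returned in the flag
    list. A single-column matrix cannot be standardized for comparison.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-score needs >= 2 libraries")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out, [matrix.index[i] for i in flat]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # libraries x components
    variance_explained: np.ndarray   # percent per component
    features_used: list


def pca_libraries(
    rpkm: pd.DataFrame, n_top: int = 500, n_components: int = 2
) -> PCAResult:
    """PCA of libraries from a features x libraries rpkm matrix.

    Transform: log2(rpkm+1); keep the n_top most-variable features; center
    each feature; SVD on the libraries x features matrix. Variance
    percentages are over all retained dimensions, so they sum to 100.
    """
    n_libs = rpkm.shape[1]
    if n_libs < 3:
        raise ValueError("PCA needs >= 3 libraries")
    logged = np.log2(rpkm.to_numpy(dtype=float) + 1.0)
    variances = logged.var(axis=1, ddof=0)
    order = np.argsort(variances, kind="stable")[::-1][: min(n_top, len(variances))]
    order = np.sort(order)  # deterministic feature order
    X = logged[order, :].T                      # libraries x features
    X = X - X.mean(axis=0, keepdims=True)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} > max rank {max_rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| feature positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U[:, :n_components] * S[:n_components]
    var = S**2
    var_pct = 100.0 * var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=rpkm.columns, columns=cols),
        variance_explained=var_pct,
        features_used=[rpkm.index[i] for i in order],
    )


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Region cardinalities for 2 or 3 labelled sets.

    Keys are '+'-joined label combinations; region counts sum to |union|.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    labels = list(sets)
    out: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                *(sets[l] for l in labels if l not in combo), set()
            ) if len(combo) < len(labels) else set()
            out["+".join(combo)] = len(inside - outside)
    return out


@dataclass
class PlasticitySummary:
    """Per-stage read-mass fractions on repeats vs mRNAs for one Argonaute."""

    argonaute: str
    stages: list[str]
    repeat_fraction: list[float]
    mrna_fraction: list[float]
    switch_stage: str | None  # first stage where mRNA mass exceeds repeat mass

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "WAGO_repeats": self.repeat_fraction,
                "antisense_mRNA": self.mrna_fraction,
            },
            index=self.stages,
        )


def plasticity_summary(
    stage_profiles: dict[str, pd.DataFrame], argonaute: str,
    stages: list[str] | None = None,
) -> PlasticitySummary:
    """Repeat-vs-mRNA target fractions across a stage series.

    stage_profiles maps stage -> category_profile frame (counts+fractions).
    """
    if stages is None:
        stages = list(stage_profiles)
    missing = [s for s in stages if s not in stage_profiles]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    rep, mrna = [], []
    switch = None
    for s in stages:
        prof = stage_profiles[s]["fraction"]
        r = float(prof[Category.WAGO_repeats.name])
        m = float(prof[Category.antisense_mRNA.name])
        rep.append(r)
        mrna.append(m)
        if switch is None and m > r:
            switch = s
    return PlasticitySummary(
        argonaute=argonaute, stages=list(stages),
        repeat_fraction=rep, mrna_fraction=mrna, switch_stage=switch,
    )
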