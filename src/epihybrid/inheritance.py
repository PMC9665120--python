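"""Classification of hybrid methylation inheritance and profile clustering.

A differentially methylated cytosine (DMC) is *additive* when the hybrid
group's mean normalized count lies within the closed interval spanned by the
two parental group means (intermediate methylation), *overdominant* when it
exceeds the higher parental mean and *underdominant* when it falls below the
lower one.  Boundary equality counts as additive, because transgression is
defined strictly (and ties are measure-zero on continuous CPMs).

Which loci to classify is the caller's choice: the parental DMC set for the
"intermediate in hybrids" bookkeeping, or the set of DMCs common to both
hybrid-vs-parent comparisons for the transgressive bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import DataError
from .normalize import CpmMatrix

MODES = ("additive", "overdominant", "underdominant")


@dataclass
class InheritanceSummary:
    n_total: int
    n_additive: int
    n_overdominant: int
    n_underdominant: int
    pct_additive: float
    pct_overdominant: float
    pct_underdominant: float

    @property
    def n_nonadditive(self) -> int:
        return self.n_overdominant + self.n_underdominant

    @property
    def pct_nonadditive(self) -> float:
        return round(100.0 * self.n_nonadditive / self.n_total, 1)


def classify_inheritance(
    cpm: CpmMatrix,
    loci: Sequence[str],
    groups: tuple[str, str, str] = ("parent1", "parent2", "hybrid"),
) -> pd.DataFrame:
    """Classify each locus by where the hybrid mean CPM sits relative to the parents.

    Returns a DataFrame with columns locus_id, mean_cpm_p1, mean_cpm_p2,
    mean_cpm_hybrid, mode.  Invariant to swapping the two parental labels.
    """
    p1, p2, hyb = groups
    pos = {lid: i for i, lid in enumerate(cpm.locus_ids)}
    missing = [lid for lid in loci if lid not in pos]
    if missing:
        raise DataError(f"loci absent from the CPM matrix: {missing[:5]}")
    idx = np.array([pos[lid] for lid in loci], dtype=int)
    means = {}
    for g in groups:
        gi = cpm.group_index(g)
        if len(gi) == 0:
            raise DataError(f"group {g!r} has no samples")
        means[g] = cpm.values[np.ix_(idx, gi)].mean(axis=1)
    lo = np.minimum(means[p1], means[p2])
    hi = np.maximum(means[p1], means[p2])
    h = means[hyb]
    mode = np.where(h > hi, "overdominant", np.where(h < lo, "underdominant", "additive"))
    return pd.DataFrame(
        {
            "locus_id": list(loci),
            "mean_cpm_p1": means[p1],
            "mean_cpm_p2": means[p2],
            "mean_cpm_hybrid": h,
            "mode": mode,
        }
    )


def summarize_inheritance(calls: pd.DataFrame) -> InheritanceSummary:
    """Count and percentage bookkeeping over a table of inheritance calls."""
    if len(calls) == 0:
        raise DataError("cannot summarize an empty set of inheritance calls")
    n = len(calls)
    counts = calls["mode"].value_counts()
    n_add = int(counts.get("additive", 0))
    n_over = int(counts.get("overdominant", 0))
    n_under = int(counts.get("underdominant", 0))
    return InheritanceSummary(
        n_total=n,
        n_additive=n_add,
        n_overdominant=n_over,
        n_underdominant=n_under,
        pct_additive=round(100.0 * n_add / n, 1),
        pct_overdominant=round(100.0 * n_over / n, 1),
        pct_underdominant=round(100.0 * n_under / n, 1),
    )


def scale_profiles(cpm: CpmMatrix, loci: Sequence[str] | None = None) -> np.ndarray:
    """Per-locus z-scores of normalized counts across samples.

    Each row (locus) is centred to mean 0 and scaled to unit sample variance
    (ddof=1); zero-variance rows map to all zeros.
    """
    if len(cpm.samples) < 2:
        raise DataError("scaling needs at least two samples")
    x = cpm.values
    if loci is not None:
        pos = {lid: i for i, lid in enumerate(cpm.locus_ids)}
        x = x[np.array([pos[lid] for lid in loci], dtype=int), :]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    nz = (sd > 0).ravel()
    out[nz, :] = (x[nz, :] - mu[nz, :]) / sd[nz, :]
    return out


def hierarchical_cluster(scaled: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) clustering of samples on Euclidean distances of scaled profiles.

    ``scaled`` is loci x samples; returns a scipy linkage matrix over samples.
    """
    if scaled.shape[1] < 2:
        raise DataError("clustering needs at least two samples")
    d = pdist(scaled.T, metric="euclidean")
    return hierarchy.linkage(d, method="average")


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]}:0;"
    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"
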