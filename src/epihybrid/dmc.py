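"""Two-group differential methylation testing on msGBS counts.

The test is the classic exact conditional negative-binomial (NB) test for
two groups of count libraries: counts are brought to a common (mean) library
size, summed within each group, and the observed split of the per-locus total
between the groups is compared with its conditional NB distribution given the
total.  The two-sided p-value sums the probabilities of all splits no more
likely than the observed one (minimum-likelihood convention, ties included).
At dispersion 0 the conditional distribution is exactly binomial, which gives
a closed-form oracle for testing.

Because methylation at a cut site blocks digestion, *more* reads mean *less*
methylation: a positive log2 fold change of the focal group over the reference
is reported as hypomethylation in the focal group.

Dispersion is estimated by maximizing the NB conditional likelihood given
group totals (quantile-adjusted conditional maximum likelihood in spirit),
pooled across loci for the common value; per-locus estimates are shrunk
toward the common value by a fixed-weight convex combination, reflecting the
small group sizes typical of these designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, DataError
from .normalize import FilterSpec, cpm_normalize, filter_loci

_DISP_FLOOR = 1e-6  # below this the NB is numerically Poisson
_DISP_CEIL = 5.0


@dataclass
class DispersionEstimate:
    """Common and (shrunk) per-locus NB dispersions for one two-group comparison."""

    common: float
    per_locus: np.ndarray
    shrinkage_weight: float


@dataclass
class DmcSet:
    """Per-locus differential-methylation results for one ordered comparison.

    ``results`` columns: locus_id, scaffold, position, strand, logFC, p_value,
    q_value, significant, direction.  ``comparison`` is (focal, reference).
    """

    comparison: tuple[str, str]
    results: pd.DataFrame
    fdr_threshold: float = 0.01

    @property
    def significant_loci(self) -> list[str]:
        return self.results.loc[self.results["significant"], "locus_id"].tolist()


def _equalized_counts(m: CountMatrix) -> np.ndarray:
    """Counts rescaled to the mean library size (float matrix)."""
    libs = m.library_sizes
    return m.counts * (libs.mean() / libs)[np.newaxis, :]


def _cond_loglik(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-locus NB conditional log-likelihood of within-group counts given the group sum.

    ``y`` is loci x n integer counts for one group at equal library sizes.
    Terms constant in phi are dropped.  For n = 1 the conditional likelihood
    is degenerate and contributes 0.
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )


def estimate_dispersion(
    m: CountMatrix,
    groups: tuple[str, str],
    shrinkage_weight: float = 0.8,
) -> DispersionEstimate:
    """Estimate the common and per-locus NB dispersion from groupwise-centred counts."""
    if m.counts.sum() == 0:
        raise DataError("cannot estimate dispersion from an all-zero matrix")
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise DataError("shrinkage_weight must be in [0, 1]")
    eq = _equalized_counts(m)
    group_counts = []
    for g in dict.fromkeys(groups):
        idx = m.group_index(g)
        if len(idx) == 0:
            raise DataError(f"group {g!r} has no samples")
        group_counts.append(np.round(eq[:, idx]).astype(np.int64))

    def neg_total(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_cond_loglik(y, phi).sum() for y in group_counts)

    opt = minimize_scalar(
        neg_total,
        bounds=(np.log(_DISP_FLOOR), np.log(_DISP_CEIL)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    common = float(np.exp(opt.x))
    if common <= 2 * _DISP_FLOOR:
        common = 0.0

    # per-locus: vectorized grid argmax of the conditional likelihood
    grid = np.exp(np.linspace(np.log(_DISP_FLOOR), np.log(_DISP_CEIL), 80))
    ll = np.zeros((len(m.loci), len(grid)))
    for k, phi in enumerate(grid):
        ll[:, k] = sum(_cond_loglik(y, phi) for y in group_counts)
    best = grid[np.argmax(ll, axis=1)]
    best[best <= 2 * _DISP_FLOOR] = 0.0
    per_locus = shrinkage_weight * common + (1.0 - shrinkage_weight) * best
    return DispersionEstimate(
        common=common, per_locus=per_locus, shrinkage_weight=shrinkage_weight
    )


def _exact_conditional_p(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for observing ``s_a`` of ``total`` in group a.

    Conditional on the total, the split is binomial(total, n_a/(n_a+n_b)) at
    dispersion 0 and a conditional-NB ratio distribution otherwise.  The
    p-value sums probabilities of all splits whose probability does not
    exceed the observed one (small tolerance for ties).
    """
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi < _DISP_FLOOR:
        p_a = n_a / (n_a + n_b)
        logp = (
            gammaln(total + 1)
            - gammaln(s + 1)
            - gammaln(total - s + 1)
            + s * np.log(p_a)
            + (total - s) * np.log1p(-p_a)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logp = (
            gammaln(s + r_a)
            - gammaln(s + 1)
            + gammaln(total - s + r_b)
            - gammaln(total - s + 1)
        )
        logp -= logsumexp(logp)
    obs = logp[s_a]
    return float(min(1.0, np.exp(logp[logp <= obs + 1e-9]).sum()))


def dmc_test(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    disp: DispersionEstimate,
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """Exact conditional NB test of every locus, focal ``group_a`` vs reference ``group_b``.

    Returns a DataFrame with columns locus_id, p_value, logFC where
    logFC = log2((meanCPM_a + c) / (meanCPM_b + c)) with pseudo-count c.
    """
    idx_a, idx_b = m.group_index(group_a), m.group_index(group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise DataError(f"unknown or empty group in ({group_a!r}, {group_b!r})")
    eq = _equalized_counts(m)
    s_a = np.round(eq[:, idx_a].sum(axis=1)).astype(np.int64)
    s_b = np.round(eq[:, idx_b].sum(axis=1)).astype(np.int64)
    n_a, n_b = len(idx_a), len(idx_b)

    cpm = cpm_normalize(m)
    mean_a = cpm.values[:, idx_a].mean(axis=1)
    mean_b = cpm.values[:, idx_b].mean(axis=1)
    logfc = np.log2((mean_a + pseudo_cpm) / (mean_b + pseudo_cpm))

    phis = np.broadcast_to(np.asarray(disp.per_locus, dtype=float), (len(m.loci),))
    p = np.array(
        [
            _exact_conditional_p(int(sa), int(sa + sb), n_a, n_b, float(phi))
            for sa, sb, phi in zip(s_a, s_b, phis)
        ]
    )
    return pd.DataFrame({"locus_id": m.locus_ids, "p_value": p, "logFC": logfc})


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmcs(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.01,
    filter_spec: FilterSpec | None = None,
    shrinkage_weight: float = 0.8,
    pseudo_cpm: float = 0.5,
    logfc_direction_threshold: float = 0.0,
) -> DmcSet:
    """Filter, test, BH-adjust and threshold one comparison (focal vs reference).

    Filtering is applied per comparison with ``n`` defaulting to the smaller
    group's size.  Direction: logFC above the direction threshold (default 0,
    i.e. sign) means more reads, hence hypomethylation, in the focal group.
    """
    spec = filter_spec or FilterSpec()
    filt = filter_loci(m, spec, (group_a, group_b))
    if len(filt.loci) == 0:
        empty = pd.DataFrame(
            columns=[
                "locus_id", "scaffold", "position", "strand",
                "logFC", "p_value", "q_value", "significant", "direction",
            ]
        )
        return DmcSet((group_a, group_b), empty, fdr_threshold)
    disp = estimate_dispersion(filt, (group_a, group_b), shrinkage_weight)
    res = dmc_test(filt, group_a, group_b, disp, pseudo_cpm)
    q = bh_fdr(res["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "locus_id": res["locus_id"],
            "scaffold": [l.scaffold for l in filt.loci],
            "position": [l.position for l in filt.loci],
            "strand": [l.strand for l in filt.loci],
            "logFC": res["logFC"],
            "p_value": res["p_value"],
            "q_value": q,
            "significant": q < fdr_threshold,
            "direction": np.where(
                res["logFC"] > logfc_direction_threshold,
                "hypo_in_focal",
                "hyper_in_focal",
            ),
        }
    )
    return DmcSet((group_a, group_b), out, fdr_threshold)


def intersect_dmcs(a: DmcSet, b: DmcSet) -> list[str]:
    """Loci significant in both comparisons, ordered by scaffold then position."""
    sig_a = set(a.significant_loci)
    rows = b.results[b.results["significant"] & b.results["locus_id"].isin(sig_a)]
    rows = rows.sort_values(["scaffold", "position", "strand"], kind="mergesort")
    return rows["locus_id"].tolist()
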