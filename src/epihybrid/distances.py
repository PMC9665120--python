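"""Pairwise distances, classical MDS, Mantel test and the pairwise mixed model.

Genome-methylome comparisons work on per-individual distance matrices:
Euclidean distances of normalized methylation profiles for ordination,
Bray-Curtis dissimilarities of methylation CPMs and of SNP dosages for the
genome-vs-methylome analyses.  The association between the two distance
matrices is assessed with a permutation Mantel test, and with an MLPE-style
Gaussian mixed model of pairwise epigenetic distance (fixed effects: genetic
distance, sampling sites and species of the two pair members; crossed random
intercepts for each individual appearing in a pair, fitted by maximum
likelihood so AIC/likelihood-ratio model comparisons are valid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .datamodel import DataError, SampleInfo


@dataclass
class MdsResult:
    """Classical MDS embedding: coordinates, eigenvalues, and which axes are real."""

    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all n, descending
    axis_real: np.ndarray  # bool per returned axis; False = zero-padded beyond rank
    sample_ids: list[str]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    alternative: str = "greater"


@dataclass
class PairwiseModelFit:
    """ML fit of the pairwise epigenetic-distance mixed model, with a no-random-effect reference."""

    coefficients: dict[str, float]
    variance_components: dict[str, float]
    log_likelihood: float
    aic: float
    aic_no_random: float
    converged: bool

    @property
    def delta_aic(self) -> float:
        """AIC(no random effects) - AIC(mixed); positive favours the mixed model."""
        return self.aic_no_random - self.aic


def euclidean_distances(x: np.ndarray, sample_ids: Sequence[str]) -> DistanceMatrix:
    """L2 distances between rows (samples) of ``x``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("Euclidean distances require complete (non-missing) data")
    return DistanceMatrix(squareform(pdist(x, metric="euclidean")), ids=list(sample_ids))


def bray_curtis_distances(
    x: np.ndarray,
    sample_ids: Sequence[str],
    pairwise_deletion: bool = False,
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a non-negative samples x features matrix.

    d(u, v) = sum|u_i - v_i| / sum(u_i + v_i) over features observed in both
    samples (NaNs allowed only with ``pairwise_deletion=True``); two all-zero
    vectors are at distance 0.
    """
    x = np.asarray(x, dtype=float)
    if np.nanmin(x) < 0 if x.size else False:
        raise DataError("Bray-Curtis requires non-negative features")
    if not pairwise_deletion and np.any(np.isnan(x)):
        raise DataError("missing values present; use pairwise_deletion=True")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u, v = x[i], x[j]
            ok = np.isfinite(u) & np.isfinite(v)
            num = np.abs(u[ok] - v[ok]).sum()
            den = (u[ok] + v[ok]).sum()
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(d, ids=list(sample_ids))


def classical_mds(d: DistanceMatrix, k: int) -> MdsResult:
    """Classical (Torgerson) MDS: eigendecomposition of the double-centred Gram matrix.

    Coordinates are ordered by descending eigenvalue; each axis's sign is
    fixed so the largest-magnitude loading is positive.  Axes requested
    beyond the number of positive eigenvalues are zero-padded and flagged.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals.max(), 0.0) * 1e-10 if n else 0.0
    n_pos = int(np.sum(evals > tol))
    coords = np.zeros((n, k))
    axis_real = np.zeros(k, dtype=bool)
    for a in range(min(k, n_pos)):
        axis = evecs[:, a] * np.sqrt(evals[a])
        i = int(np.argmax(np.abs(axis)))
        if axis[i] < 0:
            axis = -axis
        coords[:, a] = axis
        axis_real[a] = True
    return MdsResult(
        coordinates=coords, eigenvalues=evals, axis_real=axis_real, sample_ids=list(d.ids)
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel test of the Pearson correlation between two distance matrices.

    Samples of ``d2`` are relabelled jointly on rows and columns.  The
    one-tailed p (default, positive association) is
    (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    if list(d1.ids) != list(d2.ids):
        raise DataError("distance matrices must share the same samples in the same order")
    if alternative not in ("greater", "two-sided"):
        raise DataError(f"unknown alternative {alternative!r}")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = d1.data[iu]
    v2 = d2.data[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise DataError("degenerate (constant) distance matrix")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(v1, v2)
    rng = np.random.default_rng(seed)
    count = 0
    m2 = d2.data
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2p = m2[np.ix_(perm, perm)][iu]
        r_perm = corr(v1, v2p)
        if alternative == "greater":
            hit = r_perm >= r_obs - 1e-12
        else:
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        count += int(hit)
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p_value=p, n_permutations=n_permutations, seed=seed, alternative=alternative
    )


def _pair_table(
    epi_d: DistanceMatrix, gen_d: DistanceMatrix, samples: Sequence[SampleInfo]
) -> pd.DataFrame:
    ids = [s.sample_id for s in samples]
    if list(epi_d.ids) != ids or list(gen_d.ids) != ids:
        raise DataError("distance matrices must be aligned with the sample list")
    rows = []
    # slot 1/2 of each unordered pair fixed by the sample-list ordering
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                {
                    "epi": epi_d.data[i, j],
                    "gen": gen_d.data[i, j],
                    "site1": samples[i].site,
                    "site2": samples[j].site,
                    "species1": samples[i].group,
                    "species2": samples[j].group,
                    "c1": ids[i],
                    "c2": ids[j],
                }
            )
    return pd.DataFrame(rows)


def fit_pairwise_mixed_model(
    epi_d: DistanceMatrix,
    gen_d: DistanceMatrix,
    samples: Sequence[SampleInfo],
) -> PairwiseModelFit:
    """Fit epigenetic pairwise distance on genetic distance with crossed individual intercepts.

    Model: epi ~ gen + site1 + site2 + species1 + species2 + (1|individual 1)
    + (1|individual 2), Gaussian, maximum likelihood.  Categorical terms with
    a single observed level are dropped (they are unidentifiable).  The fit
    of the fixed-effects-only model (OLS) is returned alongside for AIC
    comparison.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _pair_table(epi_d, gen_d, samples)
    if df["gen"].std() == 0:
        raise DataError("genetic distances are constant; slope is unidentifiable")
    terms = ["gen"]
    for col in ("site1", "site2", "species1", "species2"):
        if df[col].nunique() > 1:
            terms.append(f"C({col})")
    formula = "epi ~ " + " + ".join(terms)
    df["_grp"] = "all"
    vc = {"c1": "0 + C(c1)", "c2": "0 + C(c2)"}
    model = sm.MixedLM.from_formula(
        formula, groups="_grp", vc_formula=vc, re_formula="0", data=df
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            converged = bool(getattr(res, "converged", True))
        except Exception as err:  # non-convergence surfaces as a flagged result
            raise DataError(f"mixed-model fit failed: {err}") from err
    ols = smf.ols(formula, data=df).fit()
    vc_names = list(vc.keys())
    vcomp = {name: float(v) for name, v in zip(vc_names, np.atleast_1d(res.vcomp))}
    return PairwiseModelFit(
        coefficients={k: float(v) for k, v in res.fe_params.items()},
        variance_components=vcomp,
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        aic_no_random=float(ols.aic),
        converged=converged,
    )
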