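import numpy as np
import pytest
from scipy.stats import binom

from epihybrid.datamodel import DataError
from epihybrid.dmc import (
    DispersionEstimate,
    DmcSet,
    bh_fdr,
    call_dmcs,
    dmc_test,
    estimate_dispersion,
    intersect_dmcs,
)
from conftest import make_counts

POISSON_DISP = DispersionEstimate(common=0.0, per_locus=np.array(0.0), shrinkage_weight=0.8)


def two_sided_binomial_oracle(s_a: int, total: int, p: float) -> float:
    """Independent minimum-likelihood two-sided binomial p-value."""
    pmf = binom.pmf(np.arange(total + 1), total, p)
    return float(min(1.0, pmf[pmf <= pmf[s_a] * (1 + 1e-9)].sum()))


class TestExactTest:
    def test_one_vs_one_extreme_split(self):
        m = make_counts([[0, 10]], groups=["hybrid", "parent1"])
        res = dmc_test(m, "hybrid", "parent1", POISSON_DISP)
        assert res["p_value"][0] == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_balanced_split_is_null(self):
        m = make_counts([[5, 5]], groups=["hybrid", "parent1"])
        res = dmc_test(m, "hybrid", "parent1", POISSON_DISP)
        assert res["p_value"][0] == pytest.approx(1.0)

    def test_identical_groups_zero_logfc(self):
        counts = np.tile([[4], [9], [0]], (1, 4))
        m = make_counts(counts, groups=["hybrid", "hybrid", "parent1", "parent1"])
        res = dmc_test(m, "hybrid", "parent1", POISSON_DISP)
        assert np.allclose(res["logFC"], 0.0)

    def test_matches_binomial_tail_sums_on_enumerated_grid(self):
        """At dispersion 0 the conditional NB test is exactly binomial."""
        for n_a, n_b in [(1, 1), (2, 1), (2, 3)]:
            for total in range(0, 51, 5):
                splits = list(range(total + 1))
                counts = np.zeros((len(splits), n_a + n_b), dtype=int)
                counts[:, 0] = splits
                counts[:, n_a] = [total - s for s in splits]
                m = make_counts(counts, groups=["hybrid"] * n_a + ["parent1"] * n_b)
                res = dmc_test(m, "hybrid", "parent1", POISSON_DISP)
                p_frac = n_a / (n_a + n_b)
                for s, p in zip(splits, res["p_value"]):
                    assert p == pytest.approx(
                        two_sided_binomial_oracle(s, total, p_frac), abs=1e-12
                    )

    def test_label_swap_preserves_p_and_flips_logfc(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(30, size=(50, 8))
        m = make_counts(counts, groups=["hybrid"] * 4 + ["parent1"] * 4)
        disp = estimate_dispersion(m, ("hybrid", "parent1"))
        a = dmc_test(m, "hybrid", "parent1", disp)
        b = dmc_test(m, "parent1", "hybrid", disp)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-12)
        assert np.allclose(a["logFC"], -b["logFC"], atol=1e-12)

    def test_unknown_group_rejected(self, toy_matrix):
        with pytest.raises(DataError):
            dmc_test(toy_matrix, "parent1", "hybrid", POISSON_DISP)


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self):
        rng = np.random.default_rng(11)
        mu = rng.lognormal(np.log(40), 0.7, size=200)
        counts = rng.poisson(mu[:, None], size=(200, 20))
        m = make_counts(counts, groups=["parent1"] * 10 + ["parent2"] * 10)
        est = estimate_dispersion(m, ("parent1", "parent2"))
        assert est.common < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(12)
        phi = 0.4
        mu = rng.lognormal(np.log(50), 0.7, size=500)
        lam = rng.gamma(1 / phi, scale=mu[:, None] * phi, size=(500, 16))
        counts = rng.poisson(lam)
        m = make_counts(counts, groups=["parent1"] * 8 + ["parent2"] * 8)
        est = estimate_dispersion(m, ("parent1", "parent2"))
        assert 0.2 <= est.common <= 0.6

    def test_constant_counts_give_zero_per_locus(self):
        m = make_counts([[7, 7, 7, 7]], groups=["parent1"] * 2 + ["parent2"] * 2)
        est = estimate_dispersion(m, ("parent1", "parent2"))
        assert est.per_locus[0] == pytest.approx(0.0, abs=est.shrinkage_weight * est.common + 1e-9)

    def test_all_zero_matrix_rejected(self):
        m = make_counts([[0, 0]], groups=["parent1", "parent2"])
        with pytest.raises(DataError):
            estimate_dispersion(m, ("parent1", "parent2"))


class TestBhFdr:
    def test_equal_adjusted_values_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_of_one(self):
        assert bh_fdr(np.array([1.0]))[0] == pytest.approx(1.0)

    def test_bounds_and_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        perm = rng.permutation(100)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr(np.array([0.5, 1.2]))


class TestCallDmcs:
    def test_power_and_size_on_planted_shifts(self):
        """100 null loci + 20 with an 8-fold group shift: most shifted loci called, few nulls."""
        rng = np.random.default_rng(21)
        phi = 0.1
        n_null, n_shift = 100, 20

        def nb(mean, size):
            lam = rng.gamma(1 / phi, scale=np.asarray(mean) * phi, size=size)
            return rng.poisson(lam)

        mu_null = rng.lognormal(np.log(60), 0.4, n_null)
        null = nb(mu_null[:, None], (n_null, 20))
        mu_a = rng.lognormal(np.log(60), 0.4, n_shift)
        shifted = np.hstack(
            [nb(mu_a[:, None] * 8, (n_shift, 10)), nb(mu_a[:, None], (n_shift, 10))]
        )
        m = make_counts(
            np.vstack([null, shifted]), groups=["parent1"] * 10 + ["parent2"] * 10
        )
        ds = call_dmcs(m, "parent1", "parent2", fdr_threshold=0.01)
        sig = ds.results.set_index("locus_id")["significant"]
        shifted_ids = m.locus_ids[n_null:]
        null_ids = m.locus_ids[:n_null]
        n_hit = sum(bool(sig.get(l, False)) for l in shifted_ids)
        n_false = sum(bool(sig.get(l, False)) for l in null_ids)
        assert n_hit >= 15
        assert n_false <= 3

    def test_same_group_both_sides_yields_nothing(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(50, size=(60, 6))
        m = make_counts(counts, groups=["parent1"] * 6)
        ds = call_dmcs(m, "parent1", "parent1")
        assert int(ds.results["significant"].sum()) == 0

    def test_direction_follows_logfc_sign(self):
        m = make_counts(
            [[400, 400, 2, 2], [2, 2, 400, 400]],
            groups=["hybrid", "hybrid", "parent1", "parent1"],
        )
        ds = call_dmcs(m, "hybrid", "parent1", filter_spec=None)
        res = ds.results.set_index("locus_id")
        assert res.iloc[0]["direction"] == "hypo_in_focal"
        assert res.iloc[1]["direction"] == "hyper_in_focal"


class TestIntersect:
    def _dmcset(self, sig_ids, all_ids):
        import pandas as pd

        df = pd.DataFrame(
            {
                "locus_id": all_ids,
                "scaffold": ["sc1"] * len(all_ids),
                "position": range(1, len(all_ids) + 1),
                "strand": ["+"] * len(all_ids),
                "significant": [l in sig_ids for l in all_ids],
            }
        )
        return DmcSet(("hybrid", "parent1"), df)

    def test_overlap_order_and_identity(self):
        ids = ["L1", "L2", "L3", "L4"]
        a = self._dmcset({"L1", "L2", "L3"}, ids)
        b = self._dmcset({"L2", "L3", "L4"}, ids)
        assert intersect_dmcs(a, b) == ["L2", "L3"]
        assert intersect_dmcs(a, self._dmcset(set(), ids)) == []
        assert intersect_dmcs(a, a) == ["L1", "L2", "L3"]
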