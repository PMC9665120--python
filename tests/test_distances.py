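import numpy as np
import pytest
from scipy.spatial.distance import braycurtis, pdist
from skbio import DistanceMatrix

from epihybrid.datamodel import DataError, SampleInfo
from epihybrid.distances import (
    bray_curtis_distances,
    classical_mds,
    euclidean_distances,
    fit_pairwise_mixed_model,
    mantel_test,
)


def ids(n):
    return [f"s{i}" for i in range(n)]


class TestEuclidean:
    def test_three_four_five_and_identity(self):
        d = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]]), ids(3))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 2] == pytest.approx(0.0)

    def test_triangle_inequality_on_random_data(self):
        rng = np.random.default_rng(1)
        d = euclidean_distances(rng.normal(size=(6, 4)), ids(6)).data
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_values_rejected(self):
        x = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(DataError):
            euclidean_distances(x, ids(2))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 1.0),
            ([2.0, 2.0], [1.0, 1.0], 1.0 / 3.0),
        ],
    )
    def test_definitional_values(self, u, v, expected):
        d = bray_curtis_distances(np.array([u, v]), ids(2))
        assert d[0, 1] == pytest.approx(expected)

    def test_matches_scipy_on_complete_data(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 1.0, size=(5, 30))
        d = bray_curtis_distances(x, ids(5)).data
        for i in range(5):
            for j in range(i + 1, 5):
                assert d[i, j] == pytest.approx(braycurtis(x[i], x[j]), abs=1e-12)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(8)
        x = rng.gamma(1.0, 1.0, size=(6, 20))
        d = bray_curtis_distances(x, ids(6)).data
        assert np.all(d >= 0) and np.all(d <= 1 + 1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_pairwise_deletion_ignores_missing_markers(self):
        x = np.array([[1.0, np.nan, 4.0], [1.0, 9.0, 2.0]])
        d = bray_curtis_distances(x, ids(2), pairwise_deletion=True)
        assert d[0, 1] == pytest.approx(2.0 / 8.0)  # only markers 0 and 2 used

    def test_all_zero_pair_is_distance_zero(self):
        d = bray_curtis_distances(np.zeros((2, 5)), ids(2))
        assert d[0, 1] == 0.0

    def test_negative_feature_rejected(self):
        with pytest.raises(DataError):
            bray_curtis_distances(np.array([[1.0, -2.0], [0.0, 1.0]]), ids(2))


class TestClassicalMds:
    def test_collinear_points_recover_exactly_in_one_dimension(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = euclidean_distances(pts, ids(3))
        res = classical_mds(d, k=1)
        assert np.abs(pdist(res.coordinates) - pdist(pts)).max() < 1e-9

    def test_duplicated_sample_gets_identical_coordinates(self):
        pts = np.array([[0.0, 0.0], [2.0, 1.0], [2.0, 1.0], [5.0, -1.0]])
        res = classical_mds(euclidean_distances(pts, ids(4)), k=2)
        assert np.allclose(res.coordinates[1], res.coordinates[2], atol=1e-9)

    def test_full_rank_embedding_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = euclidean_distances(pts, ids(8))
        res = classical_mds(d, k=3)
        assert np.abs(pdist(res.coordinates) - pdist(pts)).max() < 1e-9

    def test_axes_beyond_rank_padded_and_flagged(self):
        pts = np.array([[0.0], [1.0], [4.0]])
        res = classical_mds(euclidean_distances(pts, ids(3)), k=3)
        assert res.axis_real[0] and not res.axis_real[2]
        assert np.allclose(res.coordinates[:, 2], 0.0)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        res = classical_mds(euclidean_distances(pts, ids(7)), k=2)
        for a in range(2):
            axis = res.coordinates[:, a]
            assert axis[np.argmax(np.abs(axis))] > 0

    def test_agrees_with_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 4))
        d = euclidean_distances(pts, ids(9))
        ours = classical_mds(d, k=2).coordinates
        ref = pcoa(d, number_of_dimensions=2).samples.to_numpy()
        for a in range(2):
            assert np.allclose(np.abs(ours[:, a]), np.abs(ref[:, a]), atol=1e-8)


class TestMantel:
    def test_identical_matrices_give_r_one_minimal_p(self):
        rng = np.random.default_rng(6)
        d = euclidean_distances(rng.normal(size=(8, 3)), ids(8))
        res = mantel_test(d, d, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        d = euclidean_distances(rng.normal(size=(7, 3)), ids(7))
        d2 = DistanceMatrix(2.0 * d.data, ids(7))
        assert mantel_test(d, d2, n_permutations=49, seed=0).r == pytest.approx(1.0)

    def test_agrees_with_skbio_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(8)
        d1 = euclidean_distances(rng.normal(size=(10, 3)), ids(10))
        d2 = euclidean_distances(rng.normal(size=(10, 3)), ids(10))
        ours = mantel_test(d1, d2, n_permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(9)
        d1 = euclidean_distances(rng.normal(size=(5, 2)), ids(5))
        d2 = euclidean_distances(rng.normal(size=(5, 2)), ["x0", "x1", "x2", "x3", "x4"])
        with pytest.raises(DataError):
            mantel_test(d1, d2)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        d1 = euclidean_distances(rng.normal(size=(8, 2)), ids(8))
        d2 = euclidean_distances(rng.normal(size=(8, 2)), ids(8))
        a = mantel_test(d1, d2, n_permutations=199, seed=5)
        b = mantel_test(d1, d2, n_permutations=199, seed=5)
        assert a.p_value == b.p_value


def _simulate_mlpe(seed, n=30, slope=0.5, id_sd=0.2, resid_sd=0.1):
    rng = np.random.default_rng(seed)
    sample_ids = ids(n)
    coords = rng.normal(size=(n, 2))
    gen = euclidean_distances(coords, sample_ids)
    a = rng.normal(0, id_sd, n)
    epi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            epi[i, j] = epi[j, i] = abs(
                1.0 + slope * gen.data[i, j] + a[i] + a[j] + rng.normal(0, resid_sd)
            )
    groups = ["parent1", "parent2", "hybrid"]
    sinfo = [
        SampleInfo(sample_ids[k], groups[k % 3], ["GUA", "FUN"][k % 2], 1_000_000)
        for k in range(n)
    ]
    return DistanceMatrix(epi, sample_ids), gen, sinfo


class TestPairwiseMixedModel:
    def test_slope_and_individual_variance_recovered(self):
        epi, gen, sinfo = _simulate_mlpe(seed=1)
        fit = fit_pairwise_mixed_model(epi, gen, sinfo)
        assert 0.35 <= fit.coefficients["gen"] <= 0.65
        assert all(v > 0 for v in fit.variance_components.values())
        assert fit.delta_aic > 0  # random effects favoured when they exist

    def test_aic_prefers_no_random_effects_when_absent(self):
        prefer_ols = 0
        n_rep = 10
        for seed in range(n_rep):
            epi, gen, sinfo = _simulate_mlpe(seed=100 + seed, id_sd=0.0)
            fit = fit_pairwise_mixed_model(epi, gen, sinfo)
            prefer_ols += int(fit.aic_no_random <= fit.aic)
        assert prefer_ols >= n_rep // 2

    def test_constant_genetic_distance_rejected(self):
        epi, gen, sinfo = _simulate_mlpe(seed=2, n=10)
        const = DistanceMatrix(
            np.ones((10, 10)) - np.eye(10), list(gen.ids)
        )
        with pytest.raises(DataError):
            fit_pairwise_mixed_model(epi, const, sinfo)
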