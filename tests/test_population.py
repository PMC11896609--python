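import numpy as np
import pandas as pd
import pytest

from alsim.population import (
    LinearPreferenceModel,
    PN_PC2_OCT_MCH_MODEL,
    apply_preference_model,
    classify_individuals,
    glomerular_organization_index,
    impute_and_average,
    pca_responses,
    response_distances,
)


def _trial_table(values, individuals, trials):
    cols = [f"g{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "individual", individuals)
    df.insert(1, "trial", trials)
    return df


class TestImputeAndAverage:
    def test_trial_averaging(self):
        tab = _trial_table(np.array([[1.0, 2.0], [3.0, 4.0], [10.0, 10.0]]),
                           ["a", "a", "b"], [0, 1, 0])
        out = impute_and_average(tab)
        assert out.loc["a"].tolist() == [2.0, 3.0]
        assert out.loc["b"].tolist() == [10.0, 10.0]

    def test_mean_imputation(self):
        tab = _trial_table(np.array([[1.0, 5.0], [3.0, np.nan], [np.nan, 7.0]]),
                           ["a", "b", "c"], [0, 0, 0])
        out = impute_and_average(tab)
        assert out.loc["b", "g1"] == pytest.approx(6.0)  # mean of {5, 7}
        assert out.loc["c", "g0"] == pytest.approx(2.0)  # mean of {1, 3}

    def test_feature_missing_everywhere_raises(self):
        tab = _trial_table(np.array([[1.0, np.nan], [2.0, np.nan]]), ["a", "b"], [0, 0])
        with pytest.raises(ValueError, match="missing"):
            impute_and_average(tab)

    def test_mean_imputation_close_to_als_on_low_rank_table(self):
        # cross-check against alternating-least-squares completion
        from alsim.odor_drive import impute_missing_responses

        rng = np.random.default_rng(0)
        u, v = rng.random(8), rng.random(6)
        X = np.outer(u, v) * 0.8 + 0.1
        X_miss = X.copy()
        X_miss[1, 2] = np.nan
        als = impute_missing_responses(pd.DataFrame(X_miss), n_repeats=20, seed=0)
        tab = _trial_table(X_miss, [f"i{k}" for k in range(8)], [0] * 8)
        mean_filled = impute_and_average(tab)
        assert abs(als.iloc[1, 2] - mean_filled.iloc[1, 2]) < 0.25


class TestPCA:
    def test_rank1_matrix_single_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.random(10), rng.random(4))
        res = pca_responses(X)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = rng.random((4, 6))
        res = pca_responses(X)
        C = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1][: len(res.variance_fraction)]
        assert np.allclose(res.variance_fraction, eig / eig.sum(), atol=1e-9)
        # loadings are orthonormal and reconstruction is exact
        assert np.allclose(res.loadings @ res.loadings.T, np.eye(res.loadings.shape[0]), atol=1e-9)
        recon = res.scores @ res.loadings + res.mean
        assert np.allclose(recon, X, atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = pca_responses(rng.random((12, 7)))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((9, 5))
        res = pca_responses(X)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError):
            pca_responses(np.ones((5, 3)))


class TestGOI:
    def _pca_like(self, loadings, var=None):
        from alsim.population import PCAResult

        L = np.atleast_2d(loadings)
        v = np.ones(L.shape[0]) / L.shape[0] if var is None else np.asarray(var)
        return PCAResult(loadings=L, scores=np.zeros((2, L.shape[0])), variance_fraction=v)

    def test_constant_within_glomeruli_is_one(self):
        l = np.array([0.5, 0.5, -0.2, -0.2, 0.7, 0.7])
        blocks = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        assert glomerular_organization_index(self._pca_like(l), blocks, 1) == pytest.approx(1.0)

    def test_zero_mean_within_glomeruli_is_zero(self):
        l = np.array([0.5, -0.5, 0.3, -0.3, 0.1, -0.1])
        blocks = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        assert glomerular_organization_index(self._pca_like(l), blocks, 1) == pytest.approx(0.0)

    def test_iid_loadings_expectation_is_one_over_odors(self):
        rng = np.random.default_rng(0)
        n_glom, n_odor = 6, 5
        blocks = [np.arange(g * n_odor, (g + 1) * n_odor) for g in range(n_glom)]
        vals = [
            glomerular_organization_index(
                self._pca_like(rng.standard_normal(n_glom * n_odor)), blocks, 1
            )
            for _ in range(1000)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1 / n_odor) < 3 * se

    def test_invariances(self):
        rng = np.random.default_rng(1)
        n_odor = 4
        l = rng.standard_normal(12)
        blocks = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        base = glomerular_organization_index(self._pca_like(l), blocks, 1)
        flipped = glomerular_organization_index(self._pca_like(-l), blocks, 1)
        assert flipped == pytest.approx(base)
        perm = l.copy()
        perm[0:4] = perm[[2, 0, 3, 1]]  # permute odors within one glomerulus
        assert glomerular_organization_index(self._pca_like(perm), blocks, 1) == pytest.approx(base)

    def test_empty_block_raises(self):
        with pytest.raises(ValueError):
            glomerular_organization_index(self._pca_like(np.ones(4)), [np.array([], dtype=int)], 1)


class TestPreferenceModel:
    def test_pn_pc2_model_values(self):
        assert apply_preference_model(PN_PC2_OCT_MCH_MODEL, 0.0) == pytest.approx(-0.058)
        assert apply_preference_model(PN_PC2_OCT_MCH_MODEL, 1.0) == pytest.approx(-0.139)

    def test_zero_slope_constant(self):
        m = LinearPreferenceModel(beta0=0.3, beta1=0.0)
        assert np.allclose(apply_preference_model(m, np.linspace(-5, 5, 7)), 0.3)

    def test_affine_in_scores(self):
        m = PN_PC2_OCT_MCH_MODEL
        s = np.array([-1.0, 0.5, 2.0])
        pred = apply_preference_model(m, s)
        assert np.allclose(np.diff(pred), m.beta1 * np.diff(s))


class TestClassifier:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        assert classify_individuals(X, y, seed=1) == 1.0

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        accs = [
            classify_individuals(X, rng.permutation(y), seed=s) for s in range(200)
        ]
        sd = np.sqrt(0.25 / 40)  # binomial SD of an accuracy at chance
        assert abs(np.mean(accs) - 0.5) < 3 * sd

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classify_individuals(np.random.rand(10, 2), np.zeros(10), seed=0)

    def test_fold_sizes_balanced(self):
        from alsim.population import _two_folds

        rng = np.random.default_rng(2)
        for n0, n1 in [(10, 11), (7, 4), (3, 3)]:
            y = np.array([0] * n0 + [1] * n1)
            a, b = _two_folds(len(y), y, rng)
            assert abs(len(a) - len(b)) <= 1
            assert sorted(np.concatenate([a, b])) == list(range(len(y)))


class TestResponseDistances:
    def test_identical_trials_zero_within(self):
        tab = pd.DataFrame(
            {"individual": ["a", "a", "b", "b"], "hemisphere": ["L", "R", "L", "R"],
             "x": [1.0, 1.0, 5.0, 5.0], "y": [0.0, 0.0, 1.0, 1.0]}
        )
        out = response_distances(tab)
        assert out["within"].max() == pytest.approx(0.0)
        assert (out["across"] > 0).all()

    def test_across_exceeds_within_for_separated_individuals(self):
        rng = np.random.default_rng(0)
        rows = []
        for k, center in enumerate([0.0, 10.0, 20.0]):
            for t in range(4):
                rows.append({"individual": f"i{k}", "hemisphere": "L" if t % 2 else "R",
                             "x": center + 0.01 * rng.standard_normal()})
        out = response_distances(pd.DataFrame(rows))
        assert (out["across"] > out["within"]).all()

    def test_ratio_grows_with_individual_spread(self):
        def ratio(sigma_i):
            rng = np.random.default_rng(5)
            rows = []
            for k in range(8):
                c = sigma_i * rng.standard_normal()
                for t in range(4):
                    rows.append({"individual": f"i{k}", "hemisphere": "L" if t % 2 else "R",
                                 "x": c + 0.1 * rng.standard_normal()})
            out = response_distances(pd.DataFrame(rows))
            return out["across"].mean() / out["within"].mean()

        assert ratio(5.0) > ratio(0.5) > ratio(0.05)
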