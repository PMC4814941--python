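import numpy as np
import pytest
from sklearn.linear_model import Lasso

from pulsedx.errors import PulseError
from pulsedx.models import (classify_by_index, design_regressand,
                            efbls_select, format_model_equation, lasso_cv,
                            lasso_fit, lasso_lambda_max, lasso_path,
                            pca_classify, regressand_for_labels,
                            repeated_rounds_report, separation_pvalue,
                            standardize, threshold_search)


# --- standardization --------------------------------------------------------

class TestStandardize:
    def test_constant_column_flagged_and_centered(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.0
        Z, st = standardize(X)
        assert st.flagged[1] and not st.flagged[0]
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z[:, 1], 0.0)

    def test_standardize_twice_is_identity_on_moments(self, rng):
        Z, _ = standardize(rng.normal(2.0, 5.0, size=(50, 4)))
        Z2, st2 = standardize(Z)
        np.testing.assert_allclose(st2.centers, 0.0, atol=1e-12)
        np.testing.assert_allclose(st2.scales, 1.0, atol=1e-12)

    def test_heldout_rows_use_training_moments(self, rng):
        Xtr = rng.normal(0.0, 1.0, size=(30, 2))
        Xte = rng.normal(3.0, 1.0, size=(10, 2))
        _, st = standardize(Xtr)
        Zte = st.transform(Xte)
        assert Zte.mean() > 1.0  # group shift survives; self-scaling would hide it


# --- designed regressand ----------------------------------------------------

@pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (98, 38)])
def test_designed_regressand_values_and_zero_sum(n1, n2):
    y = design_regressand(n1, n2)
    assert len(y) == n1 + n2
    assert set(y) == {float(n2), float(-n1)}
    assert y[:n1].tolist() == [n2] * n1
    assert y.sum() == 0.0


def test_designed_regressand_rejects_tiny_group():
    with pytest.raises(PulseError):
        design_regressand(1, 10)


def test_row_aligned_regressand(rng):
    labels = np.array(["a", "b", "a", "b", "b"])
    y = regressand_for_labels(labels, "a", "b")
    np.testing.assert_array_equal(y, [3, -2, 3, -2, -2])
    assert y.sum() == 0.0


# --- EFBLS ------------------------------------------------------------------

class TestEfbls:
    def test_exact_single_predictor_found_and_stops(self, rng):
        Z, _ = standardize(rng.normal(size=(60, 40)))
        y = 2.0 * Z[:, 17]
        res = efbls_select(Z, y)
        assert res.features == [17]
        assert res.rss < 1e-12

    def test_planted_three_feature_signal_recovered(self, rng):
        Z, _ = standardize(rng.normal(size=(120, 193)))
        planted = [5, 77, 150]
        y = 3 * Z[:, 5] - 2 * Z[:, 77] + 2.5 * Z[:, 150] \
            + 0.1 * rng.normal(size=120)
        res = efbls_select(Z, y)
        assert set(planted) <= set(res.features)

    def test_noise_never_exceeds_cap(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 193)))
        for _ in range(3):
            y = rng.normal(size=40)
            res = efbls_select(Z, y, k_max=7)
            assert len(res.features) <= 7

    def test_rss_path_non_increasing(self, rng):
        Z, _ = standardize(rng.normal(size=(50, 30)))
        y = Z[:, 3] + rng.normal(size=50)
        res = efbls_select(Z, y)
        assert all(a >= b - 1e-9 for a, b in zip(res.rss_path, res.rss_path[1:]))

    def test_cap_above_seven_rejected(self, rng):
        Z = rng.normal(size=(30, 10))
        with pytest.raises(PulseError):
            efbls_select(Z, np.ones(30), k_max=8)

    def test_duplicate_columns_do_not_break_selection(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 6)))
        Z = np.column_stack([Z, Z[:, 0]])  # exact duplicate
        y = Z[:, 0] + 0.01 * rng.normal(size=40)
        res = efbls_select(Z, y)
        assert 0 in res.features or 6 in res.features
        assert not (0 in res.features and 6 in res.features)


# --- LASSO ------------------------------------------------------------------

class TestLasso:
    def test_zero_above_lambda_max(self, rng):
        Z, _ = standardize(rng.normal(size=(30, 8)))
        y = rng.normal(size=30)
        lam_max = lasso_lambda_max(Z, y)
        m = lasso_fit(Z, y, 1.001 * lam_max)
        np.testing.assert_array_equal(m.coef, 0.0)
        m2 = lasso_fit(Z, y, 0.5 * lam_max)
        assert len(m2.nonzero) >= 1

    def test_lambda_zero_matches_least_squares(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 5)))
        y = Z @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=40)
        m = lasso_fit(Z, y, 0.0)
        ls, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(m.coef, ls, atol=1e-6)

    @pytest.mark.parametrize("lam_frac", [0.05, 0.2, 0.5])
    def test_matches_independent_convex_oracle(self, rng, lam_frac):
        """Cross-check against an established convex solver on the same
        objective ||y-Zb||^2 + lam*|b|_1 (oracle alpha = lam / (2n))."""
        Z, _ = standardize(rng.normal(size=(20, 3)))
        y = Z @ np.array([2.0, 0.0, -1.0]) + 0.3 * rng.normal(size=20)
        lam = lam_frac * lasso_lambda_max(Z, y)
        mine = lasso_fit(Z, y, lam)
        oracle = Lasso(alpha=lam / (2 * len(y)), fit_intercept=False,
                       tol=1e-12, max_iter=100000).fit(Z, y)
        np.testing.assert_allclose(mine.coef, oracle.coef_, atol=1e-4)

    def test_five_feature_oracle_equivalence(self, rng):
        Z, _ = standardize(rng.normal(size=(25, 5)))
        y = Z @ np.array([1.5, -0.5, 0.0, 2.0, 0.0]) + 0.2 * rng.normal(size=25)
        lam = 0.1 * lasso_lambda_max(Z, y)
        mine = lasso_fit(Z, y, lam)
        oracle = Lasso(alpha=lam / (2 * len(y)), fit_intercept=False,
                       tol=1e-12, max_iter=100000).fit(Z, y)
        np.testing.assert_allclose(mine.coef, oracle.coef_, atol=1e-4)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(PulseError):
            lasso_fit(rng.normal(size=(10, 2)), np.ones(10), -1.0)

    def test_path_nonzeros_monotone_on_verified_instance(self, rng):
        Z, _ = standardize(rng.normal(size=(50, 10)))
        y = Z @ np.concatenate([[3.0, -2.0, 1.0], np.zeros(7)]) \
            + 0.1 * rng.normal(size=50)
        lam_max = lasso_lambda_max(Z, y)
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - 3, 40)
        betas = lasso_path(Z, y, lambdas)
        nz = (np.abs(betas) > 1e-10).sum(axis=1)
        assert np.all(np.diff(nz) >= 0)


class TestLassoCV:
    def test_null_data_selects_nothing_much(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 20)))
        y = rng.normal(size=40)
        m = lasso_cv(Z, y, folds=5, seed=0)
        assert len(m.nonzero) <= 3
        i = np.searchsorted(-m.cv_lambdas, -m.lam)
        assert m.cv_mse[i] == pytest.approx(np.var(y), rel=0.5)

    def test_planted_signal_recovered_with_signs(self, rng):
        Z, _ = standardize(rng.normal(size=(80, 30)))
        beta = np.zeros(30)
        beta[[2, 11, 25]] = [4.0, -3.0, 5.0]
        y = Z @ beta + 0.2 * rng.normal(size=80)
        m = lasso_cv(Z, y, folds=5, seed=1)
        assert {2, 11, 25} <= set(m.nonzero)
        assert np.sign(m.coef[2]) == 1 and np.sign(m.coef[11]) == -1

    def test_leave_one_out_on_tiny_data_runs(self, rng):
        Z, _ = standardize(rng.normal(size=(12, 4)))
        y = Z[:, 0] + 0.1 * rng.normal(size=12)
        m = lasso_cv(Z, y, folds=12, seed=2)
        assert m.lam >= 0
        assert m.coef.shape == (4,)


# --- PCA and index classification -------------------------------------------

class TestPcaClassify:
    def test_separated_clusters_perfect_accuracy(self, rng):
        # 10-sigma separation on one axis dominates total variance, so PC1
        # aligns with it and the threshold classifies perfectly
        Z = rng.normal(size=(60, 10))
        Z[:30, 0] += 10.0
        labels = np.array(["a"] * 30 + ["b"] * 30)
        pres, cres = pca_classify(Z - Z.mean(axis=0), labels, "a", "b",
                                  component=1)
        assert cres.accuracy == 1.0
        assert cres.accuracy + cres.misclassification == 1.0

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        Z, _ = standardize(rng.normal(size=(40, 8)))
        labels = np.array(["a", "b"] * 20)
        pres, _ = pca_classify(Z, labels, "a", "b", max_components=8)
        G = pres.loadings @ pres.loadings.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-8)
        back = pres.scores @ pres.loadings + Z.mean(axis=0)
        np.testing.assert_allclose(back, Z, atol=1e-8)

    def test_threshold_search_brute_force_example(self):
        scores = np.array([1.0, 2.0, 3.0, 2.5, 4.0, 5.0])
        is_g1 = np.array([True, True, True, False, False, False])
        _, _, err = threshold_search(scores, is_g1)
        assert err == pytest.approx(1 / 6)

    def test_component_beyond_rank_rejected(self, rng):
        Z, _ = standardize(rng.normal(size=(5, 10)))
        labels = np.array(["a", "a", "b", "b", "b"])
        with pytest.raises(PulseError):
            pca_classify(Z, labels, "a", "b", component=9)

    def test_null_training_accuracy_bounded(self, rng):
        """Best-threshold search on PC1 under the null overfits, but stays
        below 0.70 on average (n=60)."""
        accs = []
        for s in range(20):
            r = np.random.default_rng(500 + s)
            Z, _ = standardize(r.normal(size=(60, 193)))
            labels = np.array(["a"] * 30 + ["b"] * 30)
            _, cres = pca_classify(Z, labels, "a", "b", component=1)
            accs.append(cres.accuracy)
        assert np.mean(accs) < 0.70

    def test_two_component_fisher_mode(self, rng):
        Z = rng.normal(size=(40, 6))
        Z[:20, :2] += 4.0
        labels = np.array(["a"] * 20 + ["b"] * 20)
        _, cres = pca_classify(*standardize(Z)[:1], labels, "a", "b",
                               component=(1, 2))
        assert cres.accuracy >= 0.95


class TestClassifyByIndex:
    def test_perfect_separation(self):
        yhat = np.array([3.0, 2.0, -2.0, -3.0])
        labels = np.array(["a", "a", "b", "b"])
        res = classify_by_index(yhat, labels, "a", "b")
        assert res.accuracy == 1.0 and not res.flipped

    def test_orientation_autocorrected(self):
        yhat = np.array([-3.0, -2.0, 2.0, 3.0])
        labels = np.array(["a", "a", "b", "b"])
        res = classify_by_index(yhat, labels, "a", "b")
        assert res.accuracy == 1.0 and res.flipped

    def test_permuted_labels_hit_majority_baseline(self, rng):
        # a degenerate one-sided predictor scores the majority-class
        # baseline under label permutation; a sign-balanced random
        # predictor stays near chance
        n1, n2 = 16, 8
        labels = np.array(["a"] * n1 + ["b"] * n2)
        one_sided = np.abs(rng.normal(size=24)) + 0.1
        accs = [classify_by_index(one_sided, rng.permutation(labels),
                                  "a", "b").accuracy for _ in range(500)]
        assert np.mean(accs) == pytest.approx(max(n1, n2) / (n1 + n2),
                                              abs=0.03)
        balanced = rng.normal(size=24)
        accs = [classify_by_index(balanced, rng.permutation(labels),
                                  "a", "b").accuracy for _ in range(500)]
        assert 0.5 <= np.mean(accs) < 0.65


class TestSeparationPvalue:
    def test_strong_separation_attains_minimum(self, rng):
        yhat = np.concatenate([rng.normal(10, 1, 15), rng.normal(-10, 1, 15)])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        p = separation_pvalue(yhat, labels, "a", n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_zero_permutations_rejected(self):
        with pytest.raises(PulseError):
            separation_pvalue(np.ones(4), np.array(["a", "a", "b", "b"]), "a",
                              n_perm=0)

    def test_null_calibration(self):
        """Under exchangeable labels the p-value is conservative-uniform:
        rejection rate at alpha=0.05 lies in [0.02, 0.09]."""
        rejections = 0
        n_runs = 200
        for s in range(n_runs):
            r = np.random.default_rng(9000 + s)
            yhat = r.normal(size=30)
            labels = np.array(["a"] * 15 + ["b"] * 15)
            p = separation_pvalue(yhat, labels, "a", n_perm=399, seed=s)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_runs <= 0.09


# --- repeated rounds --------------------------------------------------------

class TestRepeatedRounds:
    def test_used_times_bounded_by_rounds(self, rng):
        X = rng.normal(size=(30, 25))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        rep = repeated_rounds_report(X, labels, "a", "b", method="efbls",
                                     R=6, seed=0)
        assert rep.table["used_times"].max() <= 6
        assert rep.rounds == 6
        assert len(rep.accuracies) == 6

    def test_tiny_group_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        labels = np.array(["a"] * 7 + ["b"] * 3)
        with pytest.raises(PulseError, match="stratify"):
            repeated_rounds_report(X, labels, "a", "b", R=5)

    def test_too_few_rounds_rejected(self, rng):
        X = rng.normal(size=(12, 5))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(PulseError):
            repeated_rounds_report(X, labels, "a", "b", R=1)

    def test_strong_signal_selected_every_round(self, rng):
        X = rng.normal(size=(60, 30))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        X[labels == "a", 7] += 6.0
        rep = repeated_rounds_report(X, labels, "a", "b", method="efbls",
                                     R=8, seed=3, feature_names=[f"f{i}" for i in range(30)])
        row = rep.table.set_index("feature").loc["f7"]
        assert row["used_times"] == 8
        assert rep.mean_accuracy > 0.9


def test_format_model_equation():
    eq = format_model_equation(["C2_zuocun", "t4_zuochi"], np.array([-0.01, -0.11]),
                               decimals=2)
    assert eq == "Y = -0.01*C2_zuocun - 0.11*t4_zuochi"
    assert format_model_equation([], np.array([])) == "Y = 0"
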