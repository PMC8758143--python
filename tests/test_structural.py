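"""Correlation screen, ICA component fitting, standardized OLS, bootstrap, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from chandelier.structural import (
    FEATURE_COLUMNS,
    coefficient_of_variation,
    correlation_screen,
    fit_components,
    regress_on_components,
    residual_bootstrap,
)


class TestCorrelationScreen:
    def test_duplicated_feature_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        r, padj = correlation_screen(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_single_test_adjustment_is_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        _, padj = correlation_screen(df)
        raw = stats.pearsonr(df["a"], df["b"]).pvalue
        assert padj.loc["a", "b"] == pytest.approx(raw)

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "flat": [5.0, 5, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            correlation_screen(df)

    def test_familywise_error_controlled_on_null(self):
        """Independent features, n=113: FWER across the screen stays ~5%."""
        rng = np.random.default_rng(42)
        n_rep, fwe = 400, 0
        for _ in range(n_rep):
            df = pd.DataFrame(
                rng.normal(size=(113, 4)), columns=list("abcd")
            )
            _, padj = correlation_screen(df)
            tri = padj.to_numpy()[np.triu_indices(4, 1)]
            fwe += np.any(tri < 0.05)
        rate = fwe / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestFitComponents:
    def test_laplace_sources_recovered(self):
        """Known 3-source Laplace mixing, n=5000: recovered to < 0.05."""
        rng = np.random.default_rng(5)
        S = rng.laplace(0, 1 / np.sqrt(2), size=(5000, 3))
        A = np.array(
            [
                [0.9, 0.1, 0.0],
                [0.0, 0.8, 0.3],
                [0.4, 0.0, 0.7],
                [0.2, 0.6, 0.0],
                [0.0, 0.3, 0.8],
                [0.7, 0.0, 0.2],
            ]
        )
        X = S @ A.T + rng.normal(0, 0.05, size=(5000, 6))
        df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        model = fit_components(df, k=3, restarts=10, seed=0)
        # compare in z-scored feature space
        sd = X.std(axis=0, ddof=1)
        A_z = A / sd[:, None]
        est = model.mixing
        cost = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                cost[i, j] = min(
                    np.abs(A_z[:, i] - est[:, j]).max(),
                    np.abs(A_z[:, i] + est[:, j]).max(),
                )
        rows, cols = linear_sum_assignment(cost)
        assert cost[rows, cols].max() < 0.05

    def test_scores_are_uncorrelated_and_signs_positive(self, paper_population):
        cells, *_ = paper_population
        model = fit_components(cells[FEATURE_COLUMNS], restarts=10, seed=1)
        C = model.score_correlations()
        off = C[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6
        for j in range(3):
            top = np.argmax(np.abs(model.mixing[:, j]))
            assert model.mixing[top, j] > 0

    def test_needs_more_rows_than_features(self):
        df = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(ValueError):
            fit_components(df)

    def test_pca_precheck_on_paper_preset(self, paper_population):
        """First three PCs carry most variance (reference value 84%)."""
        from sklearn.decomposition import PCA
        from chandelier.structural import _zscore

        cells, *_ = paper_population
        X = _zscore(cells[FEATURE_COLUMNS].to_numpy(float))
        ratio = PCA().fit(X).explained_variance_ratio_[:3].sum()
        assert 0.74 <= ratio <= 0.94


class TestRegression:
    def test_noiseless_single_component_target(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(80, 3))
        S = S - S.mean(0)
        # orthogonalize so scores are uncorrelated as the contract assumes
        Q, _ = np.linalg.qr(S)
        y = 2.0 * Q[:, 0]
        fit = regress_on_components(y, Q)
        assert fit.coef[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.coef[1:], 0, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_k1_standardized_coef_equals_pearson_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = 0.6 * x + rng.normal(size=60)
        fit = regress_on_components(y, x.reshape(-1, 1))
        r = stats.pearsonr(x, y).statistic
        assert fit.coef[0] == pytest.approx(r, abs=1e-12)

    def test_null_target_rarely_significant(self):
        """Independent target at n=113: family-level 5% false positives."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            S = rng.normal(size=(113, 3))
            y = rng.normal(size=113)
            fit = regress_on_components(y, S)
            hits += np.any(fit.pvalues_adjusted < 0.05)
        assert hits / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_adjusted_p_dominates_raw_and_ci_covers_estimate(
        self, paper_population
    ):
        cells, *_ = paper_population
        model = fit_components(cells[FEATURE_COLUMNS], restarts=10, seed=2)
        fit = regress_on_components(cells["chc_syn_count"], model.scores)
        assert np.all(fit.pvalues_adjusted >= fit.pvalues - 1e-15)
        assert np.all(fit.pvalues_adjusted <= 1.0)
        assert np.all(fit.conf_int[:, 0] <= fit.coef)
        assert np.all(fit.coef <= fit.conf_int[:, 1])
        # Holm-Sidak is monotone in the raw-p ordering
        order = np.argsort(fit.pvalues)
        assert np.all(np.diff(fit.pvalues_adjusted[order]) >= -1e-15)


class TestResidualBootstrap:
    def test_noiseless_linear_target_band_shrinks_to_zero(self):
        """Exact linear target: band width decays ~1/sqrt(n) toward zero."""
        rng = np.random.default_rng(4)

        def width(n):
            S, _ = np.linalg.qr(rng.normal(size=(n, 3)))
            y = 0.5 * S[:, 0]
            out = residual_bootstrap(y, S, focal=0, n_boot=200, seed=0)
            return np.max(out["hi"] - out["lo"])

        w_small, w_large = width(200), width(2000)
        assert w_large < w_small / 2
        assert w_large < 0.12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        S = rng.normal(size=(60, 3))
        y = S[:, 0] + rng.normal(size=60)
        a = residual_bootstrap(y, S, focal=1, n_boot=150, seed=9)
        b = residual_bootstrap(y, S, focal=1, n_boot=150, seed=9)
        assert np.array_equal(a["lo"], b["lo"])
        assert np.array_equal(a["hi"], b["hi"])

    def test_null_band_contains_zero_slope(self):
        """Coverage: band straddles 0 slope in ~95% of null replicates."""
        rng = np.random.default_rng(6)
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            S = rng.normal(size=(80, 3))
            y = rng.normal(size=80)
            out = residual_bootstrap(
                y, S, focal=0, n_boot=200,
                seed=int(rng.integers(2**31 - 1)),
            )
            grid = out["grid"]
            cover += bool(np.all(out["lo"] <= 0) and np.all(out["hi"] >= 0))
        assert cover / n_rep >= 0.85

    def test_small_n_boot_warns(self):
        rng = np.random.default_rng(7)
        S = rng.normal(size=(30, 3))
        with pytest.warns(UserWarning):
            residual_bootstrap(S[:, 0], S, focal=0, n_boot=50, seed=0)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_pair(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2.0) / 2.0
        )

    def test_geometric_sample_matches_closed_form(self):
        """CV of geometric(p) on support 1 is sqrt(1-p); p=0.44 -> 0.748."""
        rng = np.random.default_rng(10)
        sample = rng.geometric(0.44, size=100_000)
        assert coefficient_of_variation(sample) == pytest.approx(
            np.sqrt(1 - 0.44), abs=0.01
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])
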