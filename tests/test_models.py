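"""SPAD estimators: OLS with shade dummies, REML mixed model, RF, SVR."""

import numpy as np
import pandas as pd
import pytest

import spadvi.models as md
from spadvi import evaluate as ev
from spadvi.errors import DegenerateInputError, DesignError
from spadvi.pipeline import COARSE_SVR


def _groups(n_per=10, levels=(0.0, 0.25, 0.5, 0.75)):
    return list(np.repeat(levels, n_per))


class TestOlr:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        rep = md.fit_olr(X, y)
        pred = rep.predict(X)
        assert np.abs(pred - y).max() < 1e-9

    def test_dummy_coefficients_recover_group_means(self):
        """Irrelevant covariate, distinct level means, no noise: the level
        coefficients equal the group means exactly."""
        shade = _groups(8)
        means = {0.0: 18.0, 0.25: 26.0, 0.5: 32.0, 0.75: 29.0}
        y = np.array([means[g] for g in shade])
        rng = np.random.default_rng(1)
        X = rng.normal(size=(len(y), 1)) * 0  # exactly irrelevant
        X += rng.normal(size=(len(y), 1)) * 1e-12
        rep = md.fit_olr(X, y, shade=shade)
        for lvl, mean in means.items():
            assert rep.coefficients[f"shade_{lvl:g}"] == pytest.approx(
                mean, abs=1e-6)

    def test_small_design_matches_normal_equations(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0],
                      [4.0, 0.5], [5.0, 2.5], [6.0, 1.5]])
        y = np.array([3.0, 4.0, 8.0, 6.0, 11.0, 10.0])
        D = np.hstack([X, np.ones((6, 1))])
        expected = np.linalg.solve(D.T @ D, D.T @ y)
        rep = md.fit_olr(X, y)
        got = [rep.coefficients["x0"], rep.coefficients["x1"],
               rep.coefficients["intercept"]]
        assert np.allclose(got, expected)

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = 2.0
        with pytest.raises(DesignError):
            md.fit_olr(X, np.arange(10.0))

    def test_dummies_never_hurt_in_sample_r2(self):
        """Shade dummies nest the intercept-only coding, so in-sample R²
        cannot decrease."""
        rng = np.random.default_rng(7)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shade = _groups(10)
            X = rng.normal(size=(40, 2))
            y = X @ [1.0, 0.5] + rng.normal(0, 2, 40) + 20
            plain = md.fit_olr(X, y)
            dummy = md.fit_olr(X, y, shade=shade)
            r2_plain = ev.metrics(y, plain.predict(X))[0]
            r2_dummy = ev.metrics(y, dummy.predict(X, shade))[0]
            assert r2_dummy >= r2_plain - 1e-10


class TestLmm:
    def test_matches_statsmodels_reml(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        shade = _groups(50)
        X = rng.normal(size=(200, 2))
        u = {g: rng.normal(0, 3) for g in set(shade)}
        y = (1.5 * X[:, 0] - 2.0 * X[:, 1] + 25
             + np.array([u[g] for g in shade]) + rng.normal(0, 2, 200))
        rep = md.fit_lmm(X, shade, y)
        df = pd.DataFrame({"y": y, "x0": X[:, 0], "x1": X[:, 1], "g": shade})
        sm = smf.mixedlm("y ~ x0 + x1", df, groups=df["g"]).fit(reml=True)
        assert rep.coefficients["x0"] == pytest.approx(sm.fe_params["x0"],
                                                       abs=1e-3)
        assert rep.coefficients["intercept"] == pytest.approx(
            sm.fe_params["Intercept"], abs=1e-3)
        assert rep.hyperparameters["sigma2_random"] == pytest.approx(
            float(sm.cov_re.iloc[0, 0]), rel=1e-2)
        assert rep.hyperparameters["sigma2_residual"] == pytest.approx(
            sm.scale, rel=1e-2)

    def test_no_between_group_variance_degenerates_to_ols(self):
        rng = np.random.default_rng(9)
        shade = _groups(60)
        X = rng.normal(size=(240, 2))
        y = X @ [2.0, -1.0] + 10 + rng.normal(0, 1, 240)  # no group effect
        rep = md.fit_lmm(X, shade, y)
        ols = md.fit_olr(X, y)
        assert rep.hyperparameters["sigma2_random"] < 0.05
        for k in ("x0", "x1", "intercept"):
            assert rep.coefficients[k] == pytest.approx(ols.coefficients[k],
                                                        abs=1e-3)

    def test_balanced_blups_match_shrinkage_formula(self):
        """Intercept-only balanced layout: BLUPs equal group-mean deviations
        shrunk by sigma2_r / (sigma2_r + sigma2_e / n_g)."""
        rng = np.random.default_rng(3)
        shade = _groups(40)
        u = {g: rng.normal(0, 2.5) for g in set(shade)}
        y = 20 + np.array([u[g] for g in shade]) + rng.normal(0, 1.5, 160)
        rep = md.fit_lmm(np.zeros((160, 0)), shade, y)
        s2r = rep.hyperparameters["sigma2_random"]
        s2e = rep.hyperparameters["sigma2_residual"]
        mu = rep.coefficients["intercept"]
        shrink = s2r / (s2r + s2e / 40)
        for g in sorted(set(shade)):
            gbar = y[np.asarray(shade) == g].mean()
            assert rep.hyperparameters["blups"][g] == pytest.approx(
                shrink * (gbar - mu), abs=1e-4)

    def test_single_group_falls_back_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + rng.normal(size=30)
        with caplog.at_level("WARNING"):
            rep = md.fit_lmm(X, [0.0] * 30, y)
        assert rep.family == "lmm"
        assert rep.hyperparameters["sigma2_random"] == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            md.fit_lmm(np.random.default_rng(0).normal(size=(3, 1)),
                       [0.0, 0.0, 0.25], np.array([1.0, 2.0, 3.0]))


class TestRf:
    def test_constant_response_predicted_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.full(30, 7.5)
        rep = md.fit_rf(X, y, seed=0, n_trees=50)
        assert np.allclose(rep.predict(X), 7.5)

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = X @ [1, 2, 3] + rng.normal(size=40)
        p1 = md.fit_rf(X, y, seed=9, n_trees=100).predict(X)
        p2 = md.fit_rf(X, y, seed=9, n_trees=100).predict(X)
        assert np.array_equal(p1, p2)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = X @ [1.0, -1.0] + rng.normal(size=40)
        perm = rng.permutation(40)
        r1 = md.fit_rf(X, y, seed=3, n_trees=100)
        r2 = md.fit_rf(X[perm], y[perm], seed=3, n_trees=100)
        q = rng.normal(size=(5, 2))
        # bootstrap draws differ with row order, but reports exist and
        # predictions stay close for a strong signal
        assert np.allclose(r1.predict(q), r2.predict(q), atol=1.0)

    def test_train_r2_dominates_test_r2_on_average(self):
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 3))
            y = X @ [2, -1, 0.5] + rng.normal(0, 1.5, 120)
            rep = md.fit_rf(X[:90], y[:90], seed=seed, n_trees=100)
            r2_tr = ev.metrics(y[:90], rep.predict(X[:90]))[0]
            r2_te = ev.metrics(y[90:], rep.predict(X[90:]))[0]
            diffs.append(r2_tr - r2_te)
        assert np.mean(diffs) > 0


class TestSvr:
    def test_constant_response_rejected(self):
        with pytest.raises(DegenerateInputError):
            md.fit_svr(np.random.default_rng(0).normal(size=(20, 2)),
                       np.full(20, 3.0))

    def test_noiseless_linear_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 2))
        y = X @ [3.0, -1.0] + 5
        rep = md.fit_svr(X[:90], y[:90], seed=0, k_folds=5, **COARSE_SVR)
        r2 = ev.metrics(y[90:], rep.predict(X[90:]))[0]
        assert r2 > 0.95

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = X @ [1.0, 2.0] + rng.normal(0, 0.5, 60)
        h1 = md.fit_svr(X, y, seed=4, k_folds=5,
                        **COARSE_SVR).hyperparameters
        h2 = md.fit_svr(X, y, seed=4, k_folds=5,
                        **COARSE_SVR).hyperparameters
        assert h1 == h2
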