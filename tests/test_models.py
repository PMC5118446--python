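import numpy as np
import pytest

from gsbench import models as md


def additive_data(seed=0, n=100, p=300, nq=20, h2=0.7):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
    qtl = rng.choice(p, nq, replace=False)
    eff = rng.normal(0, 1, nq)
    g = (X[:, qtl] - X[:, qtl].mean(0)) @ eff
    y = g + rng.normal(0, np.sqrt(g.var() * (1 / h2 - 1)), n)
    return X, y, g, qtl


MCMC_FAST = dict(n_iter=1200, burn_in=300, thin=2)


class TestRRBLUP:
    def test_fixed_lambda_matches_dense_ridge_solution(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.5, (5, 3)).astype(float)
        y = rng.normal(0, 1, 5)
        m = md.fit_rrblup(y, X, cfg=md.ModelConfig(fixed_lambda=1.0))
        Xc = X - X.mean(0)
        r = y - m.psi[0]
        direct = np.linalg.solve(Xc.T @ Xc + np.eye(3), Xc.T @ r)
        np.testing.assert_allclose(m.beta, direct, atol=1e-10)

    def test_infinite_shrinkage_collapses_to_fixed_fit(self):
        X, y, _, _ = additive_data(1, n=40, p=60)
        m = md.fit_rrblup(y, X, cfg=md.ModelConfig(fixed_lambda=1e12))
        np.testing.assert_allclose(m.predict(X), np.full(40, m.psi[0]), atol=1e-6)

    def test_equivalent_to_gblup_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(50, 200)).astype(float)
        y = (X[:, :10] @ rng.normal(0, 1, 10)) + rng.normal(0, 2, 50)
        m = md.fit_rrblup(y, X)
        Xc = X - X.mean(0)
        K = Xc @ Xc.T
        lam = m.hyperparams["lambda"]
        Vinv = np.linalg.inv(K + lam * np.eye(50))
        one = np.ones((50, 1))
        mu = float(np.linalg.solve(one.T @ Vinv @ one, one.T @ Vinv @ y).item())
        gblup = mu + K @ Vinv @ (y - mu)
        assert np.max(np.abs(m.predict(X) - gblup)) <= 1e-6


class TestGauss:
    def test_kernel_identity_for_duplicate_line(self):
        X, y, _, _ = additive_data(2, n=50, p=100)
        m = md.fit_gauss(y, X)
        fitted = m.predict(X)
        clone = m.predict(X[[7]])
        assert clone[0] == pytest.approx(fitted[7], abs=1e-9)

    def test_huge_bandwidth_collapses_toward_fixed_fit(self):
        X, y, _, _ = additive_data(4, n=40, p=80)
        m = md.fit_gauss(y, X, cfg=md.ModelConfig(model="gauss", theta=1e12))
        assert np.std(m.predict(X)) < np.std(y) * 0.5

    def test_nonpositive_bandwidth_rejected(self):
        X, y, _, _ = additive_data(5, n=20, p=30)
        with pytest.raises(ValueError):
            md.fit_gauss(y, X, cfg=md.ModelConfig(model="gauss", theta=-1.0))

    def test_accuracy_close_to_rrblup_on_additive_trait(self):
        diffs = []
        for seed in range(3):
            X, y, g, _ = additive_data(seed, n=150, p=400, h2=0.8)
            tr = np.arange(150) < 120
            te = ~tr
            mg = md.fit_gauss(y[tr], X[tr])
            mr = md.fit_rrblup(y[tr], X[tr])
            ag = np.corrcoef(y[te], mg.predict(X[te]))[0, 1]
            ar = np.corrcoef(y[te], mr.predict(X[te]))[0, 1]
            diffs.append(ag - ar)
        assert abs(np.mean(diffs)) <= 0.1


class TestBayesC:
    def test_pi_one_collapses_to_rrblup_effects(self):
        X, y, _, _ = additive_data(0)
        cfg = md.ModelConfig(model="bayesC", n_iter=3000, burn_in=500, pi=1.0, seed=1)
        mc = md.fit_bayesC(y, X, cfg=cfg)
        mr = md.fit_rrblup(y, X)
        assert np.corrcoef(mc.beta, mr.beta)[0, 1] > 0.98

    def test_pure_noise_inclusion_near_prior(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.5, (80, 150)).astype(float)
        y = rng.normal(0, 1, 80)
        cfg = md.ModelConfig(model="bayesC", pi=0.1, seed=2, **MCMC_FAST)
        m = md.fit_bayesC(y, X, cfg=cfg)
        mean_incl = float(np.mean(m.diagnostics["inclusion_prob"]))
        assert 0.02 <= mean_incl <= 0.3

    def test_true_qtl_rank_above_null_markers(self):
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n, p, nq = 150, 300, 20
            X = rng.binomial(2, 0.4, (n, p)).astype(float)
            qtl = rng.choice(p, nq, replace=False)
            g = (X[:, qtl] - X[:, qtl].mean(0)) @ rng.normal(0, 1, nq)
            y = g + rng.normal(0, np.sqrt(g.var() * (1 / 0.7 - 1)), n)
            cfg = md.ModelConfig(model="bayesC", seed=seed, **MCMC_FAST)
            m = md.fit_bayesC(y, X, cfg=cfg)
            incl = m.diagnostics["inclusion_prob"]
            null = np.setdiff1d(np.arange(p), qtl)
            wins += incl[qtl].mean() > incl[null].mean()
        assert wins >= 2


class TestBayesB:
    def test_large_df_pi_one_approaches_rrblup(self):
        X, y, _, _ = additive_data(0)
        cfg = md.ModelConfig(model="bayesB", n_iter=3000, burn_in=500, pi=1.0,
                             df_prior=100.0, seed=1)
        mb = md.fit_bayesB(y, X, cfg=cfg)
        mr = md.fit_rrblup(y, X)
        assert np.corrcoef(mb.predict(X), mr.predict(X))[0, 1] > 0.95

    def test_constant_response_shrinks_everything(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.5, (40, 60)).astype(float)
        y = np.full(40, 2.5)
        cfg = md.ModelConfig(model="bayesB", seed=3, **MCMC_FAST)
        m = md.fit_bayesB(y, X, cfg=cfg)
        assert np.max(np.abs(m.beta)) < 1e-3
        assert m.hyperparams["var_resid"] < 1e-3

    def test_same_seed_bit_identical(self):
        X, y, _, _ = additive_data(6, n=60, p=100)
        cfg = md.ModelConfig(model="bayesB", seed=11, **MCMC_FAST)
        m1 = md.fit_bayesB(y, X, cfg=cfg)
        m2 = md.fit_bayesB(y, X, cfg=cfg)
        np.testing.assert_array_equal(m1.beta, m2.beta)
        np.testing.assert_array_equal(m1.psi, m2.psi)


class TestBLasso:
    def test_huge_fixed_lambda_shrinks_to_fixed_fit(self):
        X, y, _, _ = additive_data(2, n=60, p=100)
        cfg = md.ModelConfig(model="blasso", lasso_lambda=1e6, seed=1, **MCMC_FAST)
        m = md.fit_blasso(y, X, cfg=cfg)
        assert np.max(np.abs(m.beta)) < 1e-3
        np.testing.assert_allclose(m.predict(X), np.full(60, np.mean(y)), atol=0.05)

    def test_orthonormal_posterior_tracks_soft_threshold(self):
        """On orthonormal X with fixed lambda the posterior mean shrinks each
        coefficient toward the soft-thresholded least-squares solution."""
        rng = np.random.default_rng(4)
        n, p = 120, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q  # orthonormal columns, zero-mean enough for the check
        beta_true = np.array([4.0, -4.0, 3.0, 0.0, 0.0, 0.0, 2.5, 0.0])
        y = X @ beta_true + rng.normal(0, 0.3, n)
        lam = 8.0
        s2e = 0.09
        cfg = md.ModelConfig(model="blasso", lasso_lambda=lam, fixed_var_resid=s2e,
                             seed=5, n_iter=4000, burn_in=1000, thin=2)
        m = md.fit_blasso(y, X, cfg=cfg)
        ols = X.T @ (y - np.mean(y))
        # posterior mode under the double-exponential prior soft-thresholds
        # the least-squares coefficients at lam * sigma_e
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam * np.sqrt(s2e), 0.0)
        assert np.max(np.abs(m.beta - soft)) < 0.35
        assert np.all(np.abs(m.beta) <= np.abs(ols) + 0.05)
        big = np.abs(beta_true) > 0
        assert np.all(np.sign(m.beta[big]) == np.sign(beta_true[big]))

    def test_sparse_architecture_concentrates_effects_on_qtl(self):
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed + 20)
            n, p, nq = 150, 500, 5
            X = rng.binomial(2, 0.5, (n, p)).astype(float)
            qtl = rng.choice(p, nq, replace=False)
            g = (X[:, qtl] - X[:, qtl].mean(0)) @ rng.normal(0, 2, nq)
            y = g + rng.normal(0, np.sqrt(g.var() * 0.2), n)
            cfg = md.ModelConfig(model="blasso", seed=seed, **MCMC_FAST)
            m = md.fit_blasso(y, X, cfg=cfg)
            null = np.setdiff1d(np.arange(p), qtl)
            wins += np.abs(m.beta[qtl]).mean() > 5 * np.abs(m.beta[null]).mean()
        assert wins >= 2


class TestRandomForest:
    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.binomial(2, 0.5, (30, 40)).astype(float)
        y = np.full(30, 3.7)
        m = md.fit_rf(y, X, cfg=md.ModelConfig(model="rf", n_trees=20, seed=0))
        np.testing.assert_allclose(m.predict(X), 3.7, atol=1e-9)

    def test_single_unpruned_tree_memorizes_training_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        cfg = md.ModelConfig(model="rf", n_trees=1, bootstrap=False, min_leaf=1,
                             mtry=10, seed=0)
        m = md.fit_rf(y, X, cfg=cfg)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-9)

    def test_mtry_exceeding_markers_rejected(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            md.fit_rf(np.zeros(10), X, cfg=md.ModelConfig(model="rf", mtry=6))

    def test_epistatic_trait_favors_forest_over_ridge(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 400, 80
            X = rng.binomial(2, 0.5, size=(n, p)).astype(float)
            q = rng.choice(p, 8, replace=False)
            g = np.zeros(n)
            for a, b in zip(q[:4], q[4:]):
                g += (X[:, a] - 1) * (X[:, b] - 1)
            g = (g - g.mean()) / g.std()
            y = g + rng.normal(0, 0.3, n)
            tr = rng.random(n) < 0.8
            te = ~tr
            mr = md.fit_rf(y[tr], X[tr],
                           cfg=md.ModelConfig(model="rf", n_trees=300, min_leaf=2, seed=seed))
            mb = md.fit_rrblup(y[tr], X[tr])
            ar = np.corrcoef(y[te], mr.predict(X[te]))[0, 1]
            ab = np.corrcoef(y[te], mb.predict(X[te]))[0, 1]
            wins += ar > ab
        assert wins >= 4


class TestPredictContract:
    def test_training_rows_reproduce_fitted_values(self):
        X, y, _, _ = additive_data(3, n=50, p=80)
        for name in ("rrblup", "gauss"):
            m = md.fit(md.ModelConfig(model=name), y, X)
            np.testing.assert_allclose(m.predict(X), m.predict(X.copy()), atol=1e-12)

    def test_column_permutation_invariance(self):
        X, y, _, _ = additive_data(4, n=50, p=60)
        perm = np.random.default_rng(0).permutation(60)
        for name in ("rrblup", "gauss"):
            m1 = md.fit(md.ModelConfig(model=name), y, X)
            m2 = md.fit(md.ModelConfig(model=name), y, X[:, perm])
            np.testing.assert_allclose(m1.predict(X), m2.predict(X[:, perm]), atol=1e-8)

    def test_column_mismatch_rejected(self):
        X, y, _, _ = additive_data(5, n=30, p=40)
        m = md.fit_rrblup(y, X)
        with pytest.raises(ValueError, match="mismatch"):
            m.predict(X[:, :30])

    @pytest.mark.parametrize("name", md.MODEL_NAMES)
    def test_shift_in_response_shifts_predictions_exactly(self, name):
        X, y, _, _ = additive_data(7, n=60, p=80)
        cfg = md.ModelConfig(model=name, seed=3, n_iter=400, burn_in=100, thin=1,
                             n_trees=50)
        m1 = md.fit(cfg, y, X)
        m2 = md.fit(cfg, y + 11.5, X)
        np.testing.assert_allclose(m2.predict(X), m1.predict(X) + 11.5, atol=1e-6)

    @pytest.mark.parametrize("name", md.MODEL_NAMES)
    def test_same_seed_same_predictions(self, name):
        X, y, _, _ = additive_data(8, n=50, p=60)
        cfg = md.ModelConfig(model=name, seed=5, n_iter=300, burn_in=100, thin=1,
                             n_trees=30)
        p1 = md.fit(cfg, y, X).predict(X)
        p2 = md.fit(cfg, y, X).predict(X)
        np.testing.assert_array_equal(p1, p2)
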