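"""Six genomic-prediction models behind one fit/predict contract.

All models operate on the linear decomposition

    y = F psi + X beta + e

where ``y`` holds adjusted phenotypes (entry BLUPs), ``X`` the marker dose
matrix centered by training-column means (dominant 0/1 markers are thereby
centered by their presence frequency), and ``F`` the fixed-effect incidence
(intercept, optionally group indicators for structure adjustment).

Models:

* ``rrblup``  — ridge-regression BLUP; one shrinkage parameter for every
  marker, the variance ratio estimated by REML on the equivalent marker-
  kinship (GBLUP) model via an eigendecomposition profile likelihood.
* ``gauss``   — Gaussian-kernel kinship regression (RKHS): K = exp(-d^2/theta)
  on squared Euclidean marker distance, BLUP solution with REML ratio.
* ``bayesC``  — Gibbs sampler with per-marker inclusion indicators, a common
  effect variance with scaled-inverse-chi-square prior, and the inclusion
  probability pi estimated under a uniform prior.
* ``bayesB``  — as bayesC but with an independent scaled-inverse-chi-square
  variance per marker and a fixed pi (default 0.05).
* ``blasso``  — Bayesian LASSO (Park-Casella hierarchy: double-exponential
  shrinkage through per-marker tau^2 latents, Gamma hyperprior on lambda^2).
* ``rf``      — random-forest regression (bagged trees, random feature
  subsets), delegated to scikit-learn.

Every fit is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

MODEL_NAMES = ("rrblup", "gauss", "bayesC", "bayesB", "blasso", "rf")


@dataclass
class ModelConfig:
    model: str = "rrblup"
    # MCMC settings (bayesC / bayesB / blasso)
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    # priors
    df_prior: float = 5.0
    scale: Optional[float] = None  # effect-variance scale; derived if None
    pi: Optional[float] = None  # bayesB fixed pi (default 0.05); bayesC: fix if set
    lasso_lambda: Optional[float] = None  # fix lambda; hyperprior if None
    fixed_var_resid: Optional[float] = None  # fix sigma_e^2 (oracle checks)
    # rrblup / gauss
    fixed_lambda: Optional[float] = None  # ridge parameter sigma_e^2/sigma_beta^2
    theta: Optional[float] = None  # gauss bandwidth; median nonzero d^2 if None
    # random forest
    n_trees: int = 500
    mtry: Optional[int] = None  # features per split; p // 3 if None
    min_leaf: int = 5
    bootstrap: bool = True
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.pi is not None and not (0.0 < self.pi <= 1.0):
            raise ValueError("pi must be in (0, 1]")


@dataclass
class FittedGSModel:
    """Uniform fitted-model container; use :meth:`predict` for GEBVs."""

    model: str
    psi: np.ndarray  # fixed effects
    col_means: np.ndarray  # training marker means used for centering
    beta: Optional[np.ndarray] = None  # marker effects (posterior means where MCMC)
    alpha: Optional[np.ndarray] = None  # kernel coefficients (gauss)
    X_train: Optional[np.ndarray] = field(default=None, repr=False)  # centered (gauss)
    theta: Optional[float] = None
    rf_model: object = field(default=None, repr=False)
    hyperparams: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X_new: np.ndarray, F_new: np.ndarray | None = None) -> np.ndarray:
        X_new = np.asarray(X_new, float)
        if X_new.shape[1] != len(self.col_means):
            raise ValueError(
                f"marker columns mismatch: got {X_new.shape[1]}, "
                f"trained on {len(self.col_means)}"
            )
        if F_new is None:
            F_new = np.ones((X_new.shape[0], 1))
        fixed = F_new @ self.psi
        Xc = X_new - self.col_means
        if self.model == "gauss":
            d2 = cdist(Xc, self.X_train, "sqeuclidean")
            return fixed + np.exp(-d2 / self.theta) @ self.alpha
        if self.model == "rf":
            return fixed + self.rf_model.predict(Xc)
        return fixed + Xc @ self.beta


def _prep(y, X, F):
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    if F is None:
        F = np.ones((len(y), 1))
    F = np.asarray(F, float)
    if not (len(y) == X.shape[0] == F.shape[0]):
        raise ValueError("rows of y, X, F must align")
    col_means = X.mean(axis=0)
    return y, X - col_means, F, col_means


# ---------------------------------------------------------------------------
# REML on a single kinship (shared by rrblup and gauss)


def _kernel_reml(y: np.ndarray, F: np.ndarray, K: np.ndarray):
    """Profile REML for y = F psi + g + e, g ~ N(0, s2g K), e ~ N(0, s2e I).

    Returns (s2g, s2e, delta) with delta = s2e / s2g, maximizing the
    restricted likelihood on the eigenvalues of the F-projected kernel.
    """
    n, p = F.shape
    FtF = F.T @ F
    if np.linalg.matrix_rank(FtF) < p:
        raise np.linalg.LinAlgError("singular fixed-effect block")
    S = np.eye(n) - F @ np.linalg.solve(FtF, F.T)
    SKS = S @ K @ S
    SKS = (SKS + SKS.T) / 2.0
    xi, U = np.linalg.eigh(SKS)
    # keep the n - p eigenpairs spanning the projected space
    order = np.argsort(xi)[::-1]
    xi = np.clip(xi[order][: n - p], 0.0, None)
    U = U[:, order][:, : n - p]
    eta2 = (U.T @ y) ** 2

    def neg_restricted_ll(log_delta: float) -> float:
        d = 10.0**log_delta
        denom = xi + d
        s2 = float(np.sum(eta2 / denom)) / (n - p)
        return 0.5 * ((n - p) * np.log(s2) + float(np.sum(np.log(denom))))

    grid = np.linspace(-8.0, 8.0, 81)
    vals = [neg_restricted_ll(g) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(lo, hi), method="bounded")
    delta = float(10.0 ** res.x)
    s2g = float(np.sum(eta2 / (xi + delta))) / (n - p)
    s2e = delta * s2g
    return s2g, s2e, delta


def _gls_fixed(y, F, Vinv):
    A = F.T @ Vinv @ F
    return np.linalg.solve(A, F.T @ Vinv @ y)


def fit_rrblup(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Ridge-regression BLUP with REML-estimated (or fixed) shrinkage.

    Solved in the n x n kernel form K = Xc Xc' (efficient when markers far
    outnumber lines); marker effects recovered as
    beta = Xc' (K + lambda I)^{-1} (y - F psi).
    """
    cfg = cfg or ModelConfig(model="rrblup")
    y, Xc, F, col_means = _prep(y, X, F)
    n = len(y)
    K = Xc @ Xc.T
    if cfg.fixed_lambda is not None:
        lam = float(cfg.fixed_lambda)
        s2g = s2e = float("nan")
    else:
        s2g, s2e, lam = _kernel_reml(y, F, K)
    Vinv = np.linalg.inv(K + lam * np.eye(n))
    psi = _gls_fixed(y, F, Vinv)
    r = y - F @ psi
    beta = Xc.T @ (Vinv @ r)
    return FittedGSModel(
        model="rrblup",
        psi=psi,
        col_means=col_means,
        beta=beta,
        hyperparams={"lambda": lam, "var_beta": s2g, "var_resid": s2e},
    )


def fit_gauss(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Gaussian-kernel (RKHS) kinship regression with REML variance ratio.

    K(i, j) = exp(-d^2_ij / theta); theta defaults to the median nonzero
    squared Euclidean marker distance.
    """
    cfg = cfg or ModelConfig(model="gauss")
    y, Xc, F, col_means = _prep(y, X, F)
    d2 = cdist(Xc, Xc, "sqeuclidean")
    theta = cfg.theta
    if theta is None:
        nonzero = d2[np.triu_indices_from(d2, k=1)]
        nonzero = nonzero[nonzero > 0]
        theta = float(np.median(nonzero)) if len(nonzero) else 1.0
    if theta <= 0:
        raise ValueError(f"kernel bandwidth must be positive, got {theta}")
    K = np.exp(-d2 / theta)
    s2g, s2e, lam = _kernel_reml(y, F, K)
    Vinv = np.linalg.inv(K + lam * np.eye(len(y)))
    psi = _gls_fixed(y, F, Vinv)
    alpha = Vinv @ (y - F @ psi)
    return FittedGSModel(
        model="gauss",
        psi=psi,
        col_means=col_means,
        alpha=alpha,
        X_train=Xc,
        theta=theta,
        hyperparams={"lambda": lam, "var_g": s2g, "var_resid": s2e, "theta": theta},
    )


# ---------------------------------------------------------------------------
# Gibbs samplers


def _default_scale(y, Xc, df, expected_nonzero_frac):
    """Effect-variance prior scale: prior mean genetic variance = var(y)/2."""
    msx = float(np.sum(Xc.var(axis=0)))
    if msx <= 0:
        msx = 1.0
    var_g_target = float(np.var(y)) / 2.0
    # mean of scaled-inv-chi2(df, S) is df*S/(df-2)
    return var_g_target * (df - 2.0) / df / (msx * expected_nonzero_frac)


def _sample_fixed(rng, F, FtF_inv, r_plus_fixed, s2e):
    mean = FtF_inv @ (F.T @ r_plus_fixed)
    chol = np.linalg.cholesky(FtF_inv * s2e)
    return mean + chol @ rng.standard_normal(F.shape[1])


def _gibbs_common(y, X, F, cfg, per_marker_var: bool):
    """Shared Gibbs machinery for bayesC (common variance, estimated pi) and
    bayesB (per-marker variance, fixed pi)."""
    rng = np.random.default_rng(cfg.seed)
    y, Xc, F, col_means = _prep(y, X, F)
    n, p = Xc.shape
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    FtF_inv = np.linalg.inv(F.T @ F)

    df = cfg.df_prior
    if cfg.model == "bayesB":
        pi = cfg.pi if cfg.pi is not None else 0.05
        estimate_pi = False
    else:
        pi = cfg.pi if cfg.pi is not None else 0.5
        estimate_pi = cfg.pi is None
    scale = cfg.scale if cfg.scale is not None else _default_scale(y, Xc, df, pi)
    scale = max(scale, 1e-12)

    var_y = max(float(np.var(y)), 1e-12)
    nu_e, S_e = 4.0, var_y / 2.0

    beta = np.zeros(p)
    delta = np.zeros(p, dtype=bool)
    sigma_b2 = np.full(p if per_marker_var else 1, scale * df / max(df - 2.0, 0.5))
    s2e = var_y / 2.0
    psi = np.linalg.solve(F.T @ F, F.T @ y)
    r = y - F @ psi  # running residual (beta = 0)

    n_keep = 0
    beta_sum = np.zeros(p)
    psi_sum = np.zeros(F.shape[1])
    incl_sum = np.zeros(p)
    pi_sum = 0.0
    s2e_samples = []

    for it in range(cfg.n_iter):
        # fixed effects
        r_full = r + F @ psi
        psi_new = _sample_fixed(rng, F, FtF_inv, r_full, s2e)
        r += F @ (psi - psi_new)
        psi = psi_new

        log_pi = np.log(pi) if pi > 0 else -np.inf
        log_1mpi = np.log1p(-pi) if pi < 1 else -np.inf
        for j in range(p):
            if xtx[j] == 0.0:
                continue
            xj = Xc[:, j]
            if delta[j]:
                r += xj * beta[j]
            sb2 = sigma_b2[j] if per_marker_var else sigma_b2[0]
            rhs = float(xj @ r)
            c = xtx[j]
            v1 = c * sb2 + s2e
            # log Bayes factor for inclusion, beta integrated out
            log_bf = 0.5 * (rhs * rhs * sb2 / (s2e * v1) - np.log(v1 / s2e))
            if pi >= 1.0:
                include = True
            elif pi <= 0.0:
                include = False
            else:
                log_odds = log_pi + log_bf - log_1mpi
                prob = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                include = rng.random() < prob
            if include:
                prec = c + s2e / sb2
                b = rng.normal(rhs / prec, np.sqrt(s2e / prec))
                beta[j] = b
                delta[j] = True
                r -= xj * b
            else:
                beta[j] = 0.0
                delta[j] = False

        m = int(delta.sum())
        if per_marker_var:
            # included: conditional posterior; excluded: draw from the prior
            ssq = np.where(delta, beta**2, 0.0)
            df_post = np.where(delta, df + 1.0, df)
            scale_post = (df * scale + ssq) / df_post
            sigma_b2 = df_post * scale_post / rng.chisquare(df_post)
        else:
            ssq = float(np.sum(beta[delta] ** 2))
            df_post = df + m
            sigma_b2[0] = (df * scale + ssq) / rng.chisquare(df_post)

        if estimate_pi:
            pi = rng.beta(1.0 + m, 1.0 + p - m)

        sse = float(r @ r)
        s2e = (sse + nu_e * S_e) / rng.chisquare(n + nu_e)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_keep += 1
            beta_sum += beta
            psi_sum += psi
            incl_sum += delta
            pi_sum += pi
            s2e_samples.append(s2e)

    s2e_samples = np.asarray(s2e_samples)
    return FittedGSModel(
        model=cfg.model,
        psi=psi_sum / n_keep,
        col_means=col_means,
        beta=beta_sum / n_keep,
        hyperparams={
            "pi": pi_sum / n_keep,
            "scale": scale,
            "df": df,
            "var_resid": float(s2e_samples.mean()),
        },
        diagnostics={
            "inclusion_prob": incl_sum / n_keep,
            "var_resid_samples": s2e_samples,
            "n_samples": n_keep,
        },
    )


def fit_bayesC(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Bayes C-pi: common marker-effect variance, pi estimated (uniform prior)."""
    cfg = cfg or ModelConfig(model="bayesC")
    return _gibbs_common(y, X, F, cfg, per_marker_var=False)


def fit_bayesB(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Bayes B: per-marker effect variances, fixed pi (default 0.05)."""
    cfg = cfg or ModelConfig(model="bayesB")
    return _gibbs_common(y, X, F, cfg, per_marker_var=True)


def fit_blasso(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Bayesian LASSO via the Park-Casella scale-mixture hierarchy."""
    cfg = cfg or ModelConfig(model="blasso")
    rng = np.random.default_rng(cfg.seed)
    y, Xc, F, col_means = _prep(y, X, F)
    n, p = Xc.shape
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    FtF_inv = np.linalg.inv(F.T @ F)

    var_y = max(float(np.var(y)), 1e-12)
    a_lam, b_lam = 0.1, 0.1  # Gamma hyperprior on lambda^2

    beta = np.zeros(p)
    tau2 = np.ones(p)
    lam2 = cfg.lasso_lambda**2 if cfg.lasso_lambda is not None else float(p)
    fix_lambda = cfg.lasso_lambda is not None
    s2e = var_y / 2.0
    psi = np.linalg.solve(F.T @ F, F.T @ y)
    r = y - F @ psi

    n_keep = 0
    beta_sum = np.zeros(p)
    psi_sum = np.zeros(F.shape[1])
    lam_sum = 0.0
    s2e_samples = []

    for it in range(cfg.n_iter):
        r_full = r + F @ psi
        psi_new = _sample_fixed(rng, F, FtF_inv, r_full, s2e)
        r += F @ (psi - psi_new)
        psi = psi_new

        for j in range(p):
            if xtx[j] == 0.0:
                continue
            xj = Xc[:, j]
            r += xj * beta[j]
            prec = xtx[j] + 1.0 / tau2[j]
            b = rng.normal(float(xj @ r) / prec, np.sqrt(s2e / prec))
            beta[j] = b
            r -= xj * b

        # 1/tau_j^2 ~ InverseGaussian(sqrt(lam2 s2e / beta_j^2), lam2)
        bj2 = np.maximum(beta**2, 1e-12)
        mu_ig = np.sqrt(lam2 * s2e / bj2)
        inv_tau2 = rng.wald(mu_ig, lam2)
        tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)

        if not fix_lambda:
            lam2 = rng.gamma(a_lam + p, 1.0 / (b_lam + float(np.sum(tau2)) / 2.0))

        if cfg.fixed_var_resid is not None:
            s2e = cfg.fixed_var_resid
        else:
            sse = float(r @ r) + float(np.sum(beta**2 / tau2))
            s2e = sse / rng.chisquare(n + p)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_keep += 1
            beta_sum += beta
            psi_sum += psi
            lam_sum += np.sqrt(lam2)
            s2e_samples.append(s2e)

    s2e_samples = np.asarray(s2e_samples)
    return FittedGSModel(
        model="blasso",
        psi=psi_sum / n_keep,
        col_means=col_means,
        beta=beta_sum / n_keep,
        hyperparams={"lambda": lam_sum / n_keep, "var_resid": float(s2e_samples.mean())},
        diagnostics={"var_resid_samples": s2e_samples, "n_samples": n_keep},
    )


# ---------------------------------------------------------------------------
# random forest


def fit_rf(y, X, F=None, cfg: ModelConfig | None = None) -> FittedGSModel:
    """Random-forest regression on marker doses (scikit-learn backend).

    Fixed effects beyond the intercept are removed by OLS first; the forest
    is fit on the residuals.  mtry defaults to p // 3, min_leaf to 5.
    """
    from sklearn.ensemble import RandomForestRegressor

    cfg = cfg or ModelConfig(model="rf")
    y, Xc, F, col_means = _prep(y, X, F)
    p = Xc.shape[1]
    mtry = cfg.mtry if cfg.mtry is not None else max(1, p // 3)
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of markers {p}")
    if cfg.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    psi = np.linalg.lstsq(F, y, rcond=None)[0]
    resid = y - F @ psi
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        min_samples_leaf=cfg.min_leaf,
        bootstrap=cfg.bootstrap,
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(Xc, resid)
    return FittedGSModel(
        model="rf",
        psi=psi,
        col_means=col_means,
        rf_model=rf,
        hyperparams={"n_trees": cfg.n_trees, "mtry": mtry, "min_leaf": cfg.min_leaf},
    )


_FITTERS = {
    "rrblup": fit_rrblup,
    "gauss": fit_gauss,
    "bayesC": fit_bayesC,
    "bayesB": fit_bayesB,
    "blasso": fit_blasso,
    "rf": fit_rf,
}


def fit(cfg: ModelConfig, y, X, F=None) -> FittedGSModel:
    """Dispatch to the model named in ``cfg.model``."""
    return _FITTERS[cfg.model](y, X, F, cfg)
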