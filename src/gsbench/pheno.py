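"""Mixed-model phenotype adjustment for replicated incomplete-block trials.

Single-environment model (replication fixed; block nested in replication and
entry random)::

    y_ijk = mu + r_i + (r/b)_ij + g_k + e_ijk

Pooled model across environments (year/environment fixed; replication in
environment, block in replication in environment, entry, and entry-by-
environment random)::

    y_ijkl = mu + e_i + (e/r)_ij + (e/r/b)_ijk + g_l + (eg)_il + e_ijkl

Variance components are estimated by EM-REML on Henderson's mixed-model
equations; entry BLUPs plus their prediction-error (co)variances feed the
unbalanced-trial broad-sense heritability

    H^2 = 1 - vbar_delta / (2 * sigma_g^2)

where ``vbar_delta`` is the mean variance of a difference of two entry BLUPs
(Piepho-Moehring form).  Adjusted entry means (mu_hat + BLUP) are the
"observed" phenotypes of the downstream genomic-prediction models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .io import validate_phenotypes

MAX_ITER = 500
TOL = 1e-8
VAR_FLOOR = 1e-10


class DegenerateDataError(ValueError):
    pass


@dataclass
class VarianceComponents:
    var_entry: float
    var_resid: float
    var_block: float = 0.0
    var_entry_by_env: float | None = None
    var_rep_in_env: float | None = None
    converged: bool = True
    n_iter: int = 0
    loglik_path: list | None = None


@dataclass
class EntryBLUPs:
    """Adjusted entry values mu_hat + g_hat with their error covariances."""

    entry_ids: list[str]
    adjusted: np.ndarray  # (n_entries,)
    pev: np.ndarray  # (n_entries,) prediction-error variance
    entry_cov: np.ndarray  # (n, n) PEV covariance of entry BLUPs
    grand_mean: float
    trait: str
    dataset: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entry": self.entry_ids, "adjusted": self.adjusted, "pev": self.pev}
        )


@dataclass
class VariabilityStats:
    mean: float
    sd: float  # residual SD (consistent with the CV column)
    cv: float
    gv: float
    h2: float
    gcv: float
    pcv: float
    ecv: float

    def as_row(self) -> dict:
        """Printed-scale row, percentages to 2 dp."""
        return {
            "Mean": round(self.mean, 2),
            "SD": round(self.sd, 2),
            "CV": round(self.cv, 2),
            "GV": round(self.gv, 2),
            "H2": round(self.h2, 2),
            "GCV": round(self.gcv, 2),
            "PCV": round(self.pcv, 2),
            "ECV": round(self.ecv, 2),
        }


# ---------------------------------------------------------------------------
# EM-REML on the mixed-model equations


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    idx = pd.Categorical(labels, categories=levels).codes
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z, levels

def _fixed_design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Intercept plus drop-first dummies for each factor (full rank)."""
    parts = [np.ones((len(df), 1))]
    for c in cols:
        Z, levels = _one_hot(df[c])
        if len(levels) > 1:
            parts.append(Z[:, 1:])
    return np.hstack(parts)


def reml_loglik(y, X, Z_blocks, var_u, var_e) -> float:
    """Direct restricted log-likelihood (for diagnostics/small problems)."""
    n = len(y)
    V = var_e * np.eye(n)
    for Z, v in zip(Z_blocks, var_u):
        V += v * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    return -0.5 * (logdetV + logdetX + float(y @ P @ y))


def emreml(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: list[np.ndarray],
    max_iter: int = MAX_ITER,
    tol: float = TOL,
    track_loglik: bool = False,
):
    """EM-REML for y = Xb + sum_k Z_k u_k + e, u_k ~ N(0, s2_k I).

    Returns ``(var_u, var_e, beta, u_list, Cinv, n_iter, converged, ll_path)``
    where ``Cinv`` is the inverse MME coefficient matrix (multiply by var_e
    for the sampling covariance of ``[beta, u]``).
    """
    y = np.asarray(y, float)
    n = len(y)
    p = X.shape[1]
    q = [Z.shape[1] for Z in Z_blocks]
    if np.ptp(y) == 0.0:
        # constant response: every component at the zero boundary, the fixed
        # intercept carries the mean, all BLUPs zero
        beta = np.zeros(p)
        beta[0] = y[0] if n else 0.0
        ptot = p + sum(q)
        return (
            np.full(len(Z_blocks), VAR_FLOOR),
            VAR_FLOOR,
            beta,
            [np.zeros(qk) for qk in q],
            np.zeros((ptot, ptot)),
            0,
            True,
            [] if track_loglik else None,
        )
    W = np.hstack([X] + list(Z_blocks))
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    rank_x = np.linalg.matrix_rank(X)

    var_y = float(np.var(y))
    if var_y == 0.0:
        var_y = 1.0
    var_u = np.full(len(Z_blocks), var_y / (len(Z_blocks) + 1))
    var_e = var_y / (len(Z_blocks) + 1)

    offsets = np.cumsum([p] + q)
    ll_path = [] if track_loglik else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for k in range(len(Z_blocks)):
            lam = var_e / max(var_u[k], VAR_FLOOR)
            sl = slice(offsets[k], offsets[k + 1])
            C[sl, sl] += lam * np.eye(q[k])
        # tiny ridge on the fixed block guards against exact singularity
        C[:p, :p] += 1e-10 * np.eye(p)
        cf = cho_factor(C, lower=True)
        sol = cho_solve(cf, Wty)
        Cinv = cho_solve(cf, np.eye(C.shape[0]))

        new_u = np.empty_like(var_u)
        for k in range(len(Z_blocks)):
            sl = slice(offsets[k], offsets[k + 1])
            uk = sol[sl]
            new_u[k] = (float(uk @ uk) + var_e * float(np.trace(Cinv[sl, sl]))) / q[k]
        new_e = (yty - float(sol @ Wty)) / (n - rank_x)
        new_u = np.maximum(new_u, VAR_FLOOR)
        new_e = max(new_e, VAR_FLOOR)

        if track_loglik:
            ll_path.append(reml_loglik(y, X, Z_blocks, new_u, new_e))

        denom = np.maximum(np.abs(var_u), VAR_FLOOR)
        rel = max(
            float(np.max(np.abs(new_u - var_u) / np.maximum(denom, var_y * 1e-12))),
            abs(new_e - var_e) / max(var_e, var_y * 1e-12),
        )
        var_u, var_e = new_u, new_e
        if rel < tol:
            converged = True
            break

    # final solve at converged components
    C = WtW.copy()
    for k in range(len(Z_blocks)):
        lam = var_e / max(var_u[k], VAR_FLOOR)
        sl = slice(offsets[k], offsets[k + 1])
        C[sl, sl] += lam * np.eye(q[k])
    C[:p, :p] += 1e-10 * np.eye(p)
    cf = cho_factor(C, lower=True)
    sol = cho_solve(cf, Wty)
    Cinv = cho_solve(cf, np.eye(C.shape[0]))
    beta = sol[:p]
    u_list = [sol[offsets[k]: offsets[k + 1]] for k in range(len(Z_blocks))]
    return var_u, var_e, beta, u_list, Cinv, it, converged, ll_path


# ---------------------------------------------------------------------------
# model fits


def _check_trait(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    records = validate_phenotypes(records)
    df = records[records["trait"] == trait].reset_index(drop=True)
    if df.empty:
        raise DegenerateDataError(f"trait {trait!r} not present")
    if df["entry"].nunique() < 2:
        raise DegenerateDataError("need at least 2 entries")
    # all-identical responses are allowed: components collapse to the zero
    # boundary and every BLUP equals the grand mean
    return df


def fit_single_env(
    records: pd.DataFrame, trait: str, track_loglik: bool = False
) -> tuple[VarianceComponents, EntryBLUPs]:
    """Fit the single-environment model by EM-REML and return entry BLUPs."""
    df = _check_trait(records, trait)
    envs = df["env"].unique()
    if len(envs) != 1:
        raise ValueError(f"fit_single_env needs exactly one environment, got {list(envs)}")
    if df["rep"].nunique() < 2:
        raise DegenerateDataError("need >= 2 replications")

    y = df["value"].to_numpy(float)
    X = _fixed_design(df, ["rep"])
    block_label = df["rep"].astype(str) + "/" + df["block"].astype(str)
    Z_block, _ = _one_hot(block_label)
    Z_entry, entry_levels = _one_hot(df["entry"])

    var_u, var_e, beta, u_list, Cinv, n_iter, conv, ll = emreml(
        y, X, [Z_block, Z_entry], track_loglik=track_loglik
    )
    p = X.shape[1]
    qb = Z_block.shape[1]
    sl_entry = slice(p + qb, p + qb + Z_entry.shape[1])
    entry_cov = var_e * Cinv[sl_entry, sl_entry]
    mu = float(np.mean(X @ beta))

    order = np.argsort(entry_levels)
    vc = VarianceComponents(
        var_entry=float(var_u[1]),
        var_resid=float(var_e),
        var_block=float(var_u[0]),
        converged=conv,
        n_iter=n_iter,
        loglik_path=ll,
    )
    blups = EntryBLUPs(
        entry_ids=[entry_levels[i] for i in order],
        adjusted=mu + u_list[1][order],
        pev=np.diag(entry_cov)[order],
        entry_cov=entry_cov[np.ix_(order, order)],
        grand_mean=mu,
        trait=trait,
        dataset=str(envs[0]),
    )
    return vc, blups


def fit_multi_env(
    records: pd.DataFrame, trait: str, track_loglik: bool = False
) -> tuple[VarianceComponents, EntryBLUPs]:
    """Fit the pooled across-environment model; environment fixed, entry and
    entry-by-environment random."""
    df = _check_trait(records, trait)
    if df["env"].nunique() < 2:
        raise ValueError("fit_multi_env needs >= 2 environments")

    all_entries = set(df["entry"])
    present = set(df["entry"].unique())
    dropped = all_entries - present
    if dropped:  # pragma: no cover - defensive
        warnings.warn(f"entries absent from all environments excluded: {sorted(dropped)}")

    y = df["value"].to_numpy(float)
    X = _fixed_design(df, ["env"])
    rep_label = df["env"] + "/" + df["rep"]
    block_label = rep_label + "/" + df["block"]
    ge_label = df["entry"] + "@" + df["env"]
    Z_rep, _ = _one_hot(rep_label)
    Z_block, _ = _one_hot(block_label)
    Z_entry, entry_levels = _one_hot(df["entry"])
    Z_ge, _ = _one_hot(ge_label)

    var_u, var_e, beta, u_list, Cinv, n_iter, conv, ll = emreml(
        y, X, [Z_rep, Z_block, Z_entry, Z_ge], track_loglik=track_loglik
    )
    p = X.shape[1]
    start = p + Z_rep.shape[1] + Z_block.shape[1]
    sl_entry = slice(start, start + Z_entry.shape[1])
    entry_cov = var_e * Cinv[sl_entry, sl_entry]
    mu = float(np.mean(X @ beta))

    order = np.argsort(entry_levels)
    vc = VarianceComponents(
        var_entry=float(var_u[2]),
        var_resid=float(var_e),
        var_block=float(var_u[1]),
        var_entry_by_env=float(var_u[3]),
        var_rep_in_env=float(var_u[0]),
        converged=conv,
        n_iter=n_iter,
        loglik_path=ll,
    )
    blups = EntryBLUPs(
        entry_ids=[entry_levels[i] for i in order],
        adjusted=mu + u_list[2][order],
        pev=np.diag(entry_cov)[order],
        entry_cov=entry_cov[np.ix_(order, order)],
        grand_mean=mu,
        trait=trait,
        dataset="pooled",
    )
    return vc, blups


# ---------------------------------------------------------------------------
# heritability and variability coefficients


def heritability(vc: VarianceComponents, blups: EntryBLUPs) -> float:
    """Broad-sense heritability for unbalanced trials.

    H^2 = 1 - vbar_delta / (2 sigma_g^2), with vbar_delta the mean variance of
    a difference of two entry BLUPs; reduces to sigma_g^2 / (sigma_g^2 +
    sigma_e^2 / r) for balanced complete designs.  Clamped to [0, 1].
    """
    sg2 = vc.var_entry
    if sg2 <= VAR_FLOOR * 10:
        return 0.0
    C = blups.entry_cov
    n = C.shape[0]
    # mean over pairs of C_ii + C_jj - 2 C_ij
    vbar = 2.0 * (n * np.trace(C) - C.sum()) / (n * (n - 1))
    return float(np.clip(1.0 - vbar / (2.0 * sg2), 0.0, 1.0))


def variability_stats(mean: float, vc: VarianceComponents, h2: float) -> VariabilityStats:
    """Genetic-estimate summary: GV, CV, GCV, PCV, ECV on the printed scale.

    GCV = 100 sqrt(GV)/mean; ECV = CV = 100 sqrt(sigma_e^2)/mean;
    PCV = sqrt(GCV^2 + ECV^2).
    """
    if mean <= 0:
        raise ValueError("trait mean must be positive for CV-type statistics")
    gv = vc.var_entry
    resid_sd = float(np.sqrt(vc.var_resid))
    gcv = 100.0 * np.sqrt(gv) / mean
    ecv = 100.0 * resid_sd / mean
    pcv = float(np.sqrt(gcv**2 + ecv**2))
    return VariabilityStats(
        mean=mean, sd=resid_sd, cv=ecv, gv=gv, h2=h2, gcv=float(gcv), pcv=pcv, ecv=float(ecv)
    )
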