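"""Cross-validation engine and accuracy summaries.

Prediction accuracy is the Pearson correlation between observed adjusted
phenotypes (entry BLUPs) and model predictions on held-out lines.  The
default design is 5-fold cross-validation repeated 20 times (100 runs);
SE is the standard deviation of the run-level accuracies divided by
sqrt(n_runs).  The observed-on-predicted OLS slope is reported alongside
(slope 1 = unbiased dispersion of the predicted breeding values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markers as mk
from . import models as md
from .io import GenotypeMatrix


@dataclass
class CVPlan:
    n_lines: int
    n_folds: int
    n_repeats: int
    seed: int
    folds: np.ndarray  # (n_repeats, n_lines) fold index per line

    @property
    def n_runs(self) -> int:
        return self.n_folds * self.n_repeats


@dataclass
class CVResult:
    trait: str
    dataset: str
    model: str
    grouping: str
    accuracies: np.ndarray  # per run
    slopes: np.ndarray  # per run (NaN where undefined)
    n_runs: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def se(self) -> float:
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(self.n_runs))

    @property
    def mean_slope(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(self.slopes))

    def summary_row(self) -> dict:
        return {
            "trait": self.trait,
            "dataset": self.dataset,
            "model": self.model,
            "grouping": self.grouping,
            "accuracy": self.mean_accuracy,
            "se": self.se,
            "slope": self.mean_slope,
            "n_runs": self.n_runs,
        }


def make_cv_plan(n_lines: int, n_folds: int = 5, n_repeats: int = 20, seed: int = 0) -> CVPlan:
    """Repeated k-fold plan: per repeat a fresh seeded permutation is split
    into near-equal folds (sizes differ by at most 1)."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_lines < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} lines, got {n_lines}")
    rng = np.random.default_rng(seed)
    folds = np.empty((n_repeats, n_lines), dtype=int)
    base = np.arange(n_lines) % n_folds  # sizes differ by <= 1
    for rep in range(n_repeats):
        perm = rng.permutation(n_lines)
        folds[rep, perm] = base
    return CVPlan(n_lines=n_lines, n_folds=n_folds, n_repeats=n_repeats, seed=seed, folds=folds)


def pearson_accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson r; constant predictions give 0 with a warning (undefined r)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        warnings.warn("undefined correlation (constant vector); scored as 0")
        return 0.0
    return float(np.corrcoef(observed, predicted)[0, 1])


def regression_slope(observed: np.ndarray, predicted: np.ndarray) -> float:
    """OLS slope of observed on predicted: cov(obs, pred) / var(pred)."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if len(observed) < 3:
        raise ValueError("need at least 3 pairs")
    vp = np.var(predicted)
    if vp == 0.0:
        return float("nan")
    return float(np.cov(observed, predicted, ddof=0)[0, 1] / vp)


def _aligned_inputs(geno: GenotypeMatrix, blups: pd.DataFrame):
    """Inner-join genotype lines with BLUP entries; returns (X, y, line index)."""
    entry_to_val = dict(zip(blups["entry"], blups["adjusted"]))
    keep = [i for i, lid in enumerate(geno.line_ids) if lid in entry_to_val]
    if len(keep) < len(geno.line_ids) or len(keep) < len(entry_to_val):
        warnings.warn(
            f"inner join: {len(keep)} lines in both genotypes and BLUPs "
            f"({geno.n_lines} genotyped, {len(entry_to_val)} with BLUPs)"
        )
    y = np.array([entry_to_val[geno.line_ids[i]] for i in keep])
    return np.asarray(keep), y


def run_cv(
    geno: GenotypeMatrix,
    blups: pd.DataFrame,
    plan: CVPlan,
    model_cfgs: list[md.ModelConfig],
    covariates: np.ndarray | None = None,
    trait: str = "",
    dataset: str = "",
    grouping: str = "All",
    X: np.ndarray | None = None,
) -> list[CVResult]:
    """Run the repeated k-fold CV for each model configuration.

    ``blups`` needs columns entry/adjusted.  ``covariates`` (aligned to
    genotype lines) become extra fixed-effect columns next to the intercept;
    they absorb structure during fitting but are excluded from the scored
    GEBV (intercept + marker term only), so accuracy reflects the genomic
    prediction rather than the covariate means.  An imputed dose matrix may
    be passed as ``X`` to skip re-imputation.
    """
    keep, y = _aligned_inputs(geno, blups)
    if X is None:
        X = mk.impute_missing(geno)
    X = X[keep]
    n = len(y)
    if covariates is not None:
        F_all = np.column_stack([np.ones(n), np.asarray(covariates)[keep]])
    else:
        F_all = np.ones((n, 1))
    if plan.n_lines != n:
        raise ValueError(f"plan built for {plan.n_lines} lines, data has {n}")

    results = []
    for cfg in model_cfgs:
        accs, slopes = [], []
        for rep in range(plan.n_repeats):
            fold_id = plan.folds[rep]
            for f in range(plan.n_folds):
                test = fold_id == f
                train = ~test
                fitted = md.fit(cfg, y[train], X[train], F_all[train])
                F_score = F_all[test].copy()
                F_score[:, 1:] = 0.0  # score the genomic component only
                pred = fitted.predict(X[test], F_score)
                accs.append(pearson_accuracy(y[test], pred))
                slopes.append(
                    regression_slope(y[test], pred) if np.var(pred) > 0 else np.nan
                )
        results.append(
            CVResult(
                trait=trait,
                dataset=dataset,
                model=cfg.model,
                grouping=grouping,
                accuracies=np.asarray(accs),
                slopes=np.asarray(slopes),
                n_runs=plan.n_runs,
            )
        )
    return results


def grid_experiment(
    geno: GenotypeMatrix,
    blups: pd.DataFrame,
    plan: CVPlan,
    model_cfgs: list[md.ModelConfig],
    trait: str = "",
    dataset: str = "",
) -> pd.DataFrame:
    """The 3x3 missingness x MAF filter-grid accuracy experiment.

    For each of the nine (max_missing, min_maf) combinations the marker panel
    is filtered, imputed and cross-validated with every model.  Variable-
    selection samplers (bayesC, bayesB) are undefined with monomorphic
    markers retained at min_maf = 0 and are emitted as missing cells there.
    Returns a long table (model, max_missing, min_maf, n_markers, accuracy, se).
    """
    summary = mk.marker_summary(geno)
    rows = []
    for max_missing, min_maf in mk.FILTER_GRID:
        idx = mk.filter_markers(summary, max_missing, min_maf)
        if len(idx) == 0:
            for cfg in model_cfgs:
                rows.append((cfg.model, max_missing, min_maf, 0, np.nan, np.nan, "empty panel"))
            continue
        sub = geno.subset_markers(idx)
        X = mk.impute_missing(sub)
        for cfg in model_cfgs:
            if cfg.model in ("bayesC", "bayesB") and min_maf == 0.0:
                rows.append((cfg.model, max_missing, min_maf, len(idx), np.nan, np.nan, "undefined at MAF 0"))
                continue
            res = run_cv(sub, blups, plan, [cfg], trait=trait, dataset=dataset, X=X)[0]
            rows.append(
                (cfg.model, max_missing, min_maf, len(idx), res.mean_accuracy, res.se, "")
            )
    return pd.DataFrame(
        rows,
        columns=["model", "max_missing", "min_maf", "n_markers", "accuracy", "se", "note"],
    )


def group_analyses(
    geno: GenotypeMatrix,
    blups: pd.DataFrame,
    plan: CVPlan,
    model_cfgs: list[md.ModelConfig],
    groups: np.ndarray,
    trait: str = "",
    dataset: str = "",
    adjust_structure: bool = True,
) -> list[CVResult]:
    """Structure-aware analyses: pooled (All), within each group, and
    optionally a structure-adjusted pooled run with group indicators as
    fixed covariates.

    Groups smaller than the fold count are skipped with a warning.
    """
    groups = np.asarray(groups)
    if len(groups) != geno.n_lines:
        raise ValueError("group labels must cover all lines")
    results = list(
        run_cv(geno, blups, plan, model_cfgs, trait=trait, dataset=dataset, grouping="All")
    )
    for g in np.unique(groups):
        sel = np.flatnonzero(groups == g)
        if len(sel) < plan.n_folds:
            warnings.warn(f"group {g} has {len(sel)} < {plan.n_folds} lines; skipped")
            continue
        sub = geno.subset_lines(sel)
        sub_entries = set(sub.line_ids)
        sub_blups = blups[blups["entry"].isin(sub_entries)]
        sub_plan = make_cv_plan(
            len(sub_blups), plan.n_folds, plan.n_repeats, plan.seed + int(g) + 1
        )
        results.extend(
            run_cv(sub, sub_blups, sub_plan, model_cfgs, trait=trait, dataset=dataset,
                   grouping=str(g))
        )
    if adjust_structure:
        levels = np.unique(groups)
        # drop-first indicator coding
        cov = np.column_stack([(groups == lv).astype(float) for lv in levels[1:]])
        results.extend(
            run_cv(geno, blups, plan, model_cfgs, covariates=cov, trait=trait,
                   dataset=dataset, grouping="All+structure")
        )
    return results


def summarize(results: list[CVResult]) -> pd.DataFrame:
    return pd.DataFrame([r.summary_row() for r in results])
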