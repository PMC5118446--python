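"""Per-marker summaries, filtering, imputation, kinship, clustering and LD.

Allele frequencies are dose-based for codominant (0/1/2) markers; dominant
presence/absence markers are summarised by treating the presence frequency of
the scored fragment as the allele frequency.  All statistics are biallelic.

Linkage disequilibrium is reported as r^2.  On unphased data it is computed
as the squared Pearson correlation of dose vectors over jointly called lines
(the composite-LD estimator); the haplotype-frequency form

    r^2 = (pAB*pab - pAb*paB)^2 / (pA*pB*pa*pb)

is implemented as a phased oracle for simulated data, where the two coincide
in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import GenotypeMatrix

MIN_SHARED_LINES = 10


# ---------------------------------------------------------------------------
# per-marker summaries


def marker_summary(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missing fraction, PIC, gene diversity and call count.

    All-missing markers are flagged (``ok = False``) with NaN statistics and
    must be excluded downstream.  PIC for a biallelic marker is
    ``1 - p^2 - q^2 - 2 p^2 q^2``; gene diversity is ``1 - p^2 - q^2``.
    """
    calls = geno.calls
    n_lines = geno.n_lines
    is_dom = geno.is_dominant
    n_called = np.sum(~np.isnan(calls), axis=0)
    missing_frac = 1.0 - n_called / n_lines

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_call = np.nanmean(calls, axis=0)
    # allele frequency of the counted allele
    p = np.where(is_dom, mean_call, mean_call / 2.0)
    maf = np.minimum(p, 1.0 - p)
    q = 1.0 - p
    gene_div = 1.0 - p**2 - q**2
    pic = gene_div - 2.0 * p**2 * q**2
    ok = n_called > 0
    out = pd.DataFrame(
        {
            "marker_id": geno.marker_ids,
            "maf": np.where(ok, maf, np.nan),
            "missing_frac": missing_frac,
            "pic": np.where(ok, pic, np.nan),
            "gene_diversity": np.where(ok, gene_div, np.nan),
            "n_called": n_called,
            "ok": ok,
        }
    )
    return out


def filter_markers(
    summary: pd.DataFrame, max_missing: float, min_maf: float
) -> np.ndarray:
    """Indices of markers with missing_frac <= max_missing and maf >= min_maf.

    Missingness is applied first; MAF is the frequency computed on called
    lines only.  All-missing (flagged) markers never pass.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (
        summary["ok"].to_numpy()
        & (summary["missing_frac"].to_numpy() <= max_missing)
        & (summary["maf"].to_numpy() >= min_maf)
    )
    return np.flatnonzero(keep)


#: the 3x3 missingness x MAF grid of the filtering experiment
FILTER_GRID = [
    (0.0, 0.0), (0.0, 0.05), (0.0, 0.10),
    (0.10, 0.0), (0.10, 0.05), (0.10, 0.10),
    (0.30, 0.0), (0.30, 0.05), (0.30, 0.10),
]


def impute_missing(geno: GenotypeMatrix) -> np.ndarray:
    """Real-valued complete dose matrix: missing -> marker mean of called lines."""
    summary_ok = np.sum(~np.isnan(geno.calls), axis=0) > 0
    if not summary_ok.all():
        raise ValueError("all-missing markers must be filtered before imputation")
    X = geno.calls.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X


# ---------------------------------------------------------------------------
# kinship and grouping


def kinship(geno: GenotypeMatrix, X: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix, mixed marker types.

    Codominant columns are centered by 2p and contribute 2p(1-p) to the
    scaling denominator; dominant columns are centered by the presence
    frequency and contribute p(1-p).
    """
    if X is None:
        X = impute_missing(geno)
    is_dom = geno.is_dominant
    mean_call = X.mean(axis=0)
    p = np.where(is_dom, mean_call, mean_call / 2.0)
    W = X - np.where(is_dom, p, 2.0 * p)
    denom = float(np.sum(np.where(is_dom, p * (1 - p), 2.0 * p * (1 - p))))
    if denom <= 0:
        raise ValueError("kinship undefined: all markers monomorphic")
    return (W @ W.T) / denom


def cluster_lines(K: np.ndarray, k: int):
    """Average-linkage grouping on the kinship-derived distance max(K) - K.

    Returns ``(labels, linkage_matrix)``; labels are 0-based, k groups.
    """
    n = K.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    D = K.max() - K
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2_phased(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """r^2 from phased haplotypes via the haplotype-frequency formula."""
    hapA = np.asarray(hapA).ravel()
    hapB = np.asarray(hapB).ravel()
    pA = hapA.mean()
    pB = hapB.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.nan
    pAB = np.mean((hapA == 1) & (hapB == 1))
    D = pAB - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def ld_r2(
    geno: GenotypeMatrix,
    pairs: list[tuple[int, int]] | None = None,
    within_chromosome: bool = True,
    include_dominant: bool = False,
    min_shared: int = MIN_SHARED_LINES,
) -> pd.DataFrame:
    """Pairwise r^2 as squared dose correlation over jointly called lines.

    With ``pairs=None`` all within-chromosome pairs are used (dominant markers
    excluded unless ``include_dominant``).  Pairs with fewer than
    ``min_shared`` jointly called lines are skipped with a warning.
    Columns: marker_a, marker_b, chrom, distance_bp, r2.
    """
    calls = geno.calls
    mm = geno.marker_map
    chrom = mm["chrom"].to_numpy()
    pos = mm["pos_bp"].to_numpy()
    if pairs is None:
        eligible = np.ones(geno.n_markers, dtype=bool)
        if not include_dominant:
            eligible &= ~geno.is_dominant
        idx = np.flatnonzero(eligible)
        pairs = []
        for c in pd.unique(chrom[idx]):
            on_c = idx[chrom[idx] == c]
            for a_i in range(len(on_c)):
                for b_i in range(a_i + 1, len(on_c)):
                    pairs.append((on_c[a_i], on_c[b_i]))

    rows = []
    n_skipped = 0
    for a, b in pairs:
        if within_chromosome and chrom[a] != chrom[b]:
            continue
        xa, xb = calls[:, a], calls[:, b]
        shared = ~np.isnan(xa) & ~np.isnan(xb)
        if shared.sum() < min_shared:
            n_skipped += 1
            continue
        va, vb = xa[shared], xb[shared]
        if va.std() == 0.0 or vb.std() == 0.0:
            r2 = np.nan
        else:
            r = np.corrcoef(va, vb)[0, 1]
            r2 = float(r * r)
        dist = abs(int(pos[a]) - int(pos[b])) if chrom[a] == chrom[b] else np.nan
        rows.append((geno.marker_ids[a], geno.marker_ids[b], chrom[a], dist, r2))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} pairs with < {min_shared} shared calls")
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "chrom", "distance_bp", "r2"])


def ld_decay(
    ld: pd.DataFrame, threshold: float = 0.2, bin_width_bp: float = 100_000.0
) -> pd.DataFrame:
    """Per-chromosome LD extent at the r^2 threshold.

    Pairs are binned by distance (``bin_width_bp``); the extent is the upper
    edge of the last bin, scanning outward from zero, whose mean r^2 is still
    >= threshold (0 if the first bin is already below it).
    """
    out = []
    ld = ld.dropna(subset=["distance_bp", "r2"])
    for c, sub in ld.groupby("chrom", sort=True):
        dist = sub["distance_bp"].to_numpy(float)
        r2 = sub["r2"].to_numpy(float)
        n_bins = int(np.ceil((dist.max() + 1) / bin_width_bp)) if len(dist) else 0
        extent = 0.0
        for b in range(n_bins):
            lo, hi = b * bin_width_bp, (b + 1) * bin_width_bp
            in_bin = (dist >= lo) & (dist < hi)
            if not in_bin.any():
                continue
            if r2[in_bin].mean() >= threshold:
                extent = hi
            else:
                break
        out.append((c, extent))
    return pd.DataFrame(out, columns=["chrom", "extent_bp"])


def binned_mean_r2(ld: pd.DataFrame, bin_width_bp: float = 100_000.0) -> pd.DataFrame:
    """Mean r^2 per distance bin, pooled over chromosomes."""
    ld = ld.dropna(subset=["distance_bp", "r2"])
    dist = ld["distance_bp"].to_numpy(float)
    r2 = ld["r2"].to_numpy(float)
    bins = (dist // bin_width_bp).astype(int)
    rows = []
    for b in np.unique(bins):
        rows.append((b * bin_width_bp, (b + 1) * bin_width_bp, r2[bins == b].mean(), int((bins == b).sum())))
    return pd.DataFrame(rows, columns=["bin_lo_bp", "bin_hi_bp", "mean_r2", "n_pairs"])
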