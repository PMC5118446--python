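"""Synthetic genotype, QTL and multi-environment trial simulator.

Emulates the statistical structure of a two-subpopulation elite chickpea
panel: ~315 lines (desi/kabuli-like groups), ~3000 markers of which roughly
half are dominant presence/absence scores, blocky within-chromosome linkage
disequilibrium, polygenic traits with entry-mean heritabilities between ~0.5
and ~0.99, and phenotypes from replicated incomplete-block trials across
environments.

The generator is a truth channel: alongside genotypes and plot records it
returns the QTL positions, effects and true breeding values so that recovery
tests can score every downstream estimator.

Model choices (see docs/methods.md for rationale):

* group divergence — one Balding–Nichols beta draw per marker per group,
  with a single ``fst`` for all markers;
* linkage disequilibrium — each line's two haplotypes are mosaics of a small
  founder-haplotype pool, with crossover points spaced exponentially at mean
  ``ld_block_len_bp``; LD extent is controlled by that one length;
* dominant markers — a latent 0/1/2 dose is thresholded (presence = dose >= 1);
* heritability — the residual plot variance is back-solved so that the
  entry-mean heritability within a single environment hits ``target_H2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CODOMINANT, DOMINANT, GenotypeMatrix, validate_phenotypes


class InvalidConfig(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults mirror the benchmark panel: 315 lines in two groups (162/153),
    3000 markers with 1432 dominant, 8 chromosomes, LD blocks on the order of
    a megabase, four traits whose entry-mean heritabilities span ~0.5-0.99,
    and 2 environments x 3 replications in incomplete blocks.
    """

    n_lines: int = 315
    n_groups: int = 2
    group_sizes: tuple[int, ...] = (162, 153)
    fst: float = 0.2
    n_chromosomes: int = 8
    chrom_length_bp: int = 60_000_000
    n_markers: int = 3000
    frac_dominant: float = 1432 / 3000
    ld_block_len_bp: float = 1_500_000.0
    n_founders: int = 8
    n_qtl: int = 100
    qtl_effect_sd: float = 1.0
    trait_names: tuple[str, ...] = ("DF", "DM", "SDW", "SY")
    target_H2: tuple[float, ...] = (0.95, 0.54, 0.99, 0.76)
    n_envs: int = 2
    n_reps: int = 3
    blocks_per_rep: int = 7
    var_block: float = 1.0
    var_ge: float = 0.5
    var_resid: float | None = None  # back-solved from target_H2 when None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.target_H2, (int, float)):
            self.target_H2 = (float(self.target_H2),) * len(self.trait_names)
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if sum(self.group_sizes) != self.n_lines:
            raise InvalidConfig(
                f"group_sizes {self.group_sizes} must sum to n_lines={self.n_lines}"
            )
        if len(self.group_sizes) != self.n_groups:
            raise InvalidConfig("len(group_sizes) must equal n_groups")
        if not (0.0 <= self.fst < 1.0):
            raise InvalidConfig(f"fst must be in [0, 1), got {self.fst}")
        if self.n_markers < self.n_chromosomes:
            raise InvalidConfig("need at least one marker per chromosome")
        if not (0.0 <= self.frac_dominant <= 1.0):
            raise InvalidConfig("frac_dominant must be in [0, 1]")
        if len(self.target_H2) != len(self.trait_names):
            raise InvalidConfig("one target_H2 per trait required")
        for h2 in self.target_H2:
            if not (0.0 < h2 <= 1.0):
                raise InvalidConfig(f"target_H2 must be in (0, 1], got {h2}")
        for name in ("var_block", "var_ge"):
            if getattr(self, name) < 0:
                raise InvalidConfig(f"{name} must be >= 0")
        if self.var_resid is not None and self.var_resid < 0:
            raise InvalidConfig("var_resid must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfig("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery tests."""

    group_labels: np.ndarray  # (n_lines,) int group index
    latent_dose: np.ndarray = field(repr=False, default=None)  # (n_lines, n_markers) 0/1/2
    haplotypes: np.ndarray = field(repr=False, default=None)  # (n_lines, 2, n_markers) 0/1
    qtl_indices: np.ndarray | None = None  # (n_qtl,) marker column indices
    qtl_effects: np.ndarray | None = None  # (n_qtl, n_traits)
    true_breeding_values: np.ndarray | None = None  # (n_lines, n_traits), centered
    trait_names: tuple[str, ...] | None = None
    realized_H2: np.ndarray | None = None  # (n_traits,)


# ---------------------------------------------------------------------------
# genotypes


def _balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Group-specific allele frequencies around ancestral p at divergence fst."""
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    q = rng.beta(a, b)
    return np.clip(q, 1e-6, 1.0 - 1e-6)


def _mosaic_haplotype(
    founders: np.ndarray,
    positions: np.ndarray,
    chrom_len: float,
    block_len: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One haplotype as a mosaic copy of founder haplotypes.

    Crossover points are spaced Exponential(block_len) along the chromosome;
    each segment copies a uniformly chosen founder.
    """
    n_founders = founders.shape[0]
    breaks = []
    pos = rng.exponential(block_len)
    while pos < chrom_len:
        breaks.append(pos)
        pos += rng.exponential(block_len)
    n_seg = len(breaks) + 1
    choice = rng.integers(0, n_founders, size=n_seg)
    seg_of_marker = np.searchsorted(np.asarray(breaks), positions)
    return founders[choice[seg_of_marker], np.arange(len(positions))]


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the genotype matrix; returns ``(GenotypeMatrix, SimTruth)``.

    The returned truth carries group labels, the latent 0/1/2 dose matrix
    (before dominant thresholding) and phased haplotypes for LD oracles.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    # markers spread near-equally over chromosomes, positions sorted, 1-based
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c, m in enumerate(per_chrom):
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=m))
        while len(pos) < m:  # resample collisions (rare at genome scale)
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=m - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos)
        positions.append(pos)
        chroms.extend([f"Ca{c + 1:02d}"] * m)
    positions = np.concatenate(positions)

    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_markers)
    group_labels = np.repeat(np.arange(cfg.n_groups), cfg.group_sizes)

    haps = np.empty((cfg.n_lines, 2, cfg.n_markers), dtype=np.int8)
    col0 = 0
    boundaries = []
    for m in per_chrom:
        boundaries.append((col0, col0 + m))
        col0 += m

    for g in range(cfg.n_groups):
        p_g = _balding_nichols(p_anc, cfg.fst, rng)
        founders = (rng.random((cfg.n_founders, cfg.n_markers)) < p_g).astype(np.int8)
        lines_g = np.flatnonzero(group_labels == g)
        for i in lines_g:
            for h in range(2):
                for (lo, hi) in boundaries:
                    haps[i, h, lo:hi] = _mosaic_haplotype(
                        founders[:, lo:hi],
                        positions[lo:hi].astype(float),
                        float(cfg.chrom_length_bp),
                        cfg.ld_block_len_bp,
                        rng,
                    )

    dose = haps.sum(axis=1).astype(float)

    n_dom = int(round(cfg.frac_dominant * cfg.n_markers))
    is_dom = np.zeros(cfg.n_markers, dtype=bool)
    is_dom[rng.choice(cfg.n_markers, size=n_dom, replace=False)] = True
    calls = dose.copy()
    calls[:, is_dom] = (dose[:, is_dom] >= 1).astype(float)

    marker_ids = [f"M{j + 1:05d}" for j in range(cfg.n_markers)]
    mm = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": chroms,
            "pos_bp": positions.astype(int),
            "marker_type": np.where(is_dom, DOMINANT, CODOMINANT),
        }
    )
    geno = GenotypeMatrix(
        line_ids=[f"L{i + 1:04d}" for i in range(cfg.n_lines)],
        marker_ids=marker_ids,
        calls=calls,
        marker_map=mm,
    )
    truth = SimTruth(group_labels=group_labels, latent_dose=dose, haplotypes=haps)
    return geno, truth


# ---------------------------------------------------------------------------
# QTL and true breeding values


def simulate_qtl(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Draw QTL among codominant markers and compute centered breeding values.

    Effects are iid Normal(0, qtl_effect_sd^2) per allele copy per trait; the
    true breeding value of a line is the effect-weighted sum of its latent
    doses at the QTL, centered to population mean zero.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    codom = np.flatnonzero(~geno.is_dominant)
    if cfg.n_qtl > len(codom):
        raise InvalidConfig(
            f"n_qtl={cfg.n_qtl} exceeds {len(codom)} codominant markers"
        )
    n_traits = len(cfg.trait_names)
    qtl = np.sort(rng.choice(codom, size=cfg.n_qtl, replace=False))
    effects = rng.normal(0.0, cfg.qtl_effect_sd, size=(cfg.n_qtl, n_traits))
    if cfg.n_qtl == 0:
        tbv = np.zeros((geno.n_lines, n_traits))
    else:
        dose = truth.latent_dose[:, qtl]
        tbv = dose @ effects
        tbv = tbv - tbv.mean(axis=0, keepdims=True)
    truth.qtl_indices = qtl
    truth.qtl_effects = effects
    truth.true_breeding_values = tbv
    truth.trait_names = cfg.trait_names
    return truth


# ---------------------------------------------------------------------------
# trials


def _residual_variance(genetic_var: float, h2: float, cfg: SimConfig) -> float:
    """Back-solve plot residual variance so entry-mean H2 in one env = h2.

    Within a single environment entry and entry-x-env effects are confounded,
    so the heritable signal there is var(tbv) + var_ge; blocks are excluded
    because the mixed model absorbs them.
    """
    if h2 <= 0:
        raise InvalidConfig("target_H2 = 0 with genetic variance > 0 is unreachable")
    return cfg.n_reps * genetic_var * (1.0 / h2 - 1.0)


def simulate_trials(
    truth: SimTruth, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate plot records for a replicated incomplete-block multi-env trial.

    plot = grand mean + env + rep-in-env + block(var_block) + tbv
           + entry-x-env(var_ge) + residual, with the residual variance per
    trait back-solved from ``target_H2`` unless ``var_resid`` is given.
    Entries are assigned to blocks within each replication by a seeded
    permutation.  Records the realized entry-mean heritability in the truth.
    """
    if truth.true_breeding_values is None:
        raise ValueError("run simulate_qtl first (true breeding values required)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n_lines, n_traits = truth.true_breeding_values.shape
    entries = [f"L{i + 1:04d}" for i in range(n_lines)]

    grand_mean = 100.0
    env_eff = rng.normal(0.0, 3.0, size=cfg.n_envs)
    rep_eff = rng.normal(0.0, 1.0, size=(cfg.n_envs, cfg.n_reps))

    realized = np.empty(n_traits)
    resid_sd = np.empty(n_traits)
    for t in range(n_traits):
        g_var = float(np.var(truth.true_breeding_values[:, t])) + cfg.var_ge
        if cfg.var_resid is not None:
            v = cfg.var_resid
        elif g_var == 0.0:
            v = 0.0
        else:
            v = _residual_variance(g_var, cfg.target_H2[t], cfg)
        resid_sd[t] = np.sqrt(v)
        realized[t] = g_var / (g_var + v / cfg.n_reps) if (g_var + v) > 0 else 0.0
    truth.realized_H2 = realized

    ge = rng.normal(0.0, np.sqrt(cfg.var_ge), size=(cfg.n_envs, n_lines, n_traits))

    rows = []
    for e in range(cfg.n_envs):
        env = f"E{e + 1}"
        for r in range(cfg.n_reps):
            perm = rng.permutation(n_lines)
            block_of = np.empty(n_lines, dtype=int)
            for b, chunk in enumerate(np.array_split(perm, cfg.blocks_per_rep)):
                block_of[chunk] = b
            block_eff = rng.normal(0.0, np.sqrt(cfg.var_block), size=(cfg.blocks_per_rep, n_traits))
            resid = rng.normal(0.0, 1.0, size=(n_lines, n_traits)) * resid_sd
            for i in range(n_lines):
                b = block_of[i]
                for t, trait in enumerate(cfg.trait_names):
                    value = (
                        grand_mean
                        + env_eff[e]
                        + rep_eff[e, r]
                        + block_eff[b, t]
                        + truth.true_breeding_values[i, t]
                        + ge[e, i, t]
                        + resid[i, t]
                    )
                    rows.append((entries[i], env, f"R{r + 1}", f"B{b + 1}", trait, value))
    df = pd.DataFrame(rows, columns=["entry", "env", "rep", "block", "trait", "value"])
    return validate_phenotypes(df)


# ---------------------------------------------------------------------------
# missingness


def inject_missing(geno: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask each call independently with probability ``rate`` (map unchanged)."""
    if not (0.0 <= rate < 1.0):
        raise InvalidConfig(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0.0:
        return geno
    rng = np.random.default_rng(seed)
    calls = geno.calls.copy()
    calls[rng.random(calls.shape) < rate] = np.nan
    return GenotypeMatrix(
        line_ids=list(geno.line_ids),
        marker_ids=list(geno.marker_ids),
        calls=calls,
        marker_map=geno.marker_map.copy(),
    )


def simulate_dataset(cfg: SimConfig):
    """Full simulation: genotypes (with missingness), truth, and trial records."""
    rng = np.random.default_rng(cfg.seed)
    geno, truth = simulate_genotypes(cfg, rng)
    truth = simulate_qtl(geno, cfg, truth, rng)
    pheno = simulate_trials(truth, cfg, rng)
    if cfg.missing_rate > 0:
        geno = inject_missing(geno, cfg.missing_rate, cfg.seed + 3)
    return geno, truth, pheno
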