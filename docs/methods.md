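# Methods

`gsbench` implements a genomic-selection (GS) analysis pipeline for an elite
chickpea breeding panel and a synthetic-data generator that reproduces the
statistical structure such an analysis assumes. This note documents the
models, the defaults and their rationale, the numerical choices, and what the
simulator does and does not emulate.

## Phenotype adjustment (mixed models)

Plot records from replicated incomplete-block trials are adjusted with two
REML-fitted mixed models.

Single environment:

    y_ijk = mu + r_i + (r/b)_ij + g_k + e_ijk

with replication `r_i` fixed, block-in-replication `(r/b)_ij ~ N(0, sigma_b^2)`
and entry `g_k ~ N(0, sigma_g^2)` random.

Pooled across environments (years/seasons):

    y_ijkl = mu + e_i + (e/r)_ij + (e/r/b)_ijk + g_l + (eg)_il + eps_ijkl

with environment fixed and replication-in-environment, block, entry and
entry-by-environment random.

Estimation is EM-REML on Henderson's mixed-model equations: at most 500
iterations, relative tolerance 1e-8, components clamped at a 1e-10 floor.
EM was chosen over AI/Newton because every component here is an i.i.d.
variance (no covariance structures), the M-step is closed-form, and the
algorithm cannot step outside the parameter space; the restricted
log-likelihood is non-decreasing across iterations, which the test suite
checks directly. A constant response vector short-circuits to the boundary
solution (all components zero, BLUPs at the grand mean).

"Observed adjusted phenotypic values" for downstream prediction are
`mu_hat + BLUP(entry)` from the dataset under analysis: per-season fits for
per-season accuracy, the pooled model for pooled accuracy. `mu_hat` is the
mean fixed-effect prediction over the observed plots.

Broad-sense heritability uses the unbalanced-trial form

    H^2 = 1 - vbar_delta / (2 sigma_g^2),

where `vbar_delta` is the mean variance of a difference of two entry BLUPs,
computed from the full prediction-error covariance block of the entries.
For balanced complete designs this reduces exactly to
`sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)` (asserted to 1e-6 in the tests).
The Cullis variant (based on mean PEV rather than mean pairwise difference
variance) is not implemented; the pairwise form is the one documented here.

Variability coefficients are reported on the printed percentage scale:
`GCV = 100 sqrt(sigma_g^2)/mean`, `ECV = CV = 100 sigma_e / mean`,
`PCV = sqrt(GCV^2 + ECV^2)`. ECV is defined as the residual coefficient of
variation — in the published table this column numerically equals the CV
column — and PCV is composed from GCV and ECV rather than from a separately
fitted phenotypic variance. The reported `SD` is the residual standard
deviation, consistent with `SD/mean * 100 = CV`.

## Marker statistics, kinship, clustering

All statistics are biallelic. For codominant (0/1/2) markers the allele
frequency comes from dose counts over called lines; for dominant
presence/absence markers the presence frequency of the scored fragment is
treated as the allele frequency. `PIC = 1 - p^2 - q^2 - 2 p^2 q^2`
(maximum 0.375), gene diversity `= 1 - p^2 - q^2` (maximum 0.5).

The missingness filter is applied before the MAF filter, and MAF is always
computed on called lines only; the 3x3 grid of
(0%, <=10%, <=30% missing) x (0%, >=5%, >=10% MAF) is exposed as a unit.
Missing calls are imputed with the marker mean dose (real-valued output).

Kinship is the VanRaden genomic relationship matrix: codominant columns
centered by `2p` contributing `2p(1-p)` to the denominator, dominant columns
centered by the presence frequency contributing `p(1-p)`. Grouping uses
average-linkage agglomerative clustering on the distance `max(K) - K`,
cut to `k` clusters; ties resolve deterministically through the ordered
condensed distance.

## Linkage disequilibrium

On unphased data, `r^2` is the squared Pearson correlation of dose vectors
over jointly called lines (the composite-LD estimator); pairs with fewer
than 10 shared calls are skipped. The haplotype-frequency form

    r^2 = D^2 / (pA pB pa pb),  D = pAB - pA pB

is implemented as a phased oracle used on simulated data, where the two
estimators agree in expectation (verified by Monte Carlo in the tests).
Dominant markers are excluded from LD by default (their 0/1 score is not a
dose) but can be included by flag, since the original marker panel pooled
both types without comment. Decay extent is computed from binned mean `r^2`
(default 100 kb bins, configurable): scanning outward, the extent is the
upper edge of the last bin whose mean is still at or above the threshold
(default `r^2 = 0.2`), or 0 if the first bin is already below it.

## Prediction models

All six models share `y = F psi + X beta + e`, with `X` centered by training
column means (which centers dominant markers by their presence frequency) and
`F` an intercept plus optional group covariates.

* **RR-BLUP** — single ridge parameter `lambda = sigma_e^2/sigma_beta^2`
  estimated by REML on the equivalent kinship model `K = Xc Xc'` via an
  eigendecomposition profile likelihood (exact for one random component,
  no iteration over effects); effects recovered through the n x n identity
  `beta = Xc'(K + lambda I)^{-1}(y - F psi)`. A fixed-lambda path exists for
  closed-form verification.
* **Gaussian kernel (RKHS)** — `K(i,j) = exp(-d2_ij/theta)` on squared
  Euclidean marker distance; `theta` defaults to the median nonzero `d2`
  (a standard bandwidth heuristic; the source analysis does not state one),
  variance ratio by the same REML machinery.
* **Bayes C-pi** — Gibbs sampler, common effect variance with
  scaled-inverse-chi-square prior (df 5), per-marker inclusion indicators,
  `pi` estimated under a uniform (Beta(1,1)) prior.
* **Bayes B** — per-marker scaled-inverse-chi-square effect variances,
  fixed `pi` (default 0.05; excluded markers redraw their variance from the
  prior, included markers from the conditional posterior).
* **Bayesian LASSO** — Park-Casella hierarchy: `beta_j ~ N(0, sigma_e^2
  tau_j^2)`, `1/tau_j^2` inverse-Gaussian updates, `lambda^2` with a
  Gamma(0.1, 0.1) hyperprior (fixable for oracle checks, as is
  `sigma_e^2`), single-site effect updates.
* **Random forest** — bagged regression trees with random feature subsets
  (`mtry = p//3`, `min_leaf = 5`, 500 trees by default), delegated to
  scikit-learn; fixed effects beyond the intercept are removed by OLS before
  the forest is grown.

MCMC defaults are 6000 iterations, 1000 burn-in, thinning 5 (the source
analysis reports no chain settings; these are conservative for panels of a
few hundred lines). The effect-variance prior scale is set so the prior mean
genetic variance equals half the phenotypic variance. All samplers are
deterministic given their seed; chains are bit-reproducible.

## Cross-validation and structure analyses

The CV plan is 5 folds x 20 repeats (100 runs) of seeded permutations with
fold sizes differing by at most 1, unstratified ("All" analyses), matching
random 80/20 assignment. Accuracy is the Pearson correlation of observed
adjusted phenotypes with predictions on held-out lines; a run with constant
predictions scores 0 with a warning rather than being dropped, keeping the
run count fixed. The summary SE is the standard deviation of run-level
accuracies divided by sqrt(n_runs) — consistent in magnitude with the
published tables (~0.002-0.009 against run SDs of ~0.05). The
observed-on-predicted OLS slope is reported per run and averaged.

Group analyses fit three variants per trait and model: pooled ("All"),
within-group CV with folds drawn inside each group, and a structure-adjusted
pooled run with drop-first group indicators in `F`. In the adjusted run the
covariates absorb between-group mean differences during fitting but are
excluded from the scored prediction (GEBV = intercept + marker term): scoring
the full fixed-effect prediction would re-introduce the group means into the
correlation and make the adjustment a no-op. Within-group CV is the primary
definition of per-group accuracy; pooled-training with group-wise test
scoring is possible through the library but is not the default.

## Synthetic-data generator

The generator emulates the study conditions: 315 lines in two subpopulations
(162/153), 3000 markers of which 1432 are dominant, 8 chromosomes, blocky LD,
four traits with entry-mean heritabilities 0.95/0.54/0.99/0.76 (spanning the
published 0.5-0.99 range), 2 environments x 3 replications in incomplete
blocks (7 blocks per replication by default — the source trial's block
dimensions are not published, so these are configurable defaults, not a
claim about the actual layout).

* **Structure** — one Balding-Nichols Beta draw per marker per group with a
  single `fst` (default 0.2), a one-parameter control of divergence.
* **LD** — each line's two haplotypes are mosaics of a small per-group
  founder-haplotype pool (default 8), with crossover points spaced
  exponentially at mean `ld_block_len_bp` (default 1.5 Mb, inside the
  published 0.5-2.5 Mb extent range). Background LD scales inversely with
  the pool size; a pool of 2 gives block-like near-complete local LD, the
  setting used for decay-extent checks.
* **Dominant markers** — a latent 0/1/2 dose is thresholded
  (presence = dose >= 1), mimicking presence/absence scoring without a
  separate frequency model.
* **Traits** — `n_qtl` (default 100) QTL drawn among codominant markers,
  effects i.i.d. normal per trait; true breeding values are centered
  effect-weighted latent doses, kept as a ground-truth channel.
* **Trials** — plot = grand mean + env + rep + block + tbv + entry-x-env +
  residual. The residual variance is back-solved per trait so the
  single-environment entry-mean heritability hits `target_H2`, treating
  `var(tbv) + var_ge` as the heritable signal (entry and entry-by-environment
  effects are confounded within one environment) and excluding block variance
  (the mixed model absorbs it). `target_H2 = 0` with genetic variance present
  is rejected as unreachable.
* **Missingness** — independent uniform masking of calls; no informative
  mechanism is modeled (none is published).

What the simulator does **not** emulate: sequence-level artifacts of the
genotyping platform (read depth, allelic dropout, complexity reduction),
pedigree relationships and selection history within the elite panel,
spatial field trends, and real G x E covariance structure (interactions are
i.i.d.). Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to those
real-data features.

## Numerical choices and problem sizes

* EM-REML: tolerance 1e-8 relative, 500-iteration cap, 1e-10 variance floor,
  tiny (1e-10) ridge on the fixed-effect block of the MME against exact
  collinearity.
* Kernel REML: profile likelihood optimized on log10(delta) over [-8, 8]
  (grid of 81 then bounded refinement); eigenvalues clipped at 0.
* Gibbs samplers: inclusion log-odds clipped at +/-700 before the logistic;
  `beta^2` floored at 1e-12 inside inverse-Gaussian updates.
* Test and validation problem sizes are chosen to exercise each property at
  the smallest scale at which it is statistically stable: REML recovery at
  300 entries x 3 reps x 20 seeds, sampler validity at n = 500, CV
  properties at 200-300 lines with 2 repeats of 5 folds, multi-env recovery
  at 120 entries x 2 environments.

## Known limitations

* The EM-REML solver builds dense mixed-model equations; it is comfortable
  up to a few thousand random-effect levels but is not intended for
  large multi-environment series.
* Bayes B's `pi` is fixed, not estimated (the source analysis does not say
  which was used); Bayes C estimates it.
* Dominant markers contribute to kinship and to the prediction design matrix
  as centered 0/1 scores; no dominance model is fit — they are treated as
  haploid-like additive markers, mirroring how the pooled panel was used.
* Heritability uses the pairwise-difference (Piepho-Moehring) form only.
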