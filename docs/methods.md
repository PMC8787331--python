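# Methods

## DNAm age

A clock is a named linear model: intercept `m₀`, probe coefficients `mᵢ`, an
output transform, and a flag for within-sample standardisation. The score of
sample *s* over probe set *P* is `m₀ + Σ_{i∈P} mᵢ βᵢₛ`. Two conventions are
implemented as data, not code paths hard-wired per clock:

* `transform="horvath_inverse"` — the Horvath clock regresses
  `F(age) = log(age+1) − log(A+1)` for `age ≤ A` and `(age−A)/(A+1)` above,
  with adult age `A = 20`; predictions are mapped back with the continuous,
  strictly increasing inverse `x ≤ 0 → (A+1)eˣ − 1`, `x > 0 → (A+1)x + A`.
  `A` is configurable (default 20, the published constant).
* `standardize_per_sample=True` — the Zhang clock z-scores each sample's
  betas over the probe set before the dot product (population SD; a
  zero-spread sample falls back to centred values rather than dividing by
  zero). This makes scores invariant to per-sample shifts in overall
  methylation level.

Probe availability follows three policies: `drop_missing` (score over the
probes present, log the count — the default, mirroring the practice of
proceeding with a handful of absent probes rather than imputing),
`intersect_tissues` (only probes present in *every* tissue matrix, for
cross-tissue comparability) and `strict` (error on any absence). Every
output row carries `n_probes_used + n_probes_missing = clock size`, so probe
accounting is auditable downstream.

The four published coefficient tables are not redistributable here, so
`csfaging.presets` generates *synthetic* stand-in tables with the published
structure — 353 (Horvath), 71 (Hannum), 513 (Levine) and 514 (Zhang) probe
coefficients plus an `"(Intercept)"` sentinel row — exercising the loader,
intersection and scoring machinery end to end. Real tables in the same
two-column CSV dialect load unchanged.

## Synthetic cohort

The generator's defaults are the study conditions, chosen once:

| parameter | default | basis |
|---|---|---|
| participants | 273 | cohort size |
| age | N(52.9, 11.1²), truncated ≥ 18 | cohort mean (SD) |
| female / White | 0.685 / 0.872 | cohort fractions |
| Fisher grade 2/3/4 | 0.297/0.495/0.209 (renormalised) | cohort table |
| smoking (never/current/social/quit/unknown) | .322/.538/.011/.114/.015 | cohort table |
| BMI | N(28.1, 7.2²), floored at 14 | cohort mean (SD) |
| CSF slots | days 1,4,7,10,13, jitter −1/0/+1, clip [0,14] | ±1-day targeted sampling |
| retention | 850/1365 per slot, i.i.d. | 850 of 1365 possible samples analysed |
| blood subset | 72 participants, one sample at a day in 0–2 | design |
| trajectory groups | flat means −8/−2/1/5 y, probs .05/.40/.40/.15, σ = 2 | four flat groups, small extreme groups flanking large middles |
| cell types | K = 5, Dirichlet weights, two blood-like components decay `e^(−0.15·day)` | blood clearing from the subarachnoid space |
| clock noise | `noise_sd` per beta entry, default 0.005 | keeps DNAm-age/age correlation ≈ 0.95, matching the stronger clocks |

Per-slot retention is modelled i.i.d. because the real distribution of
samples per participant is not described; a participant losing all five
slots (probability ≈ 0.8%) drops out of the cohort, so simulated n can fall
a participant or two short of the configured value. All draws descend from
one seed via `numpy.random.SeedSequence` spawning; identical configurations
are byte-identical.

**Planted clock.** On the m clock probes the generator writes
`β = 0.25 + 0.5·(Tᵀw) + u·α·(age + accel − 55)` with `T` the cell profiles
restricted to those probes and `u` a random unit vector projected orthogonal
to the all-ones vector and every profile row. The clock's coefficients are
`u/α` with intercept 55, so the mixture term cancels identically and the
score equals `age + accel` to machine precision on noise-free betas — the
oracle every downstream stage is tested against. The amplitude `α = 0.004`
keeps betas inside [0, 1] without clipping for adult ages (so the inversion
is exact) while a per-probe noise SD of 0.01 perturbs the recovered age by
only `noise_sd/α · √(1/m)`-scale years (≈ 2.5 y at m = 100). Each
observation's planted acceleration is its group's polynomial mean at the
sample's time bin plus N(0, σ) noise — exactly the observation model the
trajectory fitter assumes.

What the generator does *not* emulate: probe-level chemistry (Type I/II
design, batch effects), genome-wide probe counts (only clock probes plus
filler probes for deconvolution), real CSF cytology, or any dependence of
acceleration on covariates. Passing tests therefore demonstrate the
*machinery* — estimator correctness, calibration of QC criteria under the
assumed observation model — not biological validity on real arrays.

## Reference-free deconvolution

`B ≈ T W` with `T ∈ [0,1]^{P×K}` and columns of `W` on the K-simplex,
minimising squared error by alternating projected gradient steps with exact
Lipschitz step sizes (`1/‖TᵀT‖₂` and `1/‖WWᵀ‖₂`), simplex projection by the
sort-based algorithm. Each step solves a convex subproblem, so the objective
is non-increasing — a tested invariant. Five random restarts (best objective
kept) guard against local minima; the factorisation runs on the 1000 most
variable probes by default. K = 1 short-circuits to the closed form
(weights 1, profile = per-probe mean).

Like any reference-free method the components are putative and identifiable
only up to permutation — and only when the data satisfy separability:
profiles must touch the [0, 1] bounds (cell-type-discriminating probes) *and*
near-pure samples must exist. The recovery tests construct exactly such
mixtures; on non-separable data the factorisation still fits but admits a
continuum of equivalent solutions, which is a property of the problem, not
the solver. For regression adjustment the component with the lowest
across-sample variance is dropped (ties to the lowest index) to break the
sum-to-one collinearity.

## Age acceleration

Days 0–14 map to bins {0–2, 3–5, 6–8, 9–11, 12–14}; days outside stay
unassigned. Blood rows outside bin 1 are removed before analysis. Within
each (clock × tissue × bin) stratum — never pooled — acceleration is the OLS
residual of DNAm age on chronological age, plus K−1 cell proportions in the
adjusted flavor. Residuals are mean-zero and orthogonal to every regressor
by construction (tested to 1e-8). A rank-deficient design raises an error
naming the collinear columns at the operation level; the table builder first
drops covariates that are constant *within a stratum* (they carry no
information there), so the adjusted flavor degrades gracefully to the
unadjusted fit — and strata smaller than p+2 observations are skipped with a
warning rather than fitted.

Outliers: Tukey fences at `[Q1 − 3·IQR, Q3 + 3·IQR]` on DNAm age within the
stratum, quartiles by linear interpolation (R type 7 / numpy default).
Two-sided fences are the default reading of "> 3 times the IQR"; a one-sided
(upper-fence) variant is available via `two_sided=False`. Flags are
recorded, observations retained.

## Trajectory mixtures

Participant *i* with observations `y_ij` at centred bins `t_ij = bin − 3`
contributes `Σ_g π_g Π_j f(y_ij; x(t_ij)ᵀβ_g, σ)`. Polynomial order is 0, 1
or 2 per group (the default search menu applies one order to all groups per
candidate, G = 1…6). σ is shared across groups by default (per-group σ
behind a flag). `f` is a censored normal with configurable bounds; the
default bounds are infinite (plain normal) since the appropriate bounds for
residual acceleration are not obvious — both choices are config, not
guesses baked in.

EM details: with infinite bounds the M-step is exact weighted least squares
per group plus the pooled variance update, so the log-likelihood is
monotonically non-decreasing (tested on random panels); with finite bounds a
warm-started L-BFGS maximisation of the expected complete-data
log-likelihood gives a generalized EM step (the update is kept only if it
does not decrease the objective). Initialisation is a quantile split of
per-participant means into G groups; restarts jitter the intercepts by half
the response SD. Convergence at relative log-likelihood change < 1e-8 or
500 iterations; best of `n_starts` kept; groups reported in ascending
intercept order so labels are canonical. Mixture weights are floored at
1e-10 and σ at 1e-6 to keep the likelihood finite in degenerate corners.

BIC is reported on the "larger is better" scale `loglik − ½·k·log N` with
`k = Σ_g (order_g + 1) + (G − 1) + 1` and N = participants; an
observation-count BIC is also computed since both conventions are printed by
the classic SAS macro and reports rarely say which was used.

Posterior QC: APP_g = mean posterior among modally assigned members
(≥ 0.7); OCC_g = APP odds over prior odds (> 5); |π_g − observed share_g| ≤
0.1 ("approximately equal" needs a number; 0.1 is configurable). A group
with no modal members fails with an explicit reason. The QC thresholds
behave as intended on simulations: four flat groups at −8/−2/1/5 with σ = 2
pass both bounds, while middle groups ~1 σ apart fail on OCC — the OCC
criterion binds before APP for large groups because the prior odds in its
denominator grow with π_g.

Out of scope by design: covariates inside the mixture, dual-trajectory
models, and the macro's quasi-Newton standard errors.

## Statistics

Wrappers over scipy/statsmodels with the selection rules made explicit:
Fisher's exact test for 2×2 tables with any expected count < 5, otherwise
chi-square *without* continuity correction (no exact RxC test is attempted;
larger sparse tables fall back to chi-square with a warning). Correlations
use pairwise-complete deletion, regressions listwise, and every result
echoes the n used. The five-level smoking history collapses to yes
(current/social/quit) vs no (never) for tests, with unknown treated as
missing. p-values are unadjusted.

## Problem sizes

The test suite and acceptance script run the cohort at its design size
(273 participants, ~850 CSF samples) for the trajectory analyses, which are
cheap, and at 40–200 participants with 150–300 probes for the
methylation-layer checks, where the planted-clock algebra makes correctness
independent of scale. Recovery rates (BIC model selection, group-mean
error) use 20 seeded replicates.
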