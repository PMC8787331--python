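# csfaging

Epigenetic-clock analysis of longitudinal cerebrospinal-fluid (CSF) DNA
methylation after aneurysmal subarachnoid hemorrhage (aSAH).

After an aneurysm ruptures, CSF is drained for up to two weeks through an
external ventricular drain, giving a rare serial window into the methylome of
a tissue that is otherwise inaccessible. This package implements the full
analysis chain needed to ask whether "epigenetic age" measured in CSF tracks
chronological age, how it compares with blood, and whether a patient's *age
acceleration* is stable during recovery:

1. **DNAm age** — an epigenetic clock is a linear predictor over a fixed CpG
   probe set, `DNAmAge = m₀ + Σᵢ mᵢ βᵢ`, with βᵢ the methylation beta value
   in [0, 1]. Clock presets cover the published conventions: the Horvath
   clock's piecewise age anti-transformation
   (`x ≤ 0 → 21·eˣ − 1`, `x > 0 → 21·x + 20`) and the Zhang clock's
   within-sample standardisation. Only probes available in every tissue are
   scored, and missing probes are counted, not imputed.
2. **Cell-type heterogeneity (CTH)** — no reference panel exists for CSF, so
   putative cell-type proportions are estimated reference-free by a
   constrained factorisation `B ≈ T W` (profiles `T` in [0, 1], per-sample
   weights `W` on the K-simplex, K = 5), solved by alternating projected
   gradient descent with a provably non-increasing objective.
3. **Age acceleration** — samples are collapsed into five cross-sectional
   time bins (days 0–2, 3–5, 6–8, 9–11, 12–14 post-aSAH); acceleration is
   the residual of DNAm age regressed on chronological age within each
   (clock × tissue × bin) stratum, optionally adjusting for K−1 cell
   proportions (the least-variable component dropped). Extreme DNAm ages are
   flagged with 3×IQR Tukey fences but retained.
4. **Group-based trajectory analysis (GBTA)** — a finite mixture of
   polynomial trajectories over time bins with a (censored-)normal
   observation model, fitted by EM from multiple starts. Models over group
   number G and shape (intercept-only / linear / quadratic) are compared by
   BIC (`loglik − ½·k·log N`, larger is better), and a chosen model must
   pass posterior QC: per-group average posterior probability (APP) ≥ 0.7,
   odds of correct classification (OCC) > 5, and estimated group
   probabilities ≈ observed assignment shares.
5. **Cohort statistics** — Pearson correlations, one-way ANOVA, chi-square /
   Fisher exact tests and bivariate regressions for group characterisation.

Because no cohort methylation data are publicly deposited, the package ships
a first-class synthetic cohort generator (`csfaging.simulate`) that emulates
the study design — 273 participants, CSF at targeted days 1/4/7/10/13 ± 1
with ~62% slot retention (~850 samples), a 72-participant blood subset at
days 0–2, age ~ N(52.9, 11.1²) truncated at 18 — with planted trajectory
groups, decaying blood-like cell mixtures, and an *invertible planted clock*
whose score equals `age + acceleration` exactly on noise-free betas, so every
stage is testable against known truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort, writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_compute_dnam_age.py
python analysis/03_estimate_cell_types.py
python analysis/04_age_acceleration.py
python analysis/05_trajectory_analysis.py
python analysis/06_cohort_statistics.py
```

Output of the trajectory stage (seed 173, four flat groups planted at
−8/−2/1/5 years, residual SD 2 plus clock noise):

```
[unadjusted] BIC-best: G=4, order=0, intercepts=[-7.67, -2.01, 1.1, 5.07], pi=[0.057, 0.338, 0.493, 0.111]
[unadjusted] posterior QC: passed=True (min APP=0.843, min OCC=5.52)
[cth_adjusted] BIC-best: G=4, order=0, intercepts=[-7.56, -1.91, 1.11, 4.93], pi=[0.058, 0.349, 0.479, 0.114]
[cth_adjusted] posterior QC: passed=False (min APP=0.819, min OCC=4.91)
```

The BIC search recovers the planted four flat groups in both flavors with
intercepts within ~0.4 years of truth. The unadjusted model passes posterior
QC; the CTH-adjusted model misses the OCC bound for one middle group
(4.91 < 5) — middle groups separated by only ~1.5 residual SDs sit exactly at
the edge the OCC criterion is designed to police, the same failure mode that
disqualifies weakly separated models in practice. The clock stage prints the
planted-signal check (`CSF: R = 0.951` between DNAm age and chronological
age), and the statistics stage the CSF-vs-blood concordance at time bin 1
(`R = 0.957, n = 49`).

The same chain is available as a config-driven CLI:

```bash
csf-aging all --config run.yaml --outdir out/ --seed 1
```

which writes every intermediate table plus a manifest with SHA-256 digests —
two runs with the same config and seed are digest-identical.

## Layout

```
src/csfaging/      library: simulate, clocks, presets, celltypes,
                   acceleration, trajectory, stats, pipeline, cli
analysis/          numbered narrative drivers over the library
scripts/           acceptance recomputation
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model and design notes
```
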