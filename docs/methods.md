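# Methods

This note records the models, defaults and numerical choices behind
`smfdiag`, and what the synthetic cohorts do and do not establish about real
serum data.

## Synthetic spectrum model

A cohort is defined by a `SimConfig`. Per sample the profile intensity on an
axis of `axis_points` (default 120,000) over `mz_range` (default 100–1000 Da)
is

    I(m) = g_s · Σᵢ A_{s,i} · G(m; μᵢ, σ) + B(m) + ε(m)

- **Peak catalog.** `n_species` (default 908) Gaussian species with centers
  drawn uniformly under a minimum-spacing constraint (`min_spacing`, default
  0.5 Da; hard floor 4σ) using the measure-preserving shift construction, so
  center placement is exactly uniform given the spacing. Species base areas
  are log-normal (`base_log_mean` = log 100, `base_log_sd` = 1.0), giving a
  realistic dynamic range of roughly two orders of magnitude.
- **Peak shape.** Constant-σ Gaussian; the default σ makes the FWHM about
  three axis steps (0.0096 Da at 120k points), i.e. peaks are barely
  oversampled, as in TOF profile data. Peaks are truncated at ±5σ when
  rendered. A species' "intensity" is its Gaussian *area*; heights are
  area/(σ√2π).
- **Adducts.** A fraction `adduct_fraction` (default 0.3) of species are K⁺
  partners of a Na⁺ species, offset by exactly 15.9739 Da, sharing analyte
  abundance through a correlated log-area jitter (ρ = 0.8) and ionizing
  slightly less efficiently.
- **Case/control signal.** `n_informative` species (default 4) carry fold
  changes drawn uniformly from `fold_change_range` (default 1.09–2.30),
  applied multiplicatively to case samples. Informative species are drawn
  from the adduct-unpaired pool only: a correlated partner would act as a
  noise-cancelling covariate and push the true Bayes AUC above the closed
  form used for calibration (below).
- **Noise.** Three knobs: a global per-sample log-normal scale
  (`sample_cv` = 0.15), per-sample per-peak log-normal area jitter
  (`peak_jitter_sd` = 0.30) — the dominant biological/technical variation —
  and additive truncated-Gaussian (≥ 0) detector noise (`noise_sd` = 20,
  versus a median peak height of ≈ 4200). The baseline is a single
  exponential decay (amplitude 500, length 150 Da), the simplest shape that
  exercises baseline correction.
- **Bayes AUC.** Because the group difference is a pure mean shift in
  independent log-areas, the optimal discriminant is linear in the
  informative log-features and AUC* = Φ(√(Σ (log fcᵢ/τ)²)/√2).
  `tuned_config(cfg, a)` inverts this for τ so a cohort has Bayes AUC `a`.
  The default jitter (0.30) was calibrated once so that, with all other
  defaults, within-group cosine similarity exceeds 0.9 for well over 90% of
  samples — the reproducibility regime serum-fingerprint studies report —
  and was not adjusted afterwards.

What the simulator does **not** model: ionization physics, isotope fine
structure, instrument drift, m/z-dependent peak width, chemical-noise
structure, or realistic inter-metabolite correlation beyond adduct pairing.
Passing recovery tests on these cohorts therefore demonstrates that the
pipeline's statistics behave as designed under a known truth — not that any
particular clinical performance would be attained on real sera.

## Preprocessing

Savitzky–Golay smoothing (window 7, order 2; window 1 = pass-through), then
morphological baseline correction (rolling minimum followed by rolling
maximum, half-window 100 points ≈ 0.75 Da — wide against peaks, narrow
against the baseline), then local-maxima peak picking. A peak is a strict
local maximum (plateaus resolve to their midpoint via the underlying
scipy machinery); peaks closer than `min_separation` (default 0.045 Da ≈ 2×
the default FWHM) are thinned keeping the taller.

**SNR definition.** Non-negative detector noise leaves a positive floor after
baseline subtraction, so SNR is measured *above the floor*:
SNR = (height − median)/(1.4826·MAD), both statistics over the whole
spectrum (peaks occupy a small fraction of points, so the median/MAD see
noise). If the MAD degenerates to zero, the above-median points are retried
only when they are plentiful (> 20% of points); in a noiseless spectrum the
scale stays 0 and every positive local maximum is kept. The default
threshold is SNR ≥ 3.

**Alignment.** Pooled peak m/z are single-linkage chained at the alignment
tolerance (default 0.1 Da) and chains wider than the tolerance are split
recursively at their largest internal gap; the feature m/z is the
intensity-weighted member mean; each sample contributes at most one peak per
feature (nearest to the center); absent peaks are 0 — absence of an ion is
informative in LDI-MS, and zeros keep the matrix dense for L1 models.

**Prevalence filter.** A 3σ-style SNR rule cannot control the ~20,000
candidate maxima of a 120k-point profile, so single-spectrum peak lists
contain noise maxima. Genuine species recur across samples at the same m/z
while noise lands at random positions; features detected in fewer than 25% of
samples are therefore dropped (the same reasoning as MALDIquant's
`filterPeaks`). The per-operation contracts (e.g. a feature unique to one
sample surviving `align_peaks`) are unaffected — the filter is a separate,
optional step.

**Normalization and QC.** TIC normalization scales each sample to unit total
and rescales by the cohort-median total; all-zero rows are left untouched
with a warning. Cosine QC scores each sample against the leave-one-out mean
of *unit-normalized* group rows, which makes the score exactly invariant to
per-sample positive scaling.

## Sparse learning

L1-regularized logistic regression (mean deviance + λ‖w‖₁, intercept
unpenalized), solved by FISTA with adaptive restart; the Lipschitz constant
comes from a deterministic power iteration on the augmented design. Features
are standardized on the training rows inside the solver and weights are
returned in the original scale; weights are exactly zero below 1e-10 after
soft-thresholding. The solver is validated on random instances against an
independent projected-gradient solver (the split w = a − b with
non-negativity projections) to 1e-4 in objective.

- **Penalty grid.** Ten log-spaced values from λ_max = max|X̃ᵀ(y−ȳ)|/n (the
  analytic all-zero threshold) down three decades; path fits descend with
  warm starts.
- **Penalty choice.** Mean cross-validated AUC over 2 rounds × 5 stratified
  folds; "ties toward the sparser model" is implemented as the
  one-standard-error rule (a tie is any penalty within one SE of the best).
  This keeps label-permuted nulls at the empty end of the path — with exact
  ties only, a null cohort picks an arbitrary overfit penalty and spuriously
  "stable" features appear at ~1.4% of features; with the one-SE band they
  fall below 1% while signal cohorts at discovery scale are unchanged.
  `one_se=False` restores plain argmax.
- **Ensemble.** 20 rounds × 5 stratified folds = 100 models at the single
  tuned λ (one global penalty rather than per-fold tuning keeps the 100
  models comparable and the selection frequencies interpretable). Each
  model's AUC is computed only on its held-out fold; fold plans are seeded
  per round and reproducible. When stratification is impossible (folds
  exceeding the smallest class, e.g. leave-one-out) plain shuffled folds are
  used and single-class folds carry NaN AUC, ignored by the optimized-model
  choice. The "optimized model" is the best validation AUC, ties toward
  fewer nonzero weights, then lower index.
- **Reference classifiers.** Decision tree, unpenalized logistic regression,
  RBF SVM (decision-function scores), kNN and random forest at scikit-learn
  defaults, as comparators only.

## Stability selection and the panel

Selection frequency counts models with nonzero weight per feature; the
univariate p-value is the two-sided Mann–Whitney U (rank-based, robust to
intensity skew; raw by default, Benjamini–Hochberg correction is available
through `statsmodels` if desired by callers); fold changes are
mean(case)/mean(control) on the normalized intensity (never log) scale. The
stable set requires frequency ≥ 95/100 AND p < 0.05, ordered by frequency,
then mean |weight|, then ascending m/z — a total order. The panel takes the
top k = 4 and refits from scratch with a re-tuned penalty (truncating the
full model would miscalibrate the intercept). Discovery-style panel
evaluation pools out-of-fold probabilities from a fresh CV ensemble on the
panel columns; validation-style evaluation applies the fixed panel model to
an external matrix without refitting.

Recovery claims are scale-dependent. At discovery scale (357/374, 908
species, Bayes AUC 0.95) all four planted markers reach frequency ≥ 95 and
the stable set contains little else; at reduced scale (~240 samples) the
weakest fold changes (1.1–1.3) sit at the resolution limit, and in very easy
regimes the CV-AUC saturates so the sparsity tie-break legitimately discards
redundant markers. The tests assert the exact-recovery property only at
discovery scale.

## Diagnostics

- AUC is the rank statistic (midrank ties), verified exhaustively against
  concordant-pair counting for n ≤ 50.
- CIs are stratified percentile bootstrap (B = 2000, cases and controls
  resampled separately, seeded); the reported interval is clamped to contain
  the point estimate.
- The operating point maximizes the Youden index; ties take the lower
  threshold (favoring sensitivity). A fixed threshold can be supplied
  instead, and reports always store enough to recompute
  sensitivity/specificity.
- AUC comparison is a paired stratified bootstrap (two-sided, null-centered,
  with a +1/(B+1) continuity floor), sharing machinery with the CI code;
  DeLong's test is the classical alternative.
- Power: closed form is the two-sided two-sample normal approximation
  Φ(d√(n/2) − z_{1−α/2}) + Φ(−d√(n/2) − z_{1−α/2}); Monte Carlo simulates
  Welch t-tests. The two agree to < 0.02 across the default grid.
- Propensity matching: logistic propensity, greedy nearest-neighbour 1:ratio
  on the logit without replacement, caliper 0.2 × sd(logit) (common
  practice), treated units in seeded random order; unmatched treated are
  reported. With a tight caliper greedy matching can strand units even under
  identical covariate distributions — that is expected behavior, not an
  error.

## Problem sizes used by the reference experiments

The packaged experiments (`smfdiag.experiments`, used by
`scripts/acceptance.py` and the analysis drivers) run the full pipeline at
discovery scale — 357 cases / 374 controls, 908 species, 120k-point spectra,
100-model ensembles — over five seeds, plus a ten-permutation label null on
one such cohort. The cosine-QC calibration uses 50 samples per group: the
per-sample score distribution is governed by the noise knobs, not by group
size, so this estimates the pass fraction without re-simulating the largest
cohort. The analysis drivers default to a 120/120 × 300-species cohort
(`--full` switches to discovery scale) so a reader can replay the narrative
in about a minute.

## Known limitations

- The intensity distribution of real serum fingerprints is unknown; the
  log-normal choice is a modeling stand-in, not an inference from data.
- No m/z recalibration across instruments, no isotope deconvolution, no
  adduct collapsing (Na⁺/K⁺ features stay separate in the fingerprint).
- Bootstrap p-values below ~1/B are reported at the continuity floor.
- The mzML support is deliberately minimal (single profile spectrum per
  file, PSI accessions for the two arrays, f4/f8, zlib/plain); it is not a
  general mzML implementation.

One consequence worth stating explicitly: under the joint-Bayes calibration a
cohort can contain a planted marker whose individual effect is nearly null
(fold change at the bottom of the range drawn alongside two strong markers
pushes the calibrated jitter up). Such a marker is not recoverable at a 95%
selection frequency by any method that also keeps permutation nulls at the
sparse end — the stable set and the panel are then smaller, and the panel is
built from the markers that do carry signal.
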