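# smfdiag — serum metabolic fingerprint diagnostics

`smfdiag` implements a complete diagnostic workflow for serum metabolic
fingerprints (SMFs) recorded by nanoparticle-assisted laser
desorption/ionization mass spectrometry (LDI-MS): raw ~120,000-point profile
spectra over *m/z* 100–1000 are reduced to a fingerprint of aligned peak
intensities, a sparse-learning classifier separates cases from controls, and a
small metabolic biomarker panel is distilled from the full fingerprint by
stability selection. The motivating application is case/control diagnosis in
autoimmune disease (e.g. systemic lupus erythematosus against healthy
controls), where cohorts of several hundred sera are fingerprinted in minutes
and the question is whether a handful of small-molecule markers carries the
diagnostic signal of the whole profile.

Because serum cohorts of this kind are not publicly deposited, the package
ships a first-class synthetic-cohort generator with known ground truth (peak
catalog, informative species, fold changes, Na⁺/K⁺ adduct pairs), so every
stage is testable end to end and recovery claims can be checked against a
closed-form optimum.

## The model

Each sample's spectrum is reduced to a vector **x** of aligned peak
intensities (TIC-normalized, log1p-transformed for modeling). The diagnostic
core is L1-regularized logistic regression,

    min over (w, b) of  (1/n) Σᵢ log(1 + exp(−sᵢ(w·xᵢ + b))) + λ‖w‖₁ ,

solved by accelerated proximal gradient (FISTA) with internal feature
standardization. The penalty λ is tuned by cross-validated AUC with the
one-standard-error rule, then the estimator is refit as an ensemble of
**20 rounds × 5-fold stratified cross-validation = 100 models**, each scored
by ROC AUC on its held-out fold. Downstream:

- **Stability selection.** A feature is *stable* if it receives nonzero
  weight in ≥ 95 of the 100 models **and** its two-sided Mann–Whitney p-value
  is < 0.05. Stable features are ranked by selection frequency, then mean
  absolute weight.
- **Biomarker panel.** The top-k stable features (k = 4 by default) are refit
  as a standalone sparse model with a re-tuned penalty, and evaluated like any
  diagnostic: AUC with stratified percentile-bootstrap 95% CI,
  Youden-threshold sensitivity/specificity, paired-bootstrap AUC comparison
  against the full profile, and single-marker AUCs.
- **Calibrated difficulty.** In the simulator the only case/control difference
  is a log-area shift of the informative species, so the Bayes-optimal AUC has
  the closed form Φ(Δ/√2) with Δ² = Σᵢ (log fcᵢ / τ)²; the jitter τ can be
  tuned so a cohort has any target Bayes AUC (0.95 by default), giving an
  absolute yardstick for what the ensemble recovers.

## Worked example

The numbered drivers under `analysis/` run the whole study on a reduced
synthetic cohort (120/120 samples, 300 species, Bayes AUC calibrated to 0.95;
pass `--full` for the 357/374 × 908-species scale):

```bash
python analysis/01_simulate_and_fingerprint.py --seed 1
python analysis/02_train_sparse_ensemble.py   --seed 1
python analysis/03_select_biomarker_panel.py  --seed 1
python analysis/04_evaluate_diagnostics.py    --seed 1
python analysis/05_power_and_matching.py      --seed 1
```

Printed output (seed 1, abridged):

```
fingerprint: 240 samples x 933 aligned m/z features
100 models trained; mean validation AUC 0.944 (sd 0.029)
held-out AUC by method: sparse_learning 0.931, decision_tree 0.667,
  logistic_regression 0.508, svm 0.470, knn 0.444, random_forest 0.800
feature funnel: 933 aligned features -> 4 stable (frequency >= 95/100, p < 0.05) -> panel of 4
  m/z   673.359  frequency 100  p 2.11e-17  fold change 1.75
  m/z   558.179  frequency 100  p 3.77e-16  fold change 1.78
  m/z   925.568  frequency 100  p 4.11e-17  fold change 1.76
  m/z   938.663  frequency 100  p 1.58e-10  fold change 1.50
ground truth: 4/4 panel members are planted markers
full fingerprint (optimized model, in-cohort): AUC 0.956 (95% CI 0.930-0.977)
biomarker panel: AUC 0.955 (95% CI 0.928-0.976); panel AUC loss +0.002
single-marker AUCs: {'673.3593': 0.817, '558.1790': 0.804, '925.5681': 0.814, '938.6632': 0.739}
power at d=0.5, n=64/group: closed form 0.807, Monte Carlo 0.799
```

Reading this: the ensemble's mean held-out AUC (0.944) sits within a hair of
the cohort's analytic Bayes optimum (0.95); the stability screen funnels 933
features down to exactly the four planted markers; the 4-marker panel matches
the full fingerprint's AUC (loss ≈ 0), while each marker alone is a mediocre
classifier (AUC 0.74–0.82) — the panel, not any single metabolite, carries
the signal. The five standard classifiers trained on the same matrix do much
worse, the expected behavior when a few weak features hide among ~900.

A `smfdiag` console command exposes the same stages
(`simulate`, `preprocess`, `train`, `select`, `run-all`) for file-based use,
including mzML and two-column CSV spectra.

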