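# mirspec

Serum mid-infrared (MIR) metabolic fingerprinting for prognosis: spectral
pre-treatment, factor-adjusted wavenumber selection, linear-discriminant
classification under Monte Carlo cross-validation, and ROC-based comparison
against clinical severity scores.

## The problem

In decompensated cirrhosis (ascites), clinicians rank patients for
transplantation with composite scores — MELD, built from bilirubin,
creatinine and INR, and the five-component Child-Pugh score — whose
discrimination for 6-month mortality is moderate (AUROC ≈ 0.75–0.80). A
drop of serum measured by mid-infrared spectroscopy captures a broadband
metabolic fingerprint (proteins, lipids, sugars, nucleic-acid turnover) in
one measurement. The question this package's pipeline answers: can a small
panel of absorbance wavenumbers, chosen reproducibly from ~600 candidates
with only ~100 patients, out-predict the clinical scores?

The statistical core:

- **Pre-treatment** of each spectrum: restriction to 3200–950 cm⁻¹,
  replacement of the CO₂-contaminated 2800–1800 cm⁻¹ region by a chord, a
  13-point Savitzky-Golay second derivative (band sharpening + baseline
  removal), extraction of the analysis domain [962, 1800] ∪ [2800, 3188]
  (exactly 615 variables), and scaling to unit Euclidean norm.
- **Selection**: 200 runs on random 90% subsamples; each run projects out
  the dominant within-class correlation with a latent-factor model, orders
  candidates by discriminant gain (stepwise-discriminant F-to-enter) and
  passes a permutation entry gate; wavenumbers selected most often (~30)
  survive, and backward elimination under 100-run 90/10 Monte Carlo CV AUROC
  prunes them to a 7–12 panel.
- **Classification**: pooled-covariance LDA, w = Σ⁻¹(μ₁ − μ₀), scores mapped
  to P(death) by the logistic; 100-run 90/10 Monte Carlo CV with per-run
  holdout AUROC and Youden cut-offs (J = sensitivity + specificity − 1).
- **Evaluation**: Mann-Whitney AUROC, DeLong's test for correlated ROC
  curves (spectral model vs MELD vs Child-Pugh on the same patients), and a
  Spearman rank-correlation network between markers and clinical labs.
- **Synthetic cohorts** with known ground truth — Gaussian absorption bands
  with class-differential markers, realistic covariate marginals, and a
  closed-form effect calibration AUC = Φ(Δ/√2) — so every stage is testable.

## Worked example

```python
from dataclasses import replace
from mirspec import (CohortConfig, CVConfig, calibrate_effect, compare_models,
                     fit_lda, mc_cross_validate, preprocess_set, score,
                     simulate_cohort)

base = CohortConfig(seed=42)                       # 116 patients, 23 deceased
scale = calibrate_effect(0.90, base, pilot_n=2000) # aim: Bayes AUROC 0.90
spectra, cohort, truth = simulate_cohort(replace(base, effect_scale=scale))
proc = preprocess_set(spectra)                     # 116 x 615, unit-norm rows
X = proc.select_wavenumbers(truth.informative_wavenumbers)

rep = mc_cross_validate(X, proc.labels, CVConfig(seed=42))
print(rep.mean_auroc, rep.auroc_ci, rep.mean_cutoff)

model = fit_lda(X, proc.labels)
comp = compare_models({"MIR": score(model, X),
                       "MELD": cohort.frame["meld"].to_numpy(float),
                       "Child-Pugh": cohort.frame["child_pugh"].to_numpy(float)},
                      proc.labels)
```

Running `python examples/04_classify_and_evaluate.py` (which is the script
form of the snippet) prints:

```
Monte Carlo cross-validation (100 runs, 90/10 stratified):
  mean AUROC 0.855  (CI95 0.624-1.000)
  mean Youden cut-off 0.25
  sensitivity 0.62  specificity 0.85 (at the mean cut-off)
  samples misclassified every time they were held out: 17

full-population spectral model: AUROC 0.885 (DeLong CI95 0.82-0.95)
AUROCs: {'MIR': 0.885, 'MELD': 0.876, 'Child-Pugh': 0.762}
  MIR vs MELD: difference +0.009, DeLong p = 0.8582
  MIR vs Child-Pugh: difference +0.123, DeLong p = 0.0465
  MELD vs Child-Pugh: difference +0.114, DeLong p = 0.1084
```

Reading it: the cross-validated AUROC (0.855) is the honest estimate of how
the 7-marker LDA generalizes on this particular 116-patient draw — the
cohort realizes the calibrated population separation only up to sampling
noise, so individual cohorts land anywhere around the 0.90 target. The
full-population AUROC (0.885) refits on everyone and is optimistic by
construction; it is what the DeLong comparison uses, showing the spectral
model clearly ahead of Child-Pugh (p = 0.047) but statistically tied with
MELD on this draw. The mean Youden cut-off (0.25) is the probability
threshold that balanced sensitivity and specificity across the 100 holdout
sets.

The other `examples/` scripts walk the remaining capabilities: cohort
simulation (`01`), pre-treatment and quality control (`02`), two-phase
wavenumber selection (`03`), and the marker-covariate Spearman network
(`05`). `docs/methods.md` documents the models, defaults and design
decisions.

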