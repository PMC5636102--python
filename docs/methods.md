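# Methods

`mirspec` implements a serum mid-infrared (MIR) prognostic analysis chain —
spectral pre-treatment, factor-adjusted wavenumber selection under Monte
Carlo resampling, linear discriminant classification with Monte Carlo
cross-validation, ROC/Youden/DeLong evaluation against clinical severity
scores, and a Spearman marker network — together with a synthetic cohort
generator that emulates a cirrhosis-with-ascites cohort (116 analyzed
patients, 6-month mortality 23/116 = 20%) so that every stage can be tested
against known ground truth.

## Spectral pre-treatment

Raw absorbance spectra live on a 2 cm⁻¹ grid. The chain is:

1. **Work domain** — restrict to 3200–950 cm⁻¹ (1126 points). The fingerprint
   and CH-stretch regions hold essentially all serum biomolecule absorption.
2. **CO₂ gap** — replace the open interval (2800, 1800) cm⁻¹ with the straight
   chord between the endpoint absorbances. The region contains the ambient-air
   CO₂ doublet (~2349 cm⁻¹) and no useful serum bands; the endpoints are kept
   verbatim, making the operation idempotent.
3. **Second derivative** — a single 13-point Savitzky-Golay second-derivative
   filter, polynomial order 2, scaled by 1/h² (h = 2 cm⁻¹). Order 2 and order 3
   share identical second-derivative coefficients on a symmetric window.
   Derivatives sharpen overlapping bands and annihilate linear baselines
   (the filter is exact on polynomials of degree ≤ 2, which the tests use as
   an oracle). No edge padding: 6 points are dropped per edge, 1126 → 1114
   points spanning 3188–962 cm⁻¹.
4. **Analysis domain** — keep [962, 1800] ∪ [2800, 3188] (gap interior removed,
   endpoints retained): 420 + 195 = **615 variables**. This count is an
   invariant asserted throughout; padded or endpoint-exclusive variants give
   621–627 and are rejected.
5. **Vector normalization** — scale each 615-vector to unit Euclidean norm,
   removing effective path-length / amount-of-sample differences. "Whole
   spectral range" here means the 615-point analysis vector that enters the
   classifier, not the raw acquisition range.

**Quality test.** A raw-spectrum gate with two configurable thresholds: peak
absorbance in the amide region 1700–1600 cm⁻¹ must lie in [0.05, 2.0] AU
(detector linearity range) and the RMS of the linearly detrended 2200–2000
cm⁻¹ window (band-free in serum) must be ≤ 0.005 AU. These thresholds are this
package's own choices of sensible instrument limits; they are deliberately
loose enough that the default generator passes with wide margin.

**Outlier screen.** Visual PCA checking is automated as Hotelling T² on the
first 10 principal-component scores against the in-model F-based control
limit at α = 0.025. Flagged samples are reported, never silently removed —
in small prognostic cohorts an "outlier" may simply be a sick patient.

## Synthetic cohorts

Spectra are sums of Gaussian bands on the 950–3200 cm⁻¹ grid: seven marker
bands at 2925, 1496, 1468, 1316, 1078, 1030 and 972 cm⁻¹ (lipid CH₂, aromatic
ring, CH₂ bending, amide III, nucleic-acid/sugar PO₂⁻, RNA/polysaccharide C–O,
all-trans lipid) carrying a multiplicative class amplitude shift, plus ≥ 10
non-discriminative background bands (amide I/II dominate at 0.45/0.28 AU), a
random low-order Chebyshev baseline (~0.01 AU), a CO₂ artifact band at
2349 cm⁻¹, per-band lognormal amplitude jitter (σ = 0.08), a common lognormal
path-length factor (σ = 0.05) and white noise (0.002 AU). Gaussian rather than
Lorentzian/Voigt line shapes keep the derivative behaviour qualitatively right
while the calibration math stays closed-form. A multiplicative class effect
mimics concentration differences and survives vector normalization. Band
centers are snapped to the 2 cm⁻¹ grid for ground-truth bookkeeping (2925 →
2924). Every sample's spectrum is generated from an RNG stream keyed by
(seed, sample index), so cohorts are bit-reproducible.

Clinical covariates are drawn *independently given outcome* from per-group
marginals (mean ± SD per class, e.g. bilirubin 49.0 ± 54.1 alive vs
144.6 ± 183.7 µmol/L deceased; MELD 14.9 ± 4.8 vs 21.4 ± 8.2). Strongly
right-skewed positive labs (creatinine, bilirubin, AST, ALT, GGT, ALP, CRP)
use a moment-matched lognormal — a clamped Normal with CV > 1 would either
produce impossible negative values or, clamped, inflate the group mean by
~15%, breaking the mean-reproduction property the tests assert.
Approximately symmetric variables (age, albumin, prothrombin ratio, INR,
sodium, MELD, Child-Pugh) stay Normal with clamps that essentially never
bind (e.g. sodium ≥ 110 mmol/L). Independence given class is a documented
limitation: the real between-covariate correlation structure is not
emulated, so marker-covariate network edges in synthetic data arise only
through the shared outcome.

`compute_meld` (UNOS formula, arguments floored at 1.0 mg/dL, creatinine
capped at 4.0, result clipped to [6, 40]) and `compute_child_pugh` (five
components banded 1–3 points) are provided as conveniences; the generator
draws the scores directly from their per-class marginals rather than
deriving them, because ascites and encephalopathy grades are not part of
the covariate table.

**Effect calibration.** For equal-covariance Gaussian classes the Bayes AUROC
is Φ(Δ/√2), Δ the Mahalanobis separation. `calibrate_effect(a)` simulates a
balanced 2000-sample pilot, measures Δ of the processed class means over the
marker wavenumbers, and rescales the class shift twice (the map effect → Δ is
locally linear). The calibration invariant — LDA on a fresh n = 4000 cohort
reaches the target AUROC within ±0.015 — is asserted in the tests. Note that
a *particular* n = 116 cohort realizes this population separation only up to
sampling noise (sd(Δ̂) ≈ 0.25), which dominates the spread of cross-validated
AUROC across cohort draws.

## Wavenumber selection

Phase 1 runs 200 times; each run draws a stratified random 90% subsample
and then:

1. **Factor adjustment.** The shared within-class correlation (band jitter,
   path-length, baseline — structure common to many variables and
   uninformative about outcome) is modelled by the leading principal axes of
   the within-class standardized data. The number of factors k ≤ 8 is chosen
   by an elbow rule on the mean squared off-diagonal of the residual
   covariance (computed from the eigenvalue spectrum in O(p·k); the residual
   diagonal is not re-normalized — the elbow location is the same and the
   full p×p residual never needs to be formed). Adjustment subtracts the
   regression reconstruction from within-class-centered data, so class means
   are preserved exactly and the operation is idempotent. Independent-noise
   data yield k = 0 (identity).
2. **Forward selection**, classical stepwise-discriminant style. Candidates
   are ordered by the marginal discriminant gain d²/var (the F-to-enter of
   diagonal-covariance stepwise LDA), a closed-form statistic. Two designs
   were evaluated and rejected: ranking by cross-validated error maximizes
   over ~600 noisy estimates, and its winner's-curse inflation (~0.05 in
   balanced-error units per step) buries genuine moderate variables; ranking
   by the full conditional gain adds O(|S|/√n) estimation noise from chance
   correlations with already-selected strong variables. After factor
   adjustment residuals are quasi-uncorrelated, which is precisely the
   regime where the diagonal rule is the better bias-variance trade-off.
   Whether a run selects *anything* is decided by a **permutation entry
   gate**: the best candidate's cross-validated one-variable AUROC lift must
   exceed the maximum lift over 9 label-permuted versions of the same data
   plus one standard deviation of those permuted lifts. Under a
   label-independent dataset, original and permuted data are exchangeable,
   so a null run selects something with probability < 1/10. Chance
   associations *within* a dataset are present in its validation folds too,
   so no within-dataset stopping rule can screen them; the gate acts at the
   only point where a valid null reference exists. Runs that pass the gate
   select up to 15 variables in gain order; judging which of those entries
   are *stable* is the job of the histogram, not of a single run.
3. **Histogram retention.** Selections are counted per wavenumber over the
   200 runs; retention keeps the top ≈ 30 by count (ties broken toward lower
   wavenumber), or applies an explicit frequency threshold if one is given.

Phase 2 (`optimize_subset`) prunes the survivors by greedy backward
elimination: drop whichever variable's removal maximizes mean AUROC over
100 shared, pre-drawn stratified 90/10 Monte Carlo splits; stop at the lower
end of the 7–12 target range or when the best removal costs more than 0.005
mean AUROC.

On spectral data, adjacent grid points are near-duplicates by construction —
a 13-point filter's impulse response makes neighbours carry ≥ 13/14 of a
point signal — so histogram mass spreads over each marker band's
neighbourhood and the final panel lands on or next to marker centers rather
than exactly on them. This is physics, not a defect, and the backward phase
resolves each band to a single representative.

## Classification and evaluation

`fit_lda` is pooled-covariance LDA with a relative ridge (1e-8 × mean
diagonal) and empirical priors; `score` maps the discriminant through the
logistic to a posterior probability of death, so cut-offs live on a
probability scale. `youden_cutoff` scans midpoints of adjacent sorted unique
scores plus ±∞, maximizing J = sensitivity + specificity − 1 (ties → higher
specificity, then lower cut-off; positive means score strictly above the
cut-off). `mc_cross_validate` performs 100 stratified 90/10 splits (at
n = 116 each holdout is 2 deceased + 10 alive), records holdout AUROC and
Youden cut-off per run, then recomputes sensitivity/specificity per run at
the across-run mean cut-off and accumulates per-sample held-out /
misclassified counts at that same cut-off. Runs with a single-class holdout
(possible only unstratified) are dropped with a warning, never imputed.

AUROC uses the Mann-Whitney pair-count estimator with ties counted ½ (the
curve itself comes from a standard threshold sweep). CIs over CV runs are
empirical 2.5/97.5 percentiles (linear interpolation); `delong_ci` provides
the analytic alternative for a single fitted model. `delong_compare`
implements the placement-value test for correlated ROC curves with a
two-sided normal p (identical scores → p = 1 by convention). Model
comparison (spectral model vs MELD vs Child-Pugh) uses the full-population
fitted model, which is optimistic by construction — the CV summary is the
honest generalization estimate — and reports raw pairwise p-values without
multiplicity correction. The Spearman network tests every marker-marker and
marker-covariate pair (mid-rank ties, t-approximation p), keeps raw
p < 0.05 edges by default, offers Benjamini-Hochberg as an option, and
skips constant variables with a warning.

## Problem sizes and numerical choices

Simulation-based checks use the study geometry where it matters (n = 116,
23/93, 100-run CV; 200-run selection at n = 150, p = 615) and scale only
where a property demands it: the null-pipeline soundness check runs at
n = 1160 because the irreducible null sd of a single-cohort AUROC at
n = 116 is ≈ 0.074, wider than any band that could certify "no systematic
optimism" — at 10× the size the same check is sharp (sd ≈ 0.03). The
DeLong-vs-bootstrap cross-check resamples m−1 out of m per class (the plain
bootstrap biases the variance of a class mean low by (m−1)/m, ~25% at
m = 4). Degenerate inputs fail loudly: all-zero spectra cannot be
normalized, single-class labels are rejected everywhere, covariance
matrices are ridged and Cholesky-checked.

## Known limitations

- Covariates are conditionally independent given outcome; real lab-lab
  correlations (renal-hepatic axes, etc.) are absent.
- Gaussian band shapes and white noise omit water-vapour rotational
  structure, detector drift and fibre-contact variability.
- The quality-test thresholds are plausible defaults, not instrument-derived.
- The permutation entry gate bounds the *marginal* null entry rate; a
  dataset whose realized chance leader is extreme can still enter more
  often than 1/10 (the conservative +1 sd margin mitigates this).
- LDA assumes a shared covariance; the multiplicative class effect makes
  deceased-class variance slightly larger at marker bands, a mild,
  deliberate model misspecification.

What passing tests show is that the chain recovers what the generator
planted under the stated geometry; they cannot certify performance on real
serum spectra, whose artifact structure is richer than the emulation.
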