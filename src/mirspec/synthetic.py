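"""Synthetic two-class serum MIR cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: absorbance spectra on the 950-3200 cm^-1 grid (2 cm^-1 step) built
from Gaussian absorption bands, a low-order baseline, an ambient-CO2 artifact
at 2349 cm^-1 and white detector noise, together with a clinical covariate
table whose per-group means and SDs follow the published cirrhosis-with-
ascites cohort (n = 116, 23 deceased at 6 months).

Seven bands — the wavenumbers the prognostic model selected (2925, 1496,
1468, 1316, 1078, 1030, 972 cm^-1) — carry a class-differential amplitude
shift; everything else is non-discriminative background.  The shift is
multiplicative (a concentration change), so it survives vector
normalization.  ``calibrate_effect`` scales all shifts so the processed-space
Mahalanobis separation matches a requested Bayes AUROC via
``AUC = Phi(Delta / sqrt(2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from .io import CohortTable, SpectraSet, Spectrum, Stage, ValidationError
from .preprocess import PreprocessConfig, preprocess_set

__all__ = [
    "BandSpec",
    "CohortConfig",
    "GroundTruth",
    "default_band_library",
    "default_covariate_spec",
    "simulate_spectrum",
    "simulate_cohort",
    "calibrate_effect",
    "delta_for_auc",
    "auc_for_delta",
    "compute_meld",
    "compute_child_pugh",
    "TABLE_BANDS",
]


class DomainError(ValueError):
    """An argument is outside its mathematical domain."""


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_shift`` is the fractional amplitude difference of the deceased
    group relative to the alive group (0 for background bands); it is further
    multiplied by the cohort-level ``effect_scale``.
    """

    center: float       # cm^-1
    fwhm: float         # cm^-1
    amplitude: float    # AU
    class_shift: float = 0.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be non-negative")


#: the seven prognostic marker bands (centers in cm^-1) with their standard
#: vibrational assignments
TABLE_BANDS: Dict[float, str] = {
    2925.0: "nu_as CH2 acyl chains (stretching)",
    1496.0: "aromatic ring",
    1468.0: "delta CH2 (bending)",
    1316.0: "amide III, protein",
    1078.0: "PO2- nucleic acid / C-C and C-O endo-ring in sugars",
    1030.0: "nu(C=O); RNA and exo-ring in polysaccharides",
    972.0: "delta; all-trans lipid",
}


def default_band_library() -> List[BandSpec]:
    """Marker bands (nonzero class shift) plus serum background bands."""
    markers = [
        BandSpec(2925.0, 22.0, 0.050, +0.060, TABLE_BANDS[2925.0]),
        BandSpec(1496.0, 12.0, 0.035, -0.050, TABLE_BANDS[1496.0]),
        BandSpec(1468.0, 12.0, 0.040, +0.050, TABLE_BANDS[1468.0]),
        BandSpec(1316.0, 14.0, 0.030, -0.045, TABLE_BANDS[1316.0]),
        BandSpec(1078.0, 16.0, 0.050, +0.050, TABLE_BANDS[1078.0]),
        BandSpec(1030.0, 14.0, 0.045, -0.050, TABLE_BANDS[1030.0]),
        BandSpec(972.0, 12.0, 0.030, +0.045, TABLE_BANDS[972.0]),
    ]
    background = [
        BandSpec(3064.0, 35.0, 0.030, 0.0, "amide B / aromatic CH stretch"),
        BandSpec(2960.0, 20.0, 0.045, 0.0, "nu_as CH3"),
        BandSpec(2853.0, 18.0, 0.035, 0.0, "nu_s CH2 acyl chains"),
        BandSpec(1741.0, 18.0, 0.025, 0.0, "nu(C=O) ester, lipids"),
        BandSpec(1650.0, 42.0, 0.450, 0.0, "amide I, protein"),
        BandSpec(1548.0, 36.0, 0.280, 0.0, "amide II, protein"),
        BandSpec(1400.0, 26.0, 0.060, 0.0, "nu_s COO-"),
        BandSpec(1243.0, 30.0, 0.050, 0.0, "amide III / nu_as PO2-"),
        BandSpec(1160.0, 22.0, 0.040, 0.0, "nu(C-O) carbohydrates"),
        BandSpec(1120.0, 18.0, 0.030, 0.0, "nu(C-O) / skeletal"),
    ]
    return markers + background


#: per-class (alive, deceased) mean and SD of each clinical covariate, in the
#: cohort table's units, plus the sampling family used for the draw
_LOGNORMAL = "lognormal"
_NORMAL = "normal"
_NORMAL_INT = "normal_int"


def default_covariate_spec() -> Dict[str, dict]:
    """Per-variable, per-class marginals of the emulated cirrhosis cohort."""
    return {
        "age": dict(alive=(56.7, 14.4), deceased=(59.9, 9.8), family=_NORMAL, lo=18.0, hi=100.0),
        "creatinine": dict(alive=(81.9, 51.2), deceased=(127.2, 145.1), family=_LOGNORMAL),
        "albumin": dict(alive=(30.0, 4.6), deceased=(28.2, 5.1), family=_NORMAL, lo=10.0, hi=60.0),
        "bilirubin": dict(alive=(49.0, 54.1), deceased=(144.6, 183.7), family=_LOGNORMAL),
        "prothrombin_ratio": dict(alive=(56.7, 13.6), deceased=(46.6, 14.1), family=_NORMAL, lo=5.0, hi=100.0),
        "inr": dict(alive=(1.58, 0.39), deceased=(1.89, 0.45), family=_NORMAL, lo=0.8, hi=10.0),
        "sodium": dict(alive=(135.8, 4.1), deceased=(132.9, 3.9), family=_NORMAL, lo=110.0, hi=160.0),
        "ast": dict(alive=(84.8, 112.6), deceased=(89.4, 52.6), family=_LOGNORMAL),
        "alt": dict(alive=(41.3, 56.5), deceased=(44.3, 28.8), family=_LOGNORMAL),
        "ggt": dict(alive=(198.4, 184.9), deceased=(255.8, 316.3), family=_LOGNORMAL),
        "crp": dict(alive=(19.7, 39.7), deceased=(27.3, 24.5), family=_LOGNORMAL),
        "alp": dict(alive=(151.2, 83.0), deceased=(201.2, 121.1), family=_LOGNORMAL),
        "meld": dict(alive=(14.9, 4.8), deceased=(21.4, 8.2), family=_NORMAL_INT, lo=6.0, hi=40.0),
        "child_pugh": dict(alive=(9.1, 1.7), deceased=(10.9, 1.6), family=_NORMAL_INT, lo=5.0, hi=15.0),
    }


#: P(male) per class and overall beta-blocker rate of the emulated cohort
_P_MALE = (76.0 / 93.0, 18.0 / 23.0)
_P_BETA_BLOCKERS = 51.0 / 116.0


@dataclass
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults mirror the emulated study: 116 analyzed patients with a 6-month
    mortality of 23/116 (20%).
    """

    n: int = 116
    prevalence: float = 23.0 / 116.0
    band_library: List[BandSpec] = field(default_factory=default_band_library)
    noise_sd: float = 0.002            # AU, white detector noise
    baseline_order: int = 2
    baseline_scale: float = 0.01       # AU per Chebyshev coefficient
    jitter_sd: float = 0.08            # lognormal sigma, per-band per-sample
    global_scale_sd: float = 0.05      # lognormal sigma, common path-length factor
    co2_amplitude: float = 0.03        # AU, ambient CO2 artifact at 2349 cm^-1
    effect_scale: float = 1.0          # multiplier on all class_shifts
    covariate_spec: Dict[str, dict] = field(default_factory=default_covariate_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must be in (0, 1)")
        if self.n < 4:
            raise ValidationError("need at least 4 samples")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    informative_wavenumbers: np.ndarray   # grid-snapped centers of shifted bands
    labels: np.ndarray                    # per-sample outcome, 0/1
    mahalanobis: float                    # processed-space class separation


_CO2_CENTER = 2349.0
_CO2_FWHM = 25.0


def work_grid(cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    lo, hi = cfg.work_domain
    return np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)


def _gaussian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4.0 * math.log(2.0) * ((grid - center) / fwhm) ** 2)


def simulate_spectrum(
    label: int,
    cfg: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "S0",
) -> Spectrum:
    """One raw absorbance spectrum on the 950-3200 cm^-1 grid.

    Deterministic given the generator state; :func:`simulate_cohort` derives a
    fresh stream from ``(cfg.seed, sample index)`` so any single spectrum is
    reproducible in isolation.
    """
    grid = work_grid()
    y = np.zeros_like(grid)
    global_factor = float(np.exp(rng.normal(0.0, cfg.global_scale_sd)))
    for band in cfg.band_library:
        amp = band.amplitude * (1.0 + label * band.class_shift * cfg.effect_scale)
        amp *= float(np.exp(rng.normal(0.0, cfg.jitter_sd)))
        y += amp * _gaussian(grid, band.center, band.fwhm)
    y *= global_factor
    if cfg.baseline_order >= 0 and cfg.baseline_scale > 0:
        x = (grid - grid.mean()) / (grid[-1] - grid[0]) * 2.0
        coeffs = rng.normal(0.0, cfg.baseline_scale, size=cfg.baseline_order + 1)
        y += np.polynomial.chebyshev.chebval(x, coeffs)
    if cfg.co2_amplitude > 0:
        co2 = cfg.co2_amplitude * float(np.exp(rng.normal(0.0, 0.3)))
        y += co2 * _gaussian(grid, _CO2_CENTER, _CO2_FWHM)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, size=grid.size)
    return Spectrum(sample_id=sample_id, wavenumbers=grid, absorbance=y, stage=Stage.RAW)


def _snap_to_grid(values: Sequence[float], grid: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(grid, values), 1, grid.size - 1)
    left = grid[idx - 1]
    right = grid[idx]
    return np.where(np.abs(left - values) <= np.abs(right - values), left, right)


def informative_wavenumbers(cfg: CohortConfig) -> np.ndarray:
    """Centers of class-shifted bands, snapped to the nearest grid point."""
    centers = [b.center for b in cfg.band_library if b.class_shift != 0.0]
    return np.unique(_snap_to_grid(sorted(centers), work_grid()))


def _draw_covariate(rng: np.random.Generator, spec: dict, label: int, size: int) -> np.ndarray:
    mean, sd = spec["deceased"] if label == 1 else spec["alive"]
    family = spec["family"]
    if family == _LOGNORMAL:
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(rng.normal(mu, math.sqrt(sigma2), size=size))
    draws = rng.normal(mean, sd, size=size)
    draws = np.clip(draws, spec.get("lo", -np.inf), spec.get("hi", np.inf))
    if family == _NORMAL_INT:
        draws = np.round(draws)
    return draws


def simulate_cohort(cfg: CohortConfig) -> Tuple[SpectraSet, CohortTable, GroundTruth]:
    """Spectra, covariates and ground truth for one synthetic cohort.

    Exactly ``round(n * prevalence)`` samples are deceased; covariates are
    drawn independently given class from the per-group marginals; the
    realized processed-space Mahalanobis distance between class means (over
    the informative wavenumbers) is recorded in the ground truth.
    """
    n_dec = int(np.floor(cfg.n * cfg.prevalence + 0.5))
    if n_dec < 1:
        raise ValidationError("n * prevalence must be at least 1")
    if cfg.n - n_dec < 1:
        raise ValidationError("n * (1 - prevalence) must be at least 1")
    labels = np.zeros(cfg.n, dtype=int)
    labels[:n_dec] = 1
    order_rng = np.random.default_rng([int(cfg.seed), 715517])
    order_rng.shuffle(labels)

    ids = [f"S{i + 1:04d}" for i in range(cfg.n)]
    rows = []
    grid = work_grid()
    M = np.empty((cfg.n, grid.size))
    for i in range(cfg.n):
        rng = np.random.default_rng([int(cfg.seed), 1, i])
        M[i] = simulate_spectrum(int(labels[i]), cfg, rng, sample_id=ids[i]).absorbance

    cov_rng = np.random.default_rng([int(cfg.seed), 2])
    frame = pd.DataFrame(index=range(cfg.n))
    frame["sample_id"] = ids
    for name, spec in cfg.covariate_spec.items():
        col = np.empty(cfg.n)
        for label in (0, 1):
            mask = labels == label
            col[mask] = _draw_covariate(cov_rng, spec, label, int(mask.sum()))
        frame[name] = col
    p_male = np.where(labels == 1, _P_MALE[1], _P_MALE[0])
    frame["sex"] = np.where(cov_rng.random(cfg.n) < p_male, "M", "F")
    frame["beta_blockers"] = cov_rng.random(cfg.n) < _P_BETA_BLOCKERS
    frame["outcome"] = labels

    spectra = SpectraSet(sample_ids=ids, grid=grid, matrix=M, labels=labels, stage=Stage.RAW)
    cohort = CohortTable(frame)

    processed = preprocess_set(spectra)
    info = informative_wavenumbers(cfg)
    delta = _mahalanobis(processed.select_wavenumbers(info), labels)
    truth = GroundTruth(informative_wavenumbers=info, labels=labels.copy(), mahalanobis=delta)
    return spectra, cohort, truth


def _mahalanobis(X: np.ndarray, y: np.ndarray, ridge: float = 1e-12) -> float:
    """Pooled-covariance Mahalanobis distance between the two class means."""
    X0, X1 = X[y == 0], X[y == 1]
    d = X1.mean(axis=0) - X0.mean(axis=0)
    S = (
        (X0 - X0.mean(axis=0)).T @ (X0 - X0.mean(axis=0))
        + (X1 - X1.mean(axis=0)).T @ (X1 - X1.mean(axis=0))
    ) / (X.shape[0] - 2)
    S = S + ridge * np.trace(S) / max(S.shape[0], 1) * np.eye(S.shape[0])
    return float(np.sqrt(d @ np.linalg.solve(S, d)))


def delta_for_auc(target_auc: float) -> float:
    """Mahalanobis separation giving a Bayes AUROC of ``target_auc``."""
    if not (0.5 < target_auc < 1.0):
        raise DomainError("target_auc must be in (0.5, 1)")
    return math.sqrt(2.0) * float(ndtri(target_auc))


def auc_for_delta(delta: float) -> float:
    """Bayes AUROC of an equal-covariance Gaussian pair at separation ``delta``."""
    return float(norm.cdf(delta / math.sqrt(2.0)))


def calibrate_effect(
    target_auc: float,
    cfg: Optional[CohortConfig] = None,
    pilot_n: int = 2000,
    n_iter: int = 2,
) -> float:
    """Effect multiplier whose processed-space separation hits ``target_auc``.

    A balanced pilot cohort is simulated, preprocessed, and the Mahalanobis
    distance of the class means over the informative wavenumbers measured;
    the multiplier is rescaled (the shift is locally linear in the effect)
    and the measurement repeated.
    """
    target_delta = delta_for_auc(target_auc)
    cfg = cfg if cfg is not None else CohortConfig()
    scale = cfg.effect_scale if cfg.effect_scale > 0 else 1.0
    for it in range(n_iter):
        pilot = replace(
            cfg,
            n=pilot_n,
            prevalence=0.5,
            effect_scale=scale,
            seed=int(cfg.seed) + 90001 + it,
        )
        _, _, truth = simulate_cohort(pilot)
        if truth.mahalanobis <= 0:
            raise ValidationError("pilot cohort shows no separation; cannot calibrate")
        scale *= target_delta / truth.mahalanobis
    return float(scale)


# ---------------------------------------------------------------------------
# clinical scores (standard published formulas, provided for convenience)

_UMOL_PER_MGDL_CREAT = 88.4
_UMOL_PER_MGDL_BILI = 17.1


def compute_meld(creatinine_umol_l: float, bilirubin_umol_l: float, inr: float) -> int:
    """MELD score from creatinine and bilirubin (µmol/L) and INR.

    Standard formula: each argument (in mg/dL) is floored at 1.0, creatinine
    capped at 4.0 mg/dL; the result is rounded and clipped to [6, 40].
    """
    if creatinine_umol_l <= 0 or bilirubin_umol_l <= 0 or inr <= 0:
        raise DomainError("MELD inputs must be positive")
    creat = min(max(creatinine_umol_l / _UMOL_PER_MGDL_CREAT, 1.0), 4.0)
    bili = max(bilirubin_umol_l / _UMOL_PER_MGDL_BILI, 1.0)
    inr = max(inr, 1.0)
    score = 9.57 * math.log(creat) + 3.78 * math.log(bili) + 11.2 * math.log(inr) + 6.43
    return int(min(max(round(score), 6), 40))


def _bilirubin_points(bilirubin_umol_l: float) -> int:
    if bilirubin_umol_l < 34.0:
        return 1
    return 2 if bilirubin_umol_l <= 50.0 else 3


def _albumin_points(albumin_g_l: float) -> int:
    if albumin_g_l > 35.0:
        return 1
    return 2 if albumin_g_l >= 28.0 else 3


def _inr_points(inr: float) -> int:
    if inr < 1.7:
        return 1
    return 2 if inr <= 2.3 else 3


def compute_child_pugh(
    bilirubin_umol_l: float,
    albumin_g_l: float,
    inr: float,
    ascites_grade: int,
    encephalopathy_grade: int,
) -> int:
    """Child-Pugh score: five components banded 1-3 points, total in [5, 15]."""
    for grade, name in ((ascites_grade, "ascites"), (encephalopathy_grade, "encephalopathy")):
        if grade not in (1, 2, 3):
            raise DomainError(f"{name} grade must be 1, 2 or 3")
    return (
        _bilirubin_points(bilirubin_umol_l)
        + _albumin_points(albumin_g_l)
        + _inr_points(inr)
        + int(ascites_grade)
        + int(encephalopathy_grade)
    )
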