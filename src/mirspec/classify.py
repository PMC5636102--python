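"""Pooled-covariance LDA, probability scoring, Youden cut-offs and 90/10
Monte Carlo cross-validation.

The classifier is deliberately plain: two Gaussian classes with a shared
covariance give a linear discriminant ``w = Sigma^-1 (mu1 - mu0)``, and the
posterior probability of the deceased class is the logistic of the linear
score plus the log-prior offset.  Performance is summarized the way small
prognostic studies do it: 100 random 90/10 splits, per-run holdout AUROC and
Youden cut-off, then sensitivity/specificity re-evaluated at the across-run
mean cut-off, with per-sample misclassification bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .io import ValidationError
from ._stats import rank_auc, stratified_split, _round_half_up

__all__ = [
    "DiscriminantModel",
    "CVConfig",
    "CVReport",
    "fit_lda",
    "score",
    "youden_cutoff",
    "mc_cross_validate",
]


@dataclass
class DiscriminantModel:
    """Fitted two-class LDA on a set of selected variables."""

    class_means: np.ndarray        # 2 x p
    pooled_cov: np.ndarray         # p x p, after ridge
    log_priors: np.ndarray         # length 2
    weights: np.ndarray            # Sigma^-1 (mu1 - mu0)
    intercept: float               # -w . (mu0+mu1)/2 + log(pi1/pi0)
    wavenumbers: Optional[np.ndarray] = None


@dataclass
class CVConfig:
    train_fraction: float = 0.90
    n_runs: int = 100
    stratified: bool = True
    ridge: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")


@dataclass
class CVReport:
    """Per-run and aggregate Monte Carlo cross-validation metrics."""

    run_auroc: np.ndarray
    run_cutoff: np.ndarray           # per-run Youden cut-off on the holdout
    run_sensitivity: np.ndarray      # at the across-run mean cut-off
    run_specificity: np.ndarray
    mean_auroc: float
    auroc_ci: Tuple[float, float]
    mean_cutoff: float
    mean_sensitivity: float
    sensitivity_ci: Tuple[float, float]
    mean_specificity: float
    specificity_ci: Tuple[float, float]
    times_held_out: np.ndarray       # per sample
    times_misclassified: np.ndarray  # per sample, at the mean cut-off
    n_dropped_runs: int = 0


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: Optional[Sequence[float]] = None,
    ridge: float = 1e-8,
    wavenumbers: Optional[np.ndarray] = None,
) -> DiscriminantModel:
    """Fit pooled-covariance LDA; priors default to class frequencies.

    The ridge is relative: ``ridge * mean(diag(Sigma))`` is added to the
    diagonal before inversion (the selected-variable scale varies over
    orders of magnitude between raw and derivative spectra).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValidationError("need at least 2 samples in each class")
    if p > n - 2:
        raise ValidationError(f"p={p} variables exceed n-2={n - 2}")
    mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
    Xc = X - np.where(y[:, None] == 1, mu1, mu0)
    Sig = Xc.T @ Xc / (n - 2)
    eps = ridge * max(float(np.trace(Sig)) / p, 1e-300)
    Sig = Sig + eps * np.eye(p)
    try:
        np.linalg.cholesky(Sig)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("pooled covariance singular even after ridge") from exc
    if priors is None:
        priors = (n0 / n, n1 / n)
    pr = np.asarray(priors, dtype=float)
    if pr.size != 2 or np.any(pr <= 0):
        raise ValidationError("priors must be two positive numbers")
    pr = pr / pr.sum()
    w = np.linalg.solve(Sig, mu1 - mu0)
    b = -float(w @ (mu0 + mu1)) / 2.0 + math.log(pr[1] / pr[0])
    return DiscriminantModel(
        class_means=np.vstack([mu0, mu1]),
        pooled_cov=Sig,
        log_priors=np.log(pr),
        weights=w,
        intercept=b,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
    )


def score(model: DiscriminantModel, X: np.ndarray, wavenumbers: Optional[np.ndarray] = None) -> np.ndarray:
    """Posterior probability of class 1 (deceased): logistic of the discriminant."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.weights.size:
        raise ValidationError(
            f"{X.shape[1]} columns do not match the model's {model.weights.size} variables"
        )
    if wavenumbers is not None and model.wavenumbers is not None:
        if not np.allclose(wavenumbers, model.wavenumbers):
            raise ValidationError("wavenumbers do not match the model's selected set")
    return expit(X @ model.weights + model.intercept)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """Cut-off maximizing J = sensitivity + specificity - 1.

    Exhaustive scan over midpoints of adjacent sorted unique scores plus
    +/- infinity; a sample is called positive iff its score is strictly
    above the cut-off.  Ties in J break toward higher specificity, then
    lower cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    u = np.unique(scores)
    cands = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    called = scores[:, None] > cands[None, :]
    sens = called[pos].mean(axis=0)
    spec = 1.0 - called[~pos].mean(axis=0)
    J = sens + spec - 1.0
    # lexicographic: max J, then max specificity, then min cutoff
    order = np.lexsort((cands, -spec, -J))
    best = order[0]
    return float(cands[best]), float(J[best])


def mc_cross_validate(X: np.ndarray, y: np.ndarray, cfg: CVConfig = CVConfig()) -> CVReport:
    """Monte Carlo 90/10 cross-validation of LDA on a fixed variable set.

    Per run: stratified random split, fit on the training part, score the
    holdout, record holdout AUROC and Youden cut-off.  After all runs,
    sensitivity and specificity are recomputed per run at the across-run
    mean cut-off, and per-sample held-out/misclassified counts accumulated
    at that same cut-off.  Unstratified runs whose holdout lacks a class are
    dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 20 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("need n >= 20 with both classes represented")
    run_auc: List[float] = []
    run_cut: List[float] = []
    holdouts: List[Tuple[np.ndarray, np.ndarray]] = []
    dropped = 0
    for r in range(cfg.n_runs):
        rng = np.random.default_rng([int(cfg.seed), 5, r])
        if cfg.stratified:
            tr, va = stratified_split(y, cfg.train_fraction, rng)
        else:
            n_hold = max(_round_half_up(n * (1 - cfg.train_fraction)), 1)
            va = np.sort(rng.permutation(n)[:n_hold])
            tr = np.setdiff1d(np.arange(n), va)
            if len(set(y[va])) < 2 or (y[tr] == 0).sum() < 2 or (y[tr] == 1).sum() < 2:
                dropped += 1
                warnings.warn(f"run {r}: single-class holdout dropped", stacklevel=2)
                continue
        model = fit_lda(X[tr], y[tr], ridge=cfg.ridge)
        s = score(model, X[va])
        run_auc.append(rank_auc(s, y[va]))
        cut, _ = youden_cutoff(s, y[va])
        run_cut.append(cut)
        holdouts.append((va, s))
    if not run_auc:
        raise ValidationError("no usable cross-validation runs")

    run_auc_arr = np.asarray(run_auc)
    finite_cuts = np.asarray([c for c in run_cut if np.isfinite(c)])
    mean_cut = float(finite_cuts.mean()) if finite_cuts.size else 0.5
    sens_runs, spec_runs = [], []
    held = np.zeros(n, dtype=int)
    miscls = np.zeros(n, dtype=int)
    for va, s in holdouts:
        yv = y[va]
        called = s > mean_cut
        sens_runs.append(float(called[yv == 1].mean()))
        spec_runs.append(float((~called[yv == 0]).mean()))
        held[va] += 1
        miscls[va] += (called != (yv == 1)).astype(int)

    def ci(v: np.ndarray) -> Tuple[float, float]:
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    sens_arr, spec_arr = np.asarray(sens_runs), np.asarray(spec_runs)
    return CVReport(
        run_auroc=run_auc_arr,
        run_cutoff=np.asarray(run_cut),
        run_sensitivity=sens_arr,
        run_specificity=spec_arr,
        mean_auroc=float(run_auc_arr.mean()),
        auroc_ci=ci(run_auc_arr),
        mean_cutoff=mean_cut,
        mean_sensitivity=float(sens_arr.mean()),
        sensitivity_ci=ci(sens_arr),
        mean_specificity=float(spec_arr.mean()),
        specificity_ci=ci(spec_arr),
        times_held_out=held,
        times_misclassified=miscls,
        n_dropped_runs=dropped,
    )
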