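"""Small shared statistical helpers: rank-based AUROC and stratified splits."""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.stats import rankdata

from .io import ValidationError


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC estimator; ties count one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    m = int(pos.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise ValidationError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """One stratified train/holdout split.

    The holdout size is ``round(n * (1 - train_fraction))``, allocated to the
    classes proportionally with at least one holdout (and two training)
    samples per class.
    """
    y = np.asarray(y)
    n = y.size
    n_hold = _round_half_up(n * (1.0 - train_fraction))
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    if n_hold < 2:
        n_hold = 2
    h_pos = min(max(_round_half_up(n_hold * n_pos / n), 1), n_hold - 1)
    h_pos = min(h_pos, n_pos - 2)
    h_neg = min(n_hold - h_pos, n_neg - 2)
    if h_pos < 1 or h_neg < 1:
        raise ValidationError("holdout cannot contain both classes at this size")
    hold = np.concatenate([
        rng.permutation(np.flatnonzero(y == 1))[:h_pos],
        rng.permutation(np.flatnonzero(y == 0))[:h_neg],
    ])
    mask = np.ones(n, dtype=bool)
    mask[hold] = False
    return np.flatnonzero(mask), np.sort(hold)


def stratified_subsample(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified random subsample of the given fraction."""
    y = np.asarray(y)
    parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        take = max(_round_half_up(fraction * idx.size), 2)
        parts.append(rng.permutation(idx)[: min(take, idx.size)])
    return np.sort(np.concatenate(parts))


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sample fold assignment, classes dealt round-robin after shuffling."""
    y = np.asarray(y)
    folds = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        folds[idx] = np.arange(idx.size) % n_folds
    return folds
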