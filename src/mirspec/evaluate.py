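"""ROC evaluation, DeLong comparison of correlated AUROCs, and the Spearman
marker-covariate network.

The AUROC estimator is the Mann-Whitney pair-count form (ties half-weighted),
identical to the trapezoidal area under the empirical ROC curve.  Correlated
curves measured on the same patients (spectral model vs clinical scores) are
compared with the DeLong placement-value test.  The marker network connects
selected wavenumbers with each other and with clinical covariates through
Spearman rank correlations, keeping edges significant at raw p < 0.05 (an
optional Benjamini-Hochberg switch is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm, rankdata, spearmanr
from sklearn.metrics import roc_curve

from .io import CohortTable, ValidationError
from ._stats import rank_auc

__all__ = [
    "RocResult",
    "DelongResult",
    "CorrelationEdge",
    "ModelComparison",
    "roc_auc",
    "auc_ci_over_runs",
    "delong_compare",
    "delong_ci",
    "compare_models",
    "spearman_network",
]


@dataclass
class RocResult:
    """Empirical ROC curve and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_pos: int
    n_neg: int


@dataclass
class DelongResult:
    """DeLong comparison of two correlated AUROCs."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


@dataclass
class CorrelationEdge:
    """One significant Spearman association in the marker network."""

    node_a: str
    node_b: str
    r: float
    p: float

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1


@dataclass
class ModelComparison:
    """Pairwise DeLong table plus ROC overlay data for several score vectors."""

    aucs: Dict[str, float]
    rocs: Dict[str, RocResult]
    pairwise: List[Tuple[str, str, DelongResult]]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUROC by Mann-Whitney pair counting (ties half), curve by threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or not pos.any():
        raise ValidationError("both classes must be present")
    auc = rank_auc(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, auroc=auc,
                     n_pos=int(pos.sum()), n_neg=int((~pos).sum()))


def auc_ci_over_runs(values: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    """Mean and empirical 2.5/97.5 percentile interval across CV runs.

    Percentiles use the linear-interpolation quantile rule.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 runs")
    lo, hi = np.percentile(v, [2.5, 97.5])
    return float(v.mean()), (float(lo), float(hi))


def _placements(scores: np.ndarray, pos: np.ndarray):
    """DeLong structural components (placement values) for one score vector."""
    m = int(pos.sum())
    n = scores.size - m
    tx = rankdata(scores)
    tpos = rankdata(scores[pos])
    tneg = rankdata(scores[~pos])
    v10 = (tx[pos] - tpos) / n
    v01 = 1.0 - (tx[~pos] - tneg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_compare(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> DelongResult:
    """Two-sided DeLong test of AUROC(a) = AUROC(b) on the same samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.size != b.size or a.size != labels.size:
        raise ValidationError("score vectors and labels must have equal length")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 samples per class")
    auc_a, v10a, v01a = _placements(a, pos)
    auc_b, v10b, v01b = _placements(b, pos)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    V = s10 / m + s01 / n
    var_diff = float(V[0, 0] + V[1, 1] - 2.0 * V[0, 1])
    var_diff = max(var_diff, 0.0)
    diff = auc_a - auc_b
    if var_diff == 0.0:
        z = 0.0 if diff == 0.0 else math_inf(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * float(norm.sf(abs(z)))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff, z=float(z), p=float(p))


def math_inf(diff: float) -> float:
    return float(np.inf) if diff > 0 else float(-np.inf)


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """(AUROC, DeLong variance) of a single score vector."""
    labels = np.asarray(labels)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        raise ValidationError("need at least 2 samples per class")
    auc, v10, v01 = _placements(np.asarray(scores, dtype=float), pos)
    return auc, float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """AUROC with a DeLong-variance normal CI, clipped to [0, 1]."""
    auc, var = delong_variance(scores, labels)
    zq = float(norm.ppf(0.5 + level / 2.0))
    half = zq * np.sqrt(var)
    return auc, (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def compare_models(scores: Mapping[str, np.ndarray], labels: np.ndarray) -> ModelComparison:
    """Pairwise DeLong comparisons of several score vectors on one cohort.

    Raw p-values, no multiplicity correction (report all pairs and let the
    reader judge).
    """
    names = list(scores)
    if len(names) < 2:
        raise ValidationError("need at least two models to compare")
    labels = np.asarray(labels)
    rocs = {name: roc_auc(np.asarray(scores[name], dtype=float), labels) for name in names}
    pairwise = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            pairwise.append((na, nb, delong_compare(scores[na], scores[nb], labels)))
    return ModelComparison(
        aucs={k: r.auroc for k, r in rocs.items()}, rocs=rocs, pairwise=pairwise
    )


_CLINICAL_NETWORK_EXCLUDE = {"outcome", "sample_id"}


def spearman_network(
    spectral: Union[pd.DataFrame, np.ndarray],
    clinical: Union[CohortTable, pd.DataFrame],
    spectral_names: Optional[Sequence] = None,
    alpha: float = 0.05,
    adjust: Optional[str] = None,
    min_pairs: int = 10,
) -> List[CorrelationEdge]:
    """Spearman associations among selected wavenumbers and clinical covariates.

    Tests every spectral-spectral and spectral-clinical pair (mid-rank ties,
    asymptotic t-approximation p-values) and keeps edges with p < ``alpha``.
    ``adjust="bh"`` applies Benjamini-Hochberg before the cut; the default is
    raw p-values.  Constant variables are skipped with a warning.
    """
    if isinstance(spectral, pd.DataFrame):
        sp = spectral
    else:
        arr = np.asarray(spectral, dtype=float)
        names = (
            [f"{v:g}" for v in spectral_names]
            if spectral_names is not None
            else [f"var{i}" for i in range(arr.shape[1])]
        )
        sp = pd.DataFrame(arr, columns=names)
    cl = clinical.frame if isinstance(clinical, CohortTable) else clinical
    cl = cl.select_dtypes(include=[np.number, bool]).astype(float)
    cl = cl.drop(columns=[c for c in _CLINICAL_NETWORK_EXCLUDE if c in cl.columns])
    if len(sp) != len(cl):
        raise ValidationError("spectral and clinical tables must describe the same samples")
    if len(sp) < min_pairs:
        raise ValidationError(f"need at least {min_pairs} samples")

    pairs = []
    scols = list(sp.columns)
    for i, a in enumerate(scols):
        for b_name in scols[i + 1:]:
            pairs.append((str(a), sp[a].to_numpy(), str(b_name), sp[b_name].to_numpy()))
        for b_name in cl.columns:
            pairs.append((str(a), sp[a].to_numpy(), str(b_name), cl[b_name].to_numpy()))

    results = []
    for na, va, nb, vb in pairs:
        if np.std(va) == 0 or np.std(vb) == 0:
            warnings.warn(f"skipping constant variable pair ({na}, {nb})", stacklevel=2)
            continue
        r, p = spearmanr(va, vb)
        if not np.isfinite(r):
            warnings.warn(f"undefined correlation for ({na}, {nb})", stacklevel=2)
            continue
        results.append((na, nb, float(r), float(p)))
    if not results:
        return []
    pvals = np.array([t[3] for t in results])
    if adjust == "bh":
        pvals = false_discovery_control(pvals, method="bh")
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return [
        CorrelationEdge(node_a=na, node_b=nb, r=r, p=float(padj))
        for (na, nb, r, _), padj in zip(results, pvals)
        if padj < alpha
    ]
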