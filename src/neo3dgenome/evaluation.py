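"""Leave-one-out evaluation and ROC / precision-recall comparison.

Scores every curated, located peptide with the 3D-genome KNN vote
computed from all *other* peptides (leave-one-out), combines it with the
peptide's baseline pMHC score, and compares the combined ranking against
the baseline-only ranking by area under the ROC curve (AUC) and under
the precision-recall curve (AUPR). Because both scores are oriented
lower-is-positive, curves are computed on negated scores. Bootstrap
confidence intervals (resampling peptides) qualify any "outperforms"
claim the point estimates suggest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .epitopes import LabeledEpitope
from .knn import DEFAULT_K, EnsembleDistances, combine_scores, knn_score
from .polymer import ConformationEnsemble

__all__ = [
    "loocv_scores",
    "roc_auc",
    "pr_aupr",
    "compare_methods",
    "MethodReport",
]


def loocv_scores(
    epitopes: Sequence[LabeledEpitope],
    ensemble: ConformationEnsemble,
    baseline_scores: Sequence[float],
    k: int = DEFAULT_K,
) -> pd.DataFrame:
    """Leave-one-out combined scores for every located labeled epitope.

    ``baseline_scores`` aligns with ``epitopes`` and must already be in
    [0, 1], lower = stronger binder. Each epitope's KNN score is computed
    with itself removed from the training set, then combined as
    ``baseline - knn``. Returns a DataFrame with one row per epitope:
    peptide, label (1 = positive), knn_score, n_neighbors, baseline_score,
    combined_score.
    """
    epitopes = list(epitopes)
    if len(epitopes) != len(baseline_scores):
        raise ValueError("baseline_scores must align with epitopes")
    if any(not e.located for e in epitopes):
        raise ValueError("all epitopes must be located for LOOCV")
    labels = np.array([e.is_positive for e in epitopes], dtype=int)
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need >= 2 epitopes of each label for LOOCV")

    dists = EnsembleDistances(ensemble)
    rows = []
    for i, ep in enumerate(epitopes):
        training = epitopes[:i] + epitopes[i + 1 :]
        kscore, n_used = knn_score(ep, training, dists, k=k)
        combined = combine_scores(float(baseline_scores[i]), kscore)
        rows.append(
            {
                "peptide": ep.peptide,
                "mhc_allele": ep.mhc_allele,
                "label": int(ep.is_positive),
                "knn_score": kscore,
                "n_neighbors": n_used,
                "baseline_score": float(baseline_scores[i]),
                "combined_score": combined,
            }
        )
    return pd.DataFrame(rows)


def _oriented(scores, orientation: Literal["lower", "higher"]) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    return -s if orientation == "lower" else s


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: Literal["lower", "higher"] = "lower",
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and area. ``orientation="lower"`` means smaller scores
    indicate the positive class (the prioritization convention here).

    Returns ``(fpr, tpr, auc)``; tied scores are grouped per threshold,
    equivalent to half-credit in the concordant-pair formulation.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC undefined: only one class present")
    s = _oriented(scores, orientation)
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(auc(fpr, tpr))


def pr_aupr(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: Literal["lower", "higher"] = "lower",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and area (step interpolation).

    Returns ``(precision, recall, aupr)`` where the area is the
    average-precision step sum.
    """
    y = np.asarray(labels, dtype=int)
    if y.sum() < 1:
        raise ValueError("AUPR undefined: no positive labels")
    s = _oriented(scores, orientation)
    precision, recall, _ = precision_recall_curve(y, s)
    return precision, recall, float(average_precision_score(y, s))


@dataclass
class MethodReport:
    """AUC/AUPR of one scoring method with bootstrap confidence intervals."""

    method: str
    auc: float
    aupr: float
    auc_ci: tuple[float, float]
    aupr_ci: tuple[float, float]
    n: int


def _bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    metric,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n = labels.size
    stats = []
    attempts = 0
    while len(stats) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue  # resample must contain both classes
        stats.append(metric(scores[idx], labels[idx]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


def compare_methods(
    loocv_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MethodReport]:
    """Compare combined (3D-genome KNN + baseline) vs baseline-only scoring.

    Takes the output of :func:`loocv_scores`; returns per-method AUC and
    AUPR with seeded bootstrap 95% confidence intervals over peptides.
    """
    labels = loocv_table["label"].to_numpy()
    reports: dict[str, MethodReport] = {}
    for method, col in (("combined", "combined_score"), ("baseline", "baseline_score")):
        scores = loocv_table[col].to_numpy()
        _, _, a = roc_auc(scores, labels)
        _, _, p = pr_aupr(scores, labels)
        rng = np.random.default_rng(seed)
        auc_ci = _bootstrap_ci(
            scores, labels, lambda s, y: roc_auc(s, y)[2], n_boot, rng
        )
        aupr_ci = _bootstrap_ci(
            scores, labels, lambda s, y: pr_aupr(s, y)[2], n_boot, rng
        )
        reports[method] = MethodReport(
            method=method, auc=a, aupr=p, auc_ci=auc_ci, aupr_ci=aupr_ci,
            n=int(labels.size),
        )
    return reports


def write_report(reports: dict[str, MethodReport], path: str | Path) -> None:
    """Serialize a method-comparison report as JSON."""
    with open(path, "w") as fh:
        json.dump({m: asdict(r) for m, r in reports.items()}, fh, indent=1)
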