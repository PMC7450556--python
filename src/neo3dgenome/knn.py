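"""The 3D-genome nearest-neighbor immunogenicity score.

A candidate peptide is scored by looking at where its DNA locus sits in
the reconstructed 3D genome: among curated training peptides **on the
same chromosome** (chromosome territories make inter-chromosomal
distances incomparable), the k nearest in mean 3D distance (k = 10 by
default) vote with their immunogenicity labels, and the positive-vote
fraction is the KNN score. Distances are averaged over ensemble replicas
per pair — never over coordinates, since each replica's global
orientation is arbitrary.

The final prioritization score subtracts the KNN score from an external
baseline peptide-MHC score rescaled to [0, 1] with the *lower-is-better*
orientation (as a percentile rank of binding strength): lower combined
score means higher predicted immunogenicity, so both a strong predicted
binder and a positive spatial neighborhood push a peptide up the list.

`Genome3DNNClassifier` packages the whole scheme as a scikit-learn
estimator so it composes with sklearn model selection; the module
functions are the primitives it wraps.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .epitopes import LabeledEpitope
from .genome_grid import BinTable
from .polymer import ConformationEnsemble

__all__ = [
    "DEFAULT_K",
    "EnsembleDistances",
    "pairwise_model_distance",
    "mean_distance_matrix",
    "knn_score",
    "combine_scores",
    "rescale_baseline",
    "Genome3DNNClassifier",
]

DEFAULT_K = 10


class EnsembleDistances:
    """Cached replica-averaged bead-distance queries for one ensemble.

    Stacks the replica coordinates once; repeated scoring calls (e.g.
    leave-one-out over thousands of peptides) then cost one vectorized
    norm per query batch.
    """

    def __init__(self, ensemble: ConformationEnsemble):
        if ensemble.n_replicas == 0:
            raise ValueError("ensemble is empty")
        self.ensemble = ensemble
        self.bins = ensemble.bins
        self._coords = ensemble.coords_array()  # (R, n_beads, 3)

    def distance(self, bin_a: int, bin_b: int) -> float:
        d = np.linalg.norm(
            self._coords[:, bin_a, :] - self._coords[:, bin_b, :], axis=1
        )
        return float(d.mean())

    def distances_from(self, bin_a: int, bin_others: Sequence[int]) -> np.ndarray:
        others = np.asarray(bin_others, dtype=int)
        d = np.linalg.norm(
            self._coords[:, others, :] - self._coords[:, [bin_a], :], axis=2
        )
        return d.mean(axis=0)


def pairwise_model_distance(
    bin_a: int, bin_b: int, ensemble: ConformationEnsemble
) -> float:
    """Mean over replicas of the Euclidean distance between two beads."""
    if ensemble.n_replicas == 0:
        raise ValueError("ensemble is empty")
    coords = ensemble.coords_array()  # (R, n_beads, 3)
    d = np.linalg.norm(coords[:, bin_a, :] - coords[:, bin_b, :], axis=1)
    return float(d.mean())


def mean_distance_matrix(
    ensemble: ConformationEnsemble, bin_indices: Sequence[int] | None = None
) -> np.ndarray:
    """Replica-averaged pairwise bead distances, optionally on a bin subset.

    Precomputing this matrix makes leave-one-out scoring over many
    peptides cheap; entry (p, q) equals
    ``pairwise_model_distance(bin_indices[p], bin_indices[q], ensemble)``.
    """
    if ensemble.n_replicas == 0:
        raise ValueError("ensemble is empty")
    coords = ensemble.coords_array()
    if bin_indices is not None:
        coords = coords[:, np.asarray(bin_indices, dtype=int), :]
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    return np.linalg.norm(diff, axis=-1).mean(axis=0)


def knn_score(
    target: LabeledEpitope,
    training: Sequence[LabeledEpitope],
    ensemble: ConformationEnsemble | EnsembleDistances,
    k: int = DEFAULT_K,
    bins: BinTable | None = None,
) -> tuple[float, int]:
    """Positive-vote fraction among the k nearest same-chromosome neighbors.

    Neighbors are ranked by replica-averaged 3D distance, with
    deterministic tie-breaking by (distance, genome-wide bin index,
    peptide string). The target never votes for itself (the caller
    excludes it from ``training``; identical (peptide, allele) entries
    are skipped defensively). Fewer than k same-chromosome neighbors ->
    all available are used; zero -> the global training positive
    fraction is returned with neighbor count 0.

    Returns ``(score, n_neighbors_used)``.
    """
    if not target.located:
        raise ValueError(f"target peptide {target.peptide!r} is not located")
    training = [t for t in training if t.located]
    if not training:
        raise ValueError("training set has no located epitopes")
    if k < 1:
        raise ValueError("k must be >= 1")
    dists = ensemble if isinstance(ensemble, EnsembleDistances) else EnsembleDistances(ensemble)
    bins = bins if bins is not None else dists.bins
    if bins is None:
        raise ValueError("a BinTable is required (pass bins= or use an ensemble with bins)")

    chrom = bins.chrom_of_bin(target.bin_index)
    candidates = [
        t
        for t in training
        if bins.chrom_of_bin(t.bin_index) == chrom
        and not (t.peptide == target.peptide and t.mhc_allele == target.mhc_allele)
    ]
    if not candidates:
        global_rate = np.mean([t.is_positive for t in training])
        return float(global_rate), 0

    cand_d = dists.distances_from(target.bin_index, [t.bin_index for t in candidates])
    order = sorted(
        range(len(candidates)),
        key=lambda i: (cand_d[i], candidates[i].bin_index, candidates[i].peptide),
    )
    neighbors = [candidates[i] for i in order[: min(k, len(order))]]
    score = np.mean([t.is_positive for t in neighbors])
    return float(score), len(neighbors)


def combine_scores(baseline_score: float, knn_score_value: float) -> float:
    """Final prioritization score: baseline minus KNN vote fraction.

    ``baseline_score`` must already be rescaled to [0, 1] with lower =
    stronger predicted binder (see :func:`rescale_baseline`). The result
    lies in [-1, 1]; *lower* means higher predicted immunogenicity, so
    candidate lists are sorted ascending.
    """
    b = np.asarray(baseline_score, dtype=float)
    if np.any(b < 0) or np.any(b > 1):
        raise ValueError(
            "baseline_score must be in [0, 1]; rescale raw predictor output "
            "with rescale_baseline() first"
        )
    kv = np.asarray(knn_score_value, dtype=float)
    out = b - kv
    return float(out) if out.ndim == 0 else out


def rescale_baseline(
    raw_scores: Sequence[float],
    mode: Literal["rank", "affinity"] = "rank",
    invert: bool = False,
    ic50_max: float = 50_000.0,
) -> np.ndarray:
    """Rescale raw predictor output to [0, 1], lower = stronger binder.

    ``rank`` mode maps each score to its fractional rank (average ranks
    on ties), preserving the input orientation, or inverting it when
    ``invert=True`` (use this when the raw score is higher-is-stronger).
    A constant list maps to all 0.5. ``affinity`` mode treats inputs as
    half-maximal binding concentrations (IC50, nM) and maps
    ``log(ic50) / log(ic50_max)`` clipped to [0, 1], so strong binders
    (low IC50) get low scores.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("raw_scores is empty")
    if mode == "rank":
        if np.ptp(raw) == 0:
            return np.full(raw.shape, 0.5)
        ranks = rankdata(raw, method="average")
        scaled = (ranks - 1.0) / (raw.size - 1.0)
        return 1.0 - scaled if invert else scaled
    if mode == "affinity":
        clipped = np.clip(raw, 1.0, ic50_max)
        return np.log(clipped) / np.log(ic50_max)
    raise ValueError(f"unknown mode {mode!r}")


class Genome3DNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn wrapper around the 3D-genome KNN + baseline scheme.

    Samples are peptides represented by two features: column 0 the
    genome-wide bin index of the peptide's DNA locus, column 1 its
    baseline pMHC score already rescaled to [0, 1] (lower = stronger
    binder). ``y`` holds binary immunogenicity labels (1 = positive).

    ``decision_function`` returns ``knn_score - baseline`` so that, per
    sklearn convention, *higher* values mean the positive class; this is
    the negative of the ascending prioritization score used elsewhere.

    Parameters
    ----------
    ensemble : ConformationEnsemble
        Reconstructed 3D genome (with its BinTable attached).
    k : int, default 10
        Neighborhood size of the same-chromosome vote.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    X_ : ndarray
        Stored training design matrix.
    y_ : ndarray
        Stored training labels.
    """

    def __init__(self, ensemble: ConformationEnsemble | None = None, k: int = DEFAULT_K):
        self.ensemble = ensemble
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have 2 columns: bin_index, baseline_score")
        if self.ensemble is None or self.ensemble.bins is None:
            raise ValueError("ensemble with an attached BinTable is required")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        self.X_ = X
        self.y_ = y
        self._training_ = [
            LabeledEpitope(
                peptide=f"train_{i}",
                mhc_allele="",
                positive_rate=float(lab == self.classes_[1]),
                label="positive" if lab == self.classes_[1] else "negative",
                chrom=self.ensemble.bins.chrom_of_bin(int(b)),
                position=None,
                bin_index=int(b),
            )
            for i, (b, lab) in enumerate(zip(X[:, 0], y))
        ]
        self._dists_ = EnsembleDistances(self.ensemble)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = check_array(X)
        scores = np.empty(X.shape[0])
        for i, (b, baseline) in enumerate(zip(X[:, 0], X[:, 1])):
            target = LabeledEpitope(
                peptide=f"target_{i}", mhc_allele="", positive_rate=np.nan,
                label="negative", chrom=self.ensemble.bins.chrom_of_bin(int(b)),
                bin_index=int(b),
            )
            kscore, _ = knn_score(target, self._training_, self._dists_, k=self.k)
            scores[i] = kscore - combine_scores(baseline, 0.0)  # = kscore - baseline
        return scores

    def predict_proba(self, X):
        # decision values live in [-1, 1]; affine map to [0, 1]
        d = self.decision_function(X)
        p1 = (d + 1.0) / 2.0
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])
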