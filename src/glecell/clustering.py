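"""Unbiased grouping of per-cell GLE parameters.

Protocol: each cell contributes the feature vector (a, b, τ, Ω, B); every
feature is rescaled by the median of its distribution; X-means (k-means with
recursive split-and-test against a model-selection criterion, k allowed from
2 to 20) is run once for every unordered pair of cells used as the two
initial cluster centers, and the partition that occurs most often across the
n(n−1)/2 runs is reported together with its support fraction.

The split-acceptance score is a two-part description length of a spherical
Gaussian mixture (``mndl``, the default); the Bayesian information criterion
of the original X-means formulation is available as an alternative.  On
well-separated data both accept exactly the true splits; criterion details
only matter near the resolution limit.

Everything here is deterministic for a fixed feature table: no hidden RNG,
ties broken by the lexicographically smallest canonical labeling (flagged).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateInputError, ParameterError

DEFAULT_FEATURES = ("a", "b", "tau", "omega", "B")
K_RANGE = (2, 20)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FeatureTable:
    """Per-cell feature matrix plus the medians used for rescaling."""

    cell_ids: list
    features: np.ndarray
    feature_names: list
    scaling: np.ndarray | None = None  # medians applied (None = raw)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ParameterError("features must be a 2-D matrix")
        if np.isnan(self.features).any():
            raise DegenerateInputError("missing values in feature table")

    @property
    def n_cells(self) -> int:
        return self.features.shape[0]


@dataclass
class ClusterResult:
    """Partition of the cells with provenance of the consensus run."""

    labels: np.ndarray
    k: int
    centers: np.ndarray
    inertia: float = float("nan")
    support: float = float("nan")
    n_runs: int = 0
    tie: bool = False
    criterion_scores: list = field(default_factory=list)


def median_rescale(table: FeatureTable) -> FeatureTable:
    """Divide each feature by its median; idempotent (medians become 1)."""
    med = np.median(table.features, axis=0)
    if np.any(med == 0):
        bad = [n for n, m in zip(table.feature_names, med) if m == 0]
        raise DegenerateInputError(f"zero median for feature(s) {bad}")
    prior = table.scaling if table.scaling is not None else np.ones_like(med)
    return FeatureTable(
        cell_ids=list(table.cell_ids),
        features=table.features / med,
        feature_names=list(table.feature_names),
        scaling=prior * med,
    )


def kmeans(
    X: np.ndarray,
    init_centers: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> ClusterResult:
    """Lloyd's algorithm with explicit initial centers; fully deterministic.

    An emptied cluster is re-seeded at the point farthest from its assigned
    center, which keeps k constant and the inertia non-increasing overall.
    """
    X = np.asarray(X, dtype=float)
    centers = np.array(init_centers, dtype=float, copy=True)
    k = centers.shape[0]
    if k > X.shape[0]:
        raise ParameterError(f"k = {k} exceeds n = {X.shape[0]}")
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                # re-seed at the farthest point whose cluster can spare it
                own = d2[np.arange(len(X)), new_labels].copy()
                sizes = np.bincount(new_labels, minlength=k)
                own[sizes[new_labels] <= 1] = -np.inf
                far = int(np.argmax(own))
                new_labels[far] = c
                centers[c] = X[far]
        shift = 0.0
        for c in range(k):
            members = X[new_labels == c]
            newc = members.mean(axis=0) if len(members) else centers[c]
            shift = max(shift, float(((newc - centers[c]) ** 2).sum()))
            centers[c] = newc
        if np.array_equal(new_labels, labels) or shift < tol * tol:
            labels = new_labels
            break
        labels = new_labels
    d2 = ((X - centers[labels]) ** 2).sum(axis=1)
    return ClusterResult(labels=labels, k=k, centers=centers, inertia=float(d2.sum()))


def _sse_per_dim(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return ((X - centers[labels]) ** 2).sum(axis=0)


def _bic(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Diagonal-Gaussian-mixture BIC with a common within-cluster covariance
    (higher is better).  The diagonal model keeps anisotropic single
    populations — common for physical parameters on very different scales —
    from being split along their widest axis."""
    n, d = X.shape
    k = centers.shape[0]
    if n <= k:
        return -np.inf
    sigma2 = np.maximum(_sse_per_dim(X, labels, centers) / (n - k), 1e-300)
    counts = np.bincount(labels, minlength=k).astype(float)
    loglik = float(
        np.sum(counts * np.log(np.maximum(counts, 1.0) / n))
        - 0.5 * n * np.sum(_LOG2PI + np.log(sigma2))
        - 0.5 * d * (n - k)
    )
    n_params = (k + 1) * d
    return loglik - 0.5 * n_params * np.log(n)


def _mndl(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Two-part description length of the partition (lower is better).

    Data term: bits to encode the residuals under the fitted noiseless
    diagonal-Gaussian model; model term: bits for k centers, the per-axis
    noise levels, and the n assignment indices (0 bits for k = 1).
    """
    n, d = X.shape
    k = centers.shape[0]
    sigma2 = np.maximum(_sse_per_dim(X, labels, centers) / n, 1e-300)
    data_bits = 0.5 * n * np.sum(np.log2(sigma2 * 2.0 * np.pi * np.e))
    model_bits = 0.5 * k * 2 * d * np.log2(max(n, 2)) + n * np.log2(k)
    return float(data_bits + model_bits)


def _split_improves(Xc: np.ndarray, center: np.ndarray, sub: ClusterResult,
                    criterion: str) -> bool:
    one_center = center[None, :]
    one_labels = np.zeros(len(Xc), dtype=int)
    if criterion == "bic":
        return _bic(Xc, sub.labels, sub.centers) > _bic(Xc, one_labels, one_center)
    if criterion == "mndl":
        return _mndl(Xc, sub.labels, sub.centers) < _mndl(Xc, one_labels, one_center)
    raise ParameterError(f"unknown criterion {criterion!r}")


def _deterministic_split_init(Xc: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Child centers at ± the principal axis of the cluster (no RNG)."""
    Y = Xc - center
    cov = Y.T @ Y / max(len(Xc) - 1, 1)
    lam, vec = np.linalg.eigh(cov)
    direction = vec[:, -1] * np.sqrt(max(lam[-1], 1e-300))
    return np.vstack([center - direction, center + direction])


def xmeans(
    X: np.ndarray,
    init_centers: np.ndarray,
    k_max: int = K_RANGE[1],
    criterion: str = "mndl",
) -> ClusterResult:
    """Split-and-test k selection starting from the supplied initial centers.

    Runs k-means at the current k, then tentatively bisects every cluster
    (children initialized on the cluster's principal axis) and accepts the
    split iff the model-selection score improves on that cluster's points.
    Repeats until no split is accepted or k reaches ``k_max``.
    """
    X = np.asarray(X, dtype=float)
    result = kmeans(X, init_centers)
    scores = []
    while result.k < k_max:
        new_centers = []
        any_split = False
        for c in range(result.k):
            Xc = X[result.labels == c]
            center = result.centers[c]
            if len(Xc) < 3:
                new_centers.append(center[None, :])
                continue
            sub = kmeans(Xc, _deterministic_split_init(Xc, center))
            if len(np.unique(sub.labels)) == 2 and _split_improves(Xc, center, sub, criterion):
                new_centers.append(sub.centers)
                any_split = True
                scores.append((result.k, c, "accept"))
            else:
                new_centers.append(center[None, :])
                scores.append((result.k, c, "reject"))
        if not any_split:
            break
        centers = np.vstack(new_centers)[:k_max]
        result = kmeans(X, centers)
    result.criterion_scores = scores
    return result


def canonical_labels(labels: np.ndarray) -> tuple:
    """Relabel by order of first occurrence; permutation-invariant form."""
    mapping: dict[int, int] = {}
    out = []
    for l in labels:
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return tuple(out)


def allpairs_consensus(
    table: FeatureTable,
    k_max: int = K_RANGE[1],
    criterion: str = "mndl",
) -> ClusterResult:
    """Run X-means from every unordered pair of cells as the two initial
    centers (n(n−1)/2 runs) and return the modal partition."""
    X = table.features
    n = table.n_cells
    if n < 3:
        raise ParameterError("need at least 3 cells for the consensus protocol")
    counts: Counter = Counter()
    n_runs = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            res = xmeans(X, X[[i, j]], k_max=k_max, criterion=criterion)
            counts[canonical_labels(res.labels)] += 1
            n_runs += 1
    top = counts.most_common()
    best_count = top[0][1]
    tied = sorted(part for part, c in top if c == best_count)
    modal = tied[0]
    labels = np.array(modal)
    k = len(set(modal))
    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    d2 = ((X - centers[labels]) ** 2).sum(axis=1)
    return ClusterResult(
        labels=labels, k=k, centers=centers, inertia=float(d2.sum()),
        support=best_count / n_runs, n_runs=n_runs, tie=len(tied) > 1,
    )


def label_accuracy(labels: np.ndarray, truth: np.ndarray) -> float:
    """Best label-permutation agreement (Hungarian matching on the
    confusion matrix)."""
    labels = np.asarray(labels)
    truth_codes, _ = pd.factorize(pd.Series(truth))
    k1, k2 = labels.max() + 1, truth_codes.max() + 1
    conf = np.zeros((k1, k2))
    for l, t in zip(labels, truth_codes):
        conf[l, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(labels))


def build_feature_table(
    params: pd.DataFrame, feature_subset: tuple | list = DEFAULT_FEATURES
) -> FeatureTable:
    """Feature table from a CellParams table (columns a, b, tau, omega, B)."""
    missing = [f for f in feature_subset if f not in params.columns]
    if missing:
        raise ParameterError(f"missing feature columns {missing}")
    sub = params.dropna(subset=list(feature_subset))
    return FeatureTable(
        cell_ids=list(sub["cell_id"]) if "cell_id" in sub else list(sub.index),
        features=sub[list(feature_subset)].to_numpy(dtype=float),
        feature_names=list(feature_subset),
    )


def classify_cells(
    params: pd.DataFrame,
    feature_subset: tuple | list = DEFAULT_FEATURES,
    truth_column: str | None = None,
    k_max: int = K_RANGE[1],
    criterion: str = "mndl",
) -> tuple[ClusterResult, dict]:
    """End of the pipeline: median-rescaled all-pairs X-means consensus.

    Returns the modal partition and a report (k, support, tie flag, and the
    best-permutation accuracy when a ground-truth column is provided).
    """
    table = median_rescale(build_feature_table(params, feature_subset))
    result = allpairs_consensus(table, k_max=k_max, criterion=criterion)
    report = {
        "n_cells": table.n_cells,
        "features": list(feature_subset),
        "k": result.k,
        "support": result.support,
        "n_runs": result.n_runs,
        "tie": result.tie,
    }
    if truth_column is not None:
        truth = params.dropna(subset=list(feature_subset))[truth_column].to_numpy()
        report["accuracy"] = label_accuracy(result.labels, truth)
    return result, report
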