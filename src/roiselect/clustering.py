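"""Tile clustering and agreement metrics.

Tiles are grouped by k-means on their composition vectors (or on any
per-tile embedding), the number of clusters is chosen by the elbow of the
within-cluster sum-of-squares curve, and competing labelings are compared
with cluster purity, normalized mutual information, Spearman pairing of
cluster mean profiles, and canonical correlation analysis between paired
feature spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "ClusterEvaluation",
    "kmeans_tiles",
    "elbow_select_k",
    "cluster_purity",
    "nmi",
    "pair_clusters_spearman",
    "canonical_correlation",
]


def kmeans_tiles(vectors, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means (Lloyd's algorithm, k-means++ init, ``n_init`` restarts)
    on per-tile vectors; deterministic for a fixed seed up to cluster-id
    permutation."""
    vectors = np.asarray(vectors, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if vectors.shape[0] < k:
        raise ValueError("need at least k tiles")
    if k > 1 and np.allclose(vectors, vectors[0]):
        warnings.warn(
            "all vectors identical; k-means centroids are duplicated",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(vectors)


def elbow_select_k(vectors, k_range, seed: int = 0, n_init: int = 10):
    """Choose k at the knee of the within-cluster sum-of-squares curve.

    The knee is the k with the maximum second difference of
    log-inertia — the sharpest *relative* bend, which is insensitive to
    the absolute inertia scale.  Returns ``(k, inertias, confident)``
    where ``inertias`` maps each candidate k to its inertia so a caller
    can inspect the curve and override — a smaller k within the elbow is
    a legitimate manual choice — and ``confident`` is False when the
    curve has no pronounced knee (max second difference of log-inertia
    below 0.25).
    """
    k_range = sorted(int(k) for k in k_range)
    if len(k_range) < 3:
        raise ValueError("k_range needs at least 3 values")
    vectors = np.asarray(vectors, dtype=float)
    inertias = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(vectors)
        inertias[k] = float(km.inertia_)
    vals = np.array([inertias[k] for k in k_range])
    if np.any(np.diff(vals) > 1e-9 * max(1.0, vals[0])):
        warnings.warn(
            "inertia curve is not monotone decreasing; consider more restarts",
            stacklevel=2,
        )
    logv = np.log(np.maximum(vals, 1e-300))
    second = logv[:-2] - 2 * logv[1:-1] + logv[2:]
    knee_pos = int(np.argmax(second)) + 1
    chosen = k_range[knee_pos]
    confident = bool(second[knee_pos - 1] > 0.25)
    return chosen, inertias, confident


def cluster_purity(pred, truth) -> float:
    """Cluster purity: ``(1/N) * sum over predicted clusters of the
    largest overlap with any ground-truth cluster``.

    1.0 means every predicted cluster is contained in a single truth
    class; a single predicted cluster scores the modal class frequency.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be equal-length and non-empty")
    total = 0
    for c in np.unique(pred):
        members = truth[pred == c]
        total += np.bincount(_codes(members)).max()
    return total / pred.size


def _codes(arr):
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def _contingency(pred, truth):
    pc, tc = _codes(pred), _codes(truth)
    table = np.zeros((pc.max() + 1, tc.max() + 1))
    np.add.at(table, (pc, tc), 1.0)
    return table


def nmi(pred, truth, average: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings:
    ``MI(U, V) / mean(H(U), H(V))`` with the arithmetic mean by default
    (``average="geometric"`` for the geometric-mean variant).

    Two single-class labelings are defined as identical (1.0); a
    single-class labeling against a multi-class one carries no mutual
    information (0.0).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be equal-length and non-empty")
    table = _contingency(pred, truth)
    n = table.sum()
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    hu = float(-np.sum(pu[pu > 0] * np.log(pu[pu > 0])))
    hv = float(-np.sum(pv[pv > 0] * np.log(pv[pv > 0])))
    if hu == 0 and hv == 0:
        return 1.0
    if hu == 0 or hv == 0:
        return 0.0
    pij = table / n
    outer = np.outer(pu, pv)
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    denom = 0.5 * (hu + hv) if average == "arithmetic" else np.sqrt(hu * hv)
    return mi / denom


@dataclass
class ClusterEvaluation:
    """Agreement between a predicted and a ground-truth clustering."""

    purity: float | None = None
    nmi: float | None = None
    correlation_matrix: np.ndarray | None = None
    assignment: dict | None = None
    canonical_correlations: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self):
        out = {}
        if self.purity is not None:
            out["purity"] = self.purity
        if self.nmi is not None:
            out["nmi"] = self.nmi
        if self.correlation_matrix is not None:
            out["correlation_matrix"] = np.asarray(self.correlation_matrix).tolist()
        if self.assignment is not None:
            out["assignment"] = {str(k): int(v) for k, v in self.assignment.items()}
        if self.canonical_correlations is not None:
            out["canonical_correlations"] = np.asarray(
                self.canonical_correlations
            ).tolist()
        out.update(self.extras)
        return out


def pair_clusters_spearman(pred_profiles, truth_profiles, method="optimal"):
    """Pair predicted clusters to ground-truth clusters by Spearman
    correlation of their mean profiles.

    Computes the full (k_pred x k_truth) Spearman matrix and a one-to-one
    assignment maximizing total correlation (Hungarian algorithm;
    ``method="greedy"`` for the greedy variant).  Pairs whose correlation
    is undefined (a constant profile) are reported as NaN and excluded
    from the assignment.

    Returns a :class:`ClusterEvaluation` with ``correlation_matrix`` and
    ``assignment`` (pred cluster index -> truth cluster index).
    """
    P = np.atleast_2d(np.asarray(pred_profiles, dtype=float))
    T = np.atleast_2d(np.asarray(truth_profiles, dtype=float))
    if P.shape[1] != T.shape[1]:
        raise ValueError("profile vectors must have equal length")
    kp, kt = P.shape[0], T.shape[0]
    corr = np.full((kp, kt), np.nan)
    for i in range(kp):
        for j in range(kt):
            if np.ptp(P[i]) == 0 or np.ptp(T[j]) == 0:
                continue
            corr[i, j] = stats.spearmanr(P[i], T[j]).statistic
    workable = np.where(np.isnan(corr), -2.0, corr)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-workable)
        assignment = {
            int(i): int(j)
            for i, j in zip(rows, cols)
            if not np.isnan(corr[i, j])
        }
    elif method == "greedy":
        assignment = {}
        used = set()
        order = np.dstack(np.unravel_index(np.argsort(-workable, axis=None), corr.shape))[0]
        for i, j in order:
            if i in assignment or j in used or np.isnan(corr[i, j]):
                continue
            assignment[int(i)] = int(j)
            used.add(int(j))
    else:
        raise ValueError("method must be 'optimal' or 'greedy'")
    return ClusterEvaluation(correlation_matrix=corr, assignment=assignment)


def canonical_correlation(X, Y, n_components: int = 2):
    """Canonical correlation analysis between two paired feature spaces.

    Returns ``(correlations, x_scores, y_scores)``: the per-component
    canonical correlations in descending order and the projected scores
    of both views for overlap plots.

    Computed through orthonormal (SVD) bases of both views, the stable
    formulation; rank-deficient inputs (e.g. composition vectors, which
    always lose one dimension to the simplex constraint) are restricted
    to their principal subspace with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if n_components > min(X.shape[1], Y.shape[1], X.shape[0] - 1):
        raise ValueError("n_components exceeds the rank limit of the inputs")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def orthobasis(Z, name):
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
        if rank < Z.shape[1]:
            warnings.warn(
                f"rank-deficient input {name} (rank {rank} < {Z.shape[1]}); "
                "restricting to its principal subspace",
                stacklevel=3,
            )
        return U[:, :rank]

    Qx = orthobasis(Xc, "X")
    Qy = orthobasis(Yc, "Y")
    if min(Qx.shape[1], Qy.shape[1]) < n_components:
        raise ValueError("inputs have lower rank than n_components")
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    corrs = np.clip(s[:n_components], 0.0, 1.0)
    return corrs, Qx @ U[:, :n_components], Qy @ Vt.T[:, :n_components]
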