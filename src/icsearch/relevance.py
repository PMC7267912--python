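"""Spectral relevance heuristic for groups of voxels.

The relevance of a voxel set is the trace ratio of between-class to
within-class scatter,

    S(IC) = tr(W' X L_b X' W) / tr(W' X L_w X' W),

where W is the 0/1 selection matrix of the set's voxels (never materialized),
X is voxels x subjects, and L_b, L_w are graph Laplacians of label-derived
affinity matrices over subjects. With Fisher affinities

    S_b[i,j] = 1/n - 1/n_l  (same class l, incl. i=j),  1/n otherwise
    S_w[i,j] = 1/n_l        (same class),               0   otherwise

and row-sum degree matrices, L_b = -S_b and L_w = I - S_w are PSD, and the
per-voxel quadratic forms b_i = x_i L_b x_i', w_i = x_i L_w x_i' are exactly
the voxel's between- and within-class scatter. Because traces are additive,
the score of any voxel set is (sum b_i) / (sum w_i) over its members: one
matrix product up front, O(1) per candidate during the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

_EPS_DENOM = 1e-12


@dataclass
class ClassLabels:
    """Validated per-subject class labels."""

    labels: np.ndarray          # original label values, length n
    codes: np.ndarray           # 0..L-1 integer codes
    classes: np.ndarray         # unique label values
    counts: np.ndarray          # per-class subject counts

    @property
    def n(self) -> int:
        return len(self.labels)


def encode_labels(labels, require_two_classes: bool = True) -> ClassLabels:
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) < 2:
        raise ValueError("labels must be a 1D array with at least 2 subjects")
    classes, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if require_two_classes and len(classes) < 2:
        raise ValueError("labels required: at least 2 classes needed for supervised mode")
    return ClassLabels(labels=labels, codes=codes, classes=classes, counts=counts)


@dataclass
class AffinityModel:
    """Subject-level affinity matrices and their Laplacians."""

    S_b: np.ndarray
    S_w: np.ndarray
    L_b: np.ndarray
    L_w: np.ndarray
    mode: str  # "fisher_supervised" | "laplacian_unsupervised"


def _laplacian(S: np.ndarray) -> np.ndarray:
    # Row-sum degree; for the Fisher matrices this reduces to D_b = 0, D_w = I.
    return np.diag(S.sum(axis=1)) - S


def build_affinity(labels) -> AffinityModel:
    """Fisher (supervised) between/within-class affinity matrices."""
    enc = labels if isinstance(labels, ClassLabels) else encode_labels(labels)
    n = enc.n
    same = enc.codes[:, None] == enc.codes[None, :]
    nl = enc.counts[enc.codes]  # class size of subject i
    S_w = np.where(same, 1.0 / nl[:, None], 0.0)
    S_b = np.where(same, 1.0 / n - 1.0 / nl[:, None], 1.0 / n)
    return AffinityModel(S_b=S_b, S_w=S_w, L_b=_laplacian(S_b), L_w=_laplacian(S_w),
                         mode="fisher_supervised")


def build_affinity_unsupervised(
    X: np.ndarray,
    k_neighbors: int = 5,
    kernel_width: float | None = None,
) -> AffinityModel:
    """Laplacian-score affinities when labels are unavailable.

    S_w is a symmetrized k-nearest-neighbor graph over subjects (columns of
    X) with heat-kernel weights exp(-d^2 / (2 sigma^2)); S_b is the complete
    graph at weight 1/n. `kernel_width` defaults to the median pairwise
    subject distance.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} subjects, got {n}")
    D = squareform(pdist(X.T))
    if kernel_width is None:
        off = D[np.triu_indices(n, 1)]
        kernel_width = float(np.median(off))
        if kernel_width <= 0:
            kernel_width = 1.0
    if not np.isfinite(kernel_width) or kernel_width <= 0:
        raise ValueError("kernel_width must be a finite positive number")
    W = np.exp(-(D ** 2) / (2.0 * kernel_width ** 2))
    # keep k nearest neighbors per subject (excluding self), then symmetrize
    knn = np.zeros_like(W, dtype=bool)
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1)
    rows = np.repeat(np.arange(n), k_neighbors)
    knn[rows, order[:, :k_neighbors].ravel()] = True
    knn |= knn.T
    S_w = np.where(knn, W, 0.0)
    S_b = np.full((n, n), 1.0 / n)
    return AffinityModel(S_b=S_b, S_w=S_w, L_b=_laplacian(S_b), L_w=_laplacian(S_w),
                         mode="laplacian_unsupervised")


@dataclass
class SpectralCache:
    """Per-voxel diagonal entries of X L_b X' and X L_w X'.

    b[i] and w[i] are nonnegative (quadratic forms of PSD matrices); the
    score of any voxel set is b.sum / w.sum over its members.
    """

    b: np.ndarray
    w: np.ndarray


def standardize_voxels(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance per voxel across subjects (constant voxels
    are left at zero). The trace ratio is scale-sensitive per voxel;
    standardizing makes scores comparable across voxels."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def build_spectral_cache(
    X: np.ndarray,
    model: AffinityModel,
    standardize: bool = True,
) -> SpectralCache:
    """Precompute b_i = x_i L_b x_i' and w_i = x_i L_w x_i' for every voxel row.

    One pair of matrix products before the search; everything after is sums.
    """
    X = np.asarray(X, dtype=float)
    n = model.L_b.shape[0]
    if X.shape[1] != n:
        raise ValueError(
            f"X has {X.shape[1]} subjects but the affinity model has {n}")
    if standardize:
        X = standardize_voxels(X)
    b = np.einsum("ij,jk,ik->i", X, model.L_b, X)
    w = np.einsum("ij,jk,ik->i", X, model.L_w, X)
    # clip tiny negative rounding residue of the PSD forms
    return SpectralCache(b=np.maximum(b, 0.0), w=np.maximum(w, 0.0))


def cluster_score(cache: SpectralCache, members: np.ndarray) -> float:
    """Trace-ratio relevance of a voxel set (from cached per-voxel sums)."""
    members = np.asarray(members, dtype=np.int64)
    if members.size == 0:
        raise ValueError("cluster_score requires a non-empty member set")
    num = float(cache.b[members].sum())
    den = float(cache.w[members].sum())
    if den < _EPS_DENOM:
        warnings.warn("degenerate within-class scatter: treating cluster as "
                      "maximally informative", RuntimeWarning, stacklevel=2)
        return np.inf
    return num / den


def cluster_score_dense(
    X: np.ndarray,
    model: AffinityModel,
    members: np.ndarray,
    standardize: bool = True,
) -> float:
    """Reference trace-ratio computation with a materialized selection matrix.

    Used by the non-memoized path and as an oracle in tests; O(p n^2) per call
    instead of O(|members|).
    """
    X = np.asarray(X, dtype=float)
    if standardize:
        X = standardize_voxels(X)
    members = np.asarray(members, dtype=np.int64)
    p = X.shape[0]
    W = np.zeros((p, len(members)))
    W[members, np.arange(len(members))] = 1.0
    Z = W.T @ X
    num = float(np.trace(Z @ model.L_b @ Z.T))
    den = float(np.trace(Z @ model.L_w @ Z.T))
    if den < _EPS_DENOM:
        return np.inf
    return num / den


def feature_score(cache: SpectralCache, voxel: int) -> float:
    """Single-voxel spectral score b_i / w_i (the group score of a singleton)."""
    return cluster_score(cache, np.array([voxel]))


def admission_test(
    cache: SpectralCache,
    members: np.ndarray,
    candidate: int,
) -> tuple[bool, float]:
    """Admission rule for a candidate voxel arriving at a cluster.

    Admit iff the score of members + candidate strictly exceeds the score of
    members alone. Returns (admit, score difference); with an infinite
    current score the difference is NaN and the candidate is rejected.
    """
    members = np.asarray(members, dtype=np.int64)
    if candidate in members:
        raise ValueError("candidate is already a member")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        old = cluster_score(cache, members)
        new = cluster_score(cache, np.append(members, candidate))
    return bool(new > old), new - old
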