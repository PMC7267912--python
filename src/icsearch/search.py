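"""The information cluster search (ICS) engine.

Starting from every in-space voxel in turn, a cluster is grown by alternating
two phases until a whole expansion admits nothing:

expansion
    every voxel adjacent to the current cluster (minus the voxels removed by
    the immediately preceding prune) is tested one-by-one with the admission
    rule — does adding it strictly increase the cluster's trace-ratio
    relevance? — and all individually-passing candidates are admitted
    jointly. Because each passes individually, the joint score also strictly
    increases (mediant argument), so relevance rises every expansion.

prune
    redundant members are removed greedily by descending mean mutual
    information with the rest of the cluster, gated so the relevance score
    never decreases. The voxels admitted by the immediately preceding
    expansion and the origin voxel are protected; the removed voxels are
    excluded from the next expansion only. These one-phase windows are the
    anti-loop bookkeeping.

The search itself is deterministic: no randomness anywhere, all ties broken
by geometric linear index. Per-voxel spectral terms are computed once before
the loop and pairwise MI values are cached across origins, so the memoized
run does sums and hash lookups only; a non-memoized reference path
recomputes everything from matrices and is bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import relevance as rel
from .grid import VoxelGrid, build_grid
from .redundancy import RedundancyCache, prune

logger = logging.getLogger(__name__)


@dataclass
class InformationCluster:
    """A discovered cluster: origin, members, and its relevance score.

    `information` (cross-validated AUC of a classifier restricted to the
    member voxels) is filled in separately by the evaluation module.
    """

    origin: int
    members: np.ndarray
    relevance: float
    information: float | None = None
    n_phases: int = 0
    connected: bool = True
    trace: list[tuple[int, list[int], list[int]]] | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ICSResult:
    """One cluster per in-space origin voxel, plus the run configuration."""

    clusters: list[InformationCluster]
    config: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def relevance_map(self) -> np.ndarray:
        return np.array([c.relevance for c in self.clusters])

    def information_map(self) -> np.ndarray:
        return np.array([np.nan if c.information is None else c.information
                         for c in self.clusters])

    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters])


def _joint_admission(
    cache: rel.SpectralCache,
    score: float,
    B: float,
    W: float,
    candidates: np.ndarray,
) -> np.ndarray:
    """Vectorized admission rule: candidates whose individual addition to the
    current cluster strictly increases its score."""
    if candidates.size == 0:
        return candidates
    with np.errstate(divide="ignore", invalid="ignore"):
        new = (B + cache.b[candidates]) / (W + cache.w[candidates])
    return candidates[new > score]


def grow_cluster(
    origin: int,
    grid: VoxelGrid,
    spectral_cache: rel.SpectralCache,
    redundancy_cache: RedundancyCache,
    X: np.ndarray,
    max_phases: int | None = None,
    keep_trace: bool = False,
) -> InformationCluster:
    """Grow the information cluster originating at `origin`.

    A singleton is a valid result (no neighbor improves the origin). The
    phase count is capped at 4p as a hard safety bound; relevance increases
    strictly with every expansion, so the cap is not reached in practice.
    """
    p = grid.n_voxels
    if max_phases is None:
        max_phases = 4 * p
    members = np.array([origin], dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = rel.cluster_score(spectral_cache, members)
    excluded = np.array([], dtype=np.int64)
    trace: list[tuple[int, list[int], list[int]]] | None = [] if keep_trace else None
    phases = 0
    while phases < max_phases:
        candidates = grid.cluster_neighbors(members, excluded)
        B = float(spectral_cache.b[members].sum())
        W = float(spectral_cache.w[members].sum())
        admitted = _joint_admission(spectral_cache, score, B, W, candidates)
        if admitted.size == 0:
            break
        members = np.sort(np.concatenate([members, admitted]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = rel.cluster_score(spectral_cache, members)
            protected = np.append(admitted, origin)
            members, removed = prune(members, protected, spectral_cache,
                                     redundancy_cache, X)
            score = rel.cluster_score(spectral_cache, members)
        excluded = removed
        phases += 1
        if trace is not None:
            trace.append((phases, [int(v) for v in admitted], [int(v) for v in removed]))
    return InformationCluster(
        origin=origin,
        members=members,
        relevance=score,
        n_phases=phases,
        connected=grid.is_connected(members),
        trace=trace,
    )


def grow_cluster_reference(
    origin: int,
    grid: VoxelGrid,
    X: np.ndarray,
    model: rel.AffinityModel,
    bins: int = 8,
    standardize: bool = True,
    max_phases: int | None = None,
) -> InformationCluster:
    """Non-memoized reference: scores from materialized selection matrices,
    MI recomputed on every request. Must match :func:`grow_cluster` exactly."""
    p = grid.n_voxels
    if max_phases is None:
        max_phases = 4 * p
    Xs = rel.standardize_voxels(X) if standardize else np.asarray(X, dtype=float)
    no_cache = RedundancyCache(bins=bins, memoize=False)

    def dense_score(mem: np.ndarray) -> float:
        return rel.cluster_score_dense(Xs, model, mem, standardize=False)

    members = np.array([origin], dtype=np.int64)
    score = dense_score(members)
    excluded = np.array([], dtype=np.int64)
    phases = 0
    while phases < max_phases:
        candidates = grid.cluster_neighbors(members, excluded)
        admitted = np.array(
            [c for c in candidates
             if dense_score(np.append(members, c)) > score],
            dtype=np.int64)
        if admitted.size == 0:
            break
        members = np.sort(np.concatenate([members, admitted]))
        score = dense_score(members)
        # dense-score prune, mirroring redundancy.prune
        protected = set(int(v) for v in np.append(admitted, origin))
        removed = []
        while len(members) >= 2:
            cands = [int(v) for v in members if int(v) not in protected]
            if not cands:
                break
            from .redundancy import redundancy_score
            J = [redundancy_score(no_cache, members, c, Xs) for c in cands]
            best = cands[int(np.argmax(J))]
            if dense_score(members[members != best]) >= dense_score(members):
                members = members[members != best]
                removed.append(best)
            else:
                break
        score = dense_score(members)
        excluded = np.array(sorted(removed), dtype=np.int64)
        phases += 1
    return InformationCluster(origin=origin, members=members, relevance=score,
                              n_phases=phases, connected=grid.is_connected(members))


def run_ics(
    X: np.ndarray,
    labels,
    grid: VoxelGrid,
    bins: int = 8,
    standardize: bool = True,
    memoize: bool = True,
    affinity: rel.AffinityModel | None = None,
    keep_trace: bool = False,
    redundancy_cache: RedundancyCache | None = None,
    verbose: bool = False,
) -> ICSResult:
    """Run the full search: one cluster per in-space voxel as origin.

    The spectral cache is precomputed once before the loop; the redundancy
    cache is shared across origins. Deterministic given (X, labels, config).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != grid.n_voxels:
        raise ValueError(
            f"X has {X.shape[0]} voxel rows but the grid has {grid.n_voxels}")
    if affinity is None:
        if labels is None:
            affinity = rel.build_affinity_unsupervised(X)
        else:
            affinity = rel.build_affinity(labels)
    if labels is not None and len(np.asarray(labels)) != X.shape[1]:
        raise ValueError("labels length does not match subject count")
    Xs = rel.standardize_voxels(X) if standardize else X
    cache = rel.build_spectral_cache(Xs, affinity, standardize=False)
    red = redundancy_cache if redundancy_cache is not None else RedundancyCache(
        bins=bins, memoize=memoize)
    clusters = []
    for origin in range(grid.n_voxels):
        if memoize:
            c = grow_cluster(origin, grid, cache, red, Xs, keep_trace=keep_trace)
        else:
            c = grow_cluster_reference(origin, grid, X, affinity, bins=bins,
                                       standardize=standardize)
        if verbose:
            logger.info("origin %d: size=%d relevance=%.4g phases=%d",
                        origin, c.size, c.relevance, c.n_phases)
        clusters.append(c)
    config = dict(bins=bins, standardize=standardize, memoize=memoize,
                  connectivity=grid.connectivity, mode=affinity.mode)
    return ICSResult(clusters=clusters, config=config)


class InformationClusterSearch(TransformerMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the information cluster search.

    Fits on an (n_subjects, n_voxels) matrix of time-averaged activations
    plus binary (or multi-class) labels, and discovers one information
    cluster per voxel. `transform` selects the union of voxels of the top
    clusters, so the estimator composes with sklearn pipelines.

    Parameters
    ----------
    mask : ndarray or None
        3D boolean mask defining the search space. If None, the voxels are
        assumed to fill a full cuboid of shape `shape`.
    shape : tuple or None
        Grid shape when `mask` is None.
    connectivity : int, default 26
        Voxel neighborhood (6, 18 or 26).
    bins : int, default 8
        Quantile-binning level for the mutual-information pruner.
    standardize : bool, default True
        Standardize each voxel across subjects before scoring.
    memoize : bool, default True
        Use the cached implementation (results are identical either way).
    n_select : int, default 50
        Number of top clusters whose member union `transform` keeps.
    select_by : {"relevance", "information"}, default "relevance"
        Ranking used by `transform`; "information" requires
        `estimate_information` to have been called.

    Attributes
    ----------
    grid_ : VoxelGrid
    result_ : ICSResult
    clusters_ : list of InformationCluster
    relevance_ : ndarray, per-origin relevance scores
    information_ : ndarray, per-origin CV-AUC (after `estimate_information`)
    """

    def __init__(self, mask=None, shape=None, connectivity: int = 26,
                 bins: int = 8, standardize: bool = True, memoize: bool = True,
                 n_select: int = 50, select_by: str = "relevance"):
        self.mask = mask
        self.shape = shape
        self.connectivity = connectivity
        self.bins = bins
        self.standardize = standardize
        self.memoize = memoize
        self.n_select = n_select
        self.select_by = select_by

    def _make_grid(self, n_voxels: int) -> VoxelGrid:
        if self.mask is not None:
            grid = build_grid(np.asarray(self.mask), connectivity=self.connectivity)
        else:
            if self.shape is None:
                raise ValueError("either mask or shape must be given")
            grid = build_grid(np.ones(self.shape, dtype=bool),
                              connectivity=self.connectivity)
        if grid.n_voxels != n_voxels:
            raise ValueError(
                f"X has {n_voxels} voxel columns but the mask has "
                f"{grid.n_voxels} in-space voxels")
        return grid

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_subjects, n_voxels)")
        self.grid_ = self._make_grid(X.shape[1])
        self.n_features_in_ = X.shape[1]
        self.result_ = run_ics(X.T, y, self.grid_, bins=self.bins,
                               standardize=self.standardize, memoize=self.memoize)
        self.clusters_ = self.result_.clusters
        self.relevance_ = self.result_.relevance_map()
        return self

    def estimate_information(self, X, y, folds: int = 5, random_state: int = 0):
        """Score every cluster's feature set by cross-validated AUC and store
        the per-origin values in `information_`."""
        check_is_fitted(self, "clusters_")
        from .evaluate import cluster_information
        X = np.asarray(X, dtype=float)
        for c in self.clusters_:
            c.information = cluster_information(X.T, y, c.members, folds=folds,
                                                seed=random_state)
        self.information_ = self.result_.information_map()
        return self.information_

    def get_support(self) -> np.ndarray:
        """Boolean mask over voxels: union of the top `n_select` clusters."""
        check_is_fitted(self, "clusters_")
        if self.select_by == "information":
            if getattr(self, "information_", None) is None:
                raise ValueError("call estimate_information before selecting "
                                 "by information")
            keys = self.information_
        else:
            keys = self.relevance_
        order = np.lexsort((np.arange(len(keys)), -np.asarray(keys)))
        support = np.zeros(self.n_features_in_, dtype=bool)
        for origin in order[: self.n_select]:
            support[self.clusters_[origin].members] = True
        return support

    def transform(self, X):
        check_is_fitted(self, "clusters_")
        return np.asarray(X)[:, self.get_support()]
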