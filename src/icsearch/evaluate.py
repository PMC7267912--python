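"""Baselines and evaluation: searchlight, L1 map, cluster information, metrics.

The searchlight baseline slides a truncated Euclidean sphere over the grid
and assigns the sphere's spectral trace-ratio score to its center voxel —
the same relevance measure the cluster search uses, so the two maps differ
only in how voxel sets are formed. The L1 baseline scores voxels by the
absolute coefficients of an L1-penalized linear model. A cluster's reported
*information* is the stratified cross-validated AUC of a linear max-margin
classifier restricted to the cluster's voxels, which anchors "chance" at 0.5
for the above-chance selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import relevance as rel
from .grid import VoxelGrid
from .search import ICSResult


@dataclass
class InformationMap:
    """Per-voxel score vector aligned to the grid's linear indexing."""

    scores: np.ndarray
    method: str  # "ics" | "searchlight" | "l1"
    params: dict[str, Any] = field(default_factory=dict)


def searchlight_map(
    X: np.ndarray,
    labels,
    grid: VoxelGrid,
    radius: float = 3,
    cache: rel.SpectralCache | None = None,
    standardize: bool = True,
) -> InformationMap:
    """Assign each voxel the spectral score of its surrounding sphere."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if cache is None:
        model = rel.build_affinity(labels)
        cache = rel.build_spectral_cache(np.asarray(X, dtype=float), model,
                                         standardize=standardize)
    scores = np.empty(grid.n_voxels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for v in range(grid.n_voxels):
            scores[v] = rel.cluster_score(cache, grid.sphere(v, radius))
    return InformationMap(scores=scores, method="searchlight",
                          params={"radius": radius})


def l1_baseline_map(
    X: np.ndarray,
    labels,
    alpha: float = 0.001,
    max_iter: int = 5000,
) -> InformationMap:
    """Per-voxel |coefficient| of an L1-penalized logistic model.

    `alpha` is the lasso penalty weight on the mean loss (sklearn
    C = 1 / (n * alpha)); voxels shrunk to zero score 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    model = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                               C=1.0 / (n * alpha), max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X.T, np.asarray(labels))
        except ConvergenceWarning as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"L1 model did not converge (alpha={alpha}, max_iter={max_iter}): "
                f"{exc}") from exc
    return InformationMap(scores=np.abs(model.coef_).max(axis=0),
                          method="l1", params={"alpha": alpha})


def cluster_information(
    X: np.ndarray,
    labels,
    members: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV AUC of a linear SVM on the member voxels only."""
    members = np.atleast_1d(np.asarray(members, dtype=np.int64))
    if members.size < 1:
        raise ValueError("members must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(labels)
    if np.bincount(np.unique(y, return_inverse=True)[1]).min() < folds:
        raise ValueError("stratification failed: a class has fewer subjects "
                         "than folds")
    feats = np.asarray(X, dtype=float)[members].T
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = SVC(kernel="linear")
    return float(np.mean(cross_val_score(clf, feats, y, cv=cv, scoring="roc_auc")))


def holdout_information(
    X: np.ndarray,
    labels,
    members: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> float:
    """Held-out AUC of a linear SVM on the member voxels.

    The unbiased companion of :func:`cluster_information`: clusters are
    extracted from the training subjects only and their information is the
    test-set AUC, so selection effects do not inflate the score.
    """
    from sklearn.metrics import roc_auc_score
    members = np.atleast_1d(np.asarray(members, dtype=np.int64))
    y = np.asarray(labels)
    feats = np.asarray(X, dtype=float)[members].T
    clf = SVC(kernel="linear")
    clf.fit(feats[train_idx], y[train_idx])
    return float(roc_auc_score(y[test_idx], clf.decision_function(feats[test_idx])))


def select_features(
    result: ICSResult | InformationMap,
    rule: str = "above_chance",
    k: int = 50,
    by: str = "information",
) -> list[np.ndarray]:
    """Select cluster feature sets (ICS) or voxels (maps) by information.

    above_chance keeps scores strictly above 0.5; top_k keeps the k highest
    (ties by origin/voxel linear index). For an ICSResult each returned array
    is a cluster's member set; for an InformationMap each is a single voxel.
    """
    if rule not in ("above_chance", "top_k"):
        raise ValueError(f"unknown rule {rule!r}")
    if isinstance(result, ICSResult):
        scores = (result.information_map() if by == "information"
                  else result.relevance_map())
        if np.isnan(scores).any():
            raise ValueError("information scores not populated")
        sets = [c.members for c in result.clusters]
    else:
        scores = np.asarray(result.scores, dtype=float)
        sets = [np.array([v]) for v in range(len(scores))]
    if rule == "above_chance":
        keep = np.nonzero(scores > 0.5)[0]
        order = keep[np.lexsort((keep, -scores[keep]))]
    else:
        order = np.lexsort((np.arange(len(scores)), -scores))[:k]
    return [sets[i] for i in order]


def detection_metrics(
    detected: np.ndarray,
    truth: np.ndarray,
    grid: VoxelGrid,
) -> tuple[float, float, float]:
    """(TPR, FPR, FNR) of a detected voxel set against ground truth."""
    truth = set(int(v) for v in np.asarray(truth, dtype=np.int64).ravel())
    if not truth:
        raise ValueError("truth set must be non-empty")
    detected = set(int(v) for v in np.asarray(detected, dtype=np.int64).ravel())
    negatives = grid.n_voxels - len(truth)
    tpr = len(detected & truth) / len(truth)
    fpr = len(detected - truth) / negatives if negatives else 0.0
    return tpr, fpr, 1.0 - tpr


def best_cluster(
    result: ICSResult,
    X: np.ndarray,
    labels,
    preselect: int = 50,
    folds: int = 5,
    seed: int = 0,
):
    """Highest-information cluster, preselected by relevance.

    The `preselect` top-relevance clusters are scored by cross-validated AUC
    and the highest-information one is returned (ties: higher relevance,
    then lower origin index). Mirrors the top-k-then-classify protocol while
    keeping the expensive AUC scoring to a shortlist.
    """
    relev = result.relevance_map()
    shortlist = np.lexsort((np.arange(len(relev)), -relev))[:preselect]
    scored = []
    for i in shortlist:
        info = cluster_information(X, labels, result.clusters[i].members,
                                   folds=folds, seed=seed)
        scored.append((info, float(relev[i]), -int(i)))
    j = max(range(len(shortlist)), key=lambda k: scored[k])
    c = result.clusters[int(shortlist[j])]
    c.information = scored[j][0]
    return c


def ics_detected_voxels(result: ICSResult, k: int = 50,
                        by: str = "relevance") -> np.ndarray:
    """Union of member voxels of the top-k clusters."""
    scores = (result.information_map() if by == "information"
              else result.relevance_map())
    order = np.lexsort((np.arange(len(scores)), -scores))[:k]
    if len(order) == 0:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate([result.clusters[i].members for i in order]))


def searchlight_detected_voxels(smap: InformationMap, grid: VoxelGrid,
                                radius: float, k: int = 50) -> np.ndarray:
    """Union of the spheres of the top-k center voxels."""
    order = np.lexsort((np.arange(len(smap.scores)), -smap.scores))[:k]
    if len(order) == 0:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate([grid.sphere(int(v), radius) for v in order]))


def l1_detected_voxels(lmap: InformationMap) -> np.ndarray:
    """Voxels with nonzero L1 coefficients."""
    return np.nonzero(lmap.scores > 0)[0]


def f1_score_sets(detected: np.ndarray, truth: np.ndarray) -> float:
    """F1 of a detected voxel set against the truth set."""
    detected = set(int(v) for v in np.asarray(detected).ravel())
    truth = set(int(v) for v in np.asarray(truth).ravel())
    tp = len(detected & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(detected)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


class SearchlightMapper(BaseEstimator):
    """Sklearn-style wrapper for the searchlight baseline.

    fit(X, y) with X of shape (n_subjects, n_voxels) stores the per-voxel
    sphere scores in `scores_`.
    """

    def __init__(self, mask=None, shape=None, connectivity: int = 26,
                 radius: float = 3, standardize: bool = True):
        self.mask = mask
        self.shape = shape
        self.connectivity = connectivity
        self.radius = radius
        self.standardize = standardize

    def fit(self, X, y):
        from .search import InformationClusterSearch
        X = np.asarray(X, dtype=float)
        self.grid_ = InformationClusterSearch(
            mask=self.mask, shape=self.shape,
            connectivity=self.connectivity)._make_grid(X.shape[1])
        self.map_ = searchlight_map(X.T, y, self.grid_, radius=self.radius,
                                    standardize=self.standardize)
        self.scores_ = self.map_.scores
        self.n_features_in_ = X.shape[1]
        return self


class L1Mapper(BaseEstimator):
    """Sklearn-style wrapper for the L1-penalized linear baseline."""

    def __init__(self, alpha: float = 0.001, max_iter: int = 5000):
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.map_ = l1_baseline_map(X.T, y, alpha=self.alpha,
                                    max_iter=self.max_iter)
        self.scores_ = self.map_.scores
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "scores_")
        return self.scores_ > 0
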