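"""Redundancy pruning: pairwise voxel mutual information and greedy removal.

A member's redundancy J is its mean mutual information with the other members
of its cluster. MI is estimated on equal-frequency (quantile) discretized
values, in nats, via the joint histogram. Pairwise MI values are filled into
a sparse cache only when a pair is actually visited by the search — most
pairs never are, so the interaction matrix stays sparse and concentrated
near spatially adjacent pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relevance import SpectralCache, cluster_score


def quantile_bin_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize a vector into `bins` equal-frequency levels.

    Bin edges are interior quantiles; tied values always share a code, so a
    constant vector collapses to a single occupied bin.
    """
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.arange(1, bins) / bins)
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _mi_from_codes(ci: np.ndarray, cj: np.ndarray, bins: int) -> float:
    # plug-in MI of the joint histogram, in nats, with 0*log(0) := 0
    joint = np.bincount(ci * bins + cj,
                        minlength=bins * bins).reshape(bins, bins) / len(ci)
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] /
                                           np.outer(pi, pj)[nz])))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """Mutual information (nats) between two voxels' per-subject values.

    Both vectors are quantile-binned into `bins` levels and MI is computed
    from the joint histogram with the 0*log(0) := 0 convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 2 * bins:
        raise ValueError(f"need at least 2*bins={2 * bins} samples, got {len(x)}")
    return _mi_from_codes(quantile_bin_codes(x, bins), quantile_bin_codes(y, bins), bins)


@dataclass
class RedundancyCache:
    """Lazily-filled sparse table of pairwise voxel MI.

    `memoize=False` recomputes every request from scratch (the no-cache
    reference path); results are identical either way. Bin codes per voxel
    are themselves computed once on first use.
    """

    bins: int = 8
    memoize: bool = True
    mi: dict[tuple[int, int], float] = field(default_factory=dict)
    _codes: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def n_computed_pairs(self) -> int:
        return len(self.mi)

    def computed_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.mi)

    def _codes_for(self, i: int, X: np.ndarray) -> np.ndarray:
        if not self.memoize:
            return quantile_bin_codes(X[i], self.bins)
        c = self._codes.get(i)
        if c is None:
            c = quantile_bin_codes(X[i], self.bins)
            self._codes[i] = c
        return c

    def get(self, i: int, j: int, X: np.ndarray) -> float:
        key = (i, j) if i < j else (j, i)
        if self.memoize and key in self.mi:
            return self.mi[key]
        if X.shape[1] < 2 * self.bins:
            raise ValueError(
                f"need at least 2*bins={2 * self.bins} subjects for MI at "
                f"bins={self.bins}, got {X.shape[1]}")
        # canonical argument order so cached and fresh paths are bit-identical
        value = _mi_from_codes(self._codes_for(key[0], X),
                               self._codes_for(key[1], X), self.bins)
        if self.memoize:
            self.mi[key] = value
        return value

    def to_triplets(self) -> np.ndarray:
        """Sparse (i, j, mi) triplet table of all computed pairs."""
        if not self.mi:
            return np.empty((0, 3))
        return np.array([(i, j, v) for (i, j), v in sorted(self.mi.items())])


def redundancy_score(
    cache: RedundancyCache,
    members: np.ndarray,
    target: int,
    X: np.ndarray,
) -> float:
    """J = mean MI between `target` and the other cluster members."""
    members = np.asarray(members, dtype=np.int64)
    if len(members) < 2:
        raise ValueError("redundancy undefined for singleton cluster")
    if target not in members:
        raise ValueError("target must be a cluster member")
    others = members[members != target]
    return float(np.mean([cache.get(target, int(k), X) for k in others]))


def prune(
    members: np.ndarray,
    protected: np.ndarray,
    spectral_cache: SpectralCache,
    redundancy_cache: RedundancyCache,
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy redundancy-driven removal, gated by cluster relevance.

    Repeatedly pick the unprotected member with the largest redundancy J
    (ties -> lowest linear index) and remove it iff removal does not decrease
    the cluster's relevance score; stop as soon as the designated candidate
    fails the gate, or no unprotected member remains, or the cluster would
    drop below two members. Returns (kept members, removed members); the
    removed set is the next expansion's exclusion set.
    """
    members = np.asarray(members, dtype=np.int64).copy()
    protected_set = set(int(v) for v in np.asarray(protected, dtype=np.int64))
    removed: list[int] = []
    while len(members) >= 2:
        candidates = [int(v) for v in members if int(v) not in protected_set]
        if not candidates:
            break
        # J recomputed from the cache each round (cheap dict hits), keeping
        # the summation order identical to a from-scratch computation
        J = np.array([redundancy_score(redundancy_cache, members, c, X)
                      for c in candidates])
        best = candidates[int(np.argmax(J))]  # first max -> lowest linear index
        current = cluster_score(spectral_cache, members)
        without = cluster_score(spectral_cache, members[members != best])
        if without >= current:
            members = members[members != best]
            removed.append(best)
        else:
            break
    return members, np.array(sorted(removed), dtype=np.int64)
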