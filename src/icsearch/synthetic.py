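"""Synthetic fMRI-like datasets with known ground truth.

Each subject gets a voxel x time matrix of Gaussian noise. Spatial
correlation between adjacent voxels is induced by mixing every voxel's
series with the mean of its 6-neighbors' series; the mixing weight is solved
analytically for a target adjacent-pair correlation. Subjects of the second
class additionally receive a condition-locked spatial pattern whose
amplitude (in baseline-SD units) fades in and out over the scan following a
peak-normalized double-gamma hemodynamic-response-shaped envelope. Time
series are then averaged to produce the subjects x voxels activation matrix
the search operates on.

A separate helper simulates regional atrophy by scaling the case group's
signal inside a mask, for detection-rate (TPR/FPR/FNR) experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import gamma

from .grid import VoxelGrid, build_grid

#: largest adjacent-voxel correlation reachable by 6-neighbor mean mixing
MAX_RHO = 1.0 / np.sqrt(6.0)

#: preset search-space sizes (voxel counts) used across experiments
PRESET_SHAPES = {
    "tiny": (5, 5, 4),        # 100 voxels
    "small": (10, 10, 5),     # 500 voxels
    "medium": (25, 20, 20),   # 10,000 voxels
    "large": (31, 31, 31),    # ~30,000 voxels
}


def double_gamma_envelope(T: int, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic-response-shaped curve sampled at T
    points over `duration` seconds, peak-normalized to 1."""
    t = np.linspace(0.0, duration, T)
    h = gamma.pdf(t, 6.0) - gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def mixing_weight(rho: float, n_neighbors: int = 6) -> float:
    """Neighbor-mean mixing weight `a` reaching adjacent correlation `rho`.

    For y_v = g_v + (a/m) sum of m neighbor series (unit-variance g, interior
    voxel, no shared neighbors between adjacent pairs on the cubic lattice):

        corr(y_u, y_v) = (2a/m) / (1 + a^2/m)

    which is solvable for a iff rho <= 1/sqrt(m).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    if rho == 0.0:
        return 0.0
    m = float(n_neighbors)
    if rho > 1.0 / np.sqrt(m) + 1e-12:
        raise ValueError(
            f"target rho={rho} exceeds the {1 / np.sqrt(m):.3f} ceiling of "
            "neighbor-mean mixing")
    disc = 1.0 - m * rho * rho
    return float(m * (1.0 - np.sqrt(max(disc, 0.0))) / (2.0 * rho) * (2.0 / m))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Amplitudes are in units of the per-timepoint noise SD; after averaging
    over T timepoints the effective per-voxel effect is
    amplitude * mean(envelope) against a noise SD of roughly
    baseline_sd / sqrt(T).
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    n_per_class: tuple[int, int] = (500, 500)
    T: int = 120
    baseline_sd: float = 1.0
    baseline_mean: float = 0.0
    spatial_noise_rho: float = 0.3
    planted_sets: list[tuple[np.ndarray, float]] = field(default_factory=list)
    envelope: np.ndarray | None = None
    seed: int = 0


def _mixing_operator(grid: VoxelGrid, rho: float) -> sp.csr_matrix | None:
    """Sparse operator M with (M @ G) the mixed, variance-renormalized noise.

    Mixing always uses 6-connectivity (the geometry the calibration is
    derived for), independent of the grid's search connectivity.
    """
    if rho == 0.0:
        return None
    a = mixing_weight(rho)
    grid6 = (grid if grid.connectivity == 6 else
             build_grid(grid.in_space, connectivity=6))
    p = grid6.n_voxels
    rows, cols, vals = [], [], []
    norm = np.ones(p)
    for v in range(p):
        nb = grid6.neighbors(v)
        m = len(nb)
        if m:
            norm[v] = np.sqrt(1.0 + a * a / m)
            rows.extend([v] * m)
            cols.extend(nb.tolist())
            vals.extend([a / m] * m)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(p, p))
    M = M + sp.identity(p, format="csr")
    return sp.diags(1.0 / norm) @ M


def generate_dataset(
    spec: SyntheticSpec,
    grid: VoxelGrid | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X voxels x subjects, labels, ground-truth voxel indices).

    Deterministic given `spec.seed`. Class labels are 0 (controls) and 1
    (the condition carrying the planted patterns).
    """
    if grid is None:
        grid = build_grid(np.ones(spec.shape, dtype=bool))
    p = grid.n_voxels
    for voxels, _ in spec.planted_sets:
        voxels = np.asarray(voxels)
        if voxels.size and (voxels.min() < 0 or voxels.max() >= p):
            raise ValueError("planted voxel outside the grid")
    if not 0.0 <= spec.spatial_noise_rho < 1.0:
        raise ValueError("spatial_noise_rho must be in [0, 1)")
    env = (double_gamma_envelope(spec.T) if spec.envelope is None
           else np.asarray(spec.envelope, dtype=float))
    if len(env) != spec.T:
        raise ValueError("envelope length must equal T")
    rng = np.random.default_rng(spec.seed)
    M = _mixing_operator(grid, spec.spatial_noise_rho)
    n0, n1 = spec.n_per_class
    labels = np.repeat([0, 1], [n0, n1])
    X = np.empty((p, n0 + n1))
    signal = np.zeros((p, spec.T))
    for voxels, amplitude in spec.planted_sets:
        signal[np.asarray(voxels, dtype=np.int64)] += amplitude * spec.baseline_sd * env
    for s in range(n0 + n1):
        G = rng.standard_normal((p, spec.T)) * spec.baseline_sd
        if M is not None:
            G = M @ G
        if labels[s] == 1:
            G = G + signal
        X[:, s] = G.mean(axis=1) + spec.baseline_mean
    truth = (np.unique(np.concatenate([np.asarray(v, dtype=np.int64)
                                       for v, _ in spec.planted_sets]))
             if spec.planted_sets else np.array([], dtype=np.int64))
    return X, labels, truth


def planted_block(grid: VoxelGrid, corner: tuple[int, int, int],
                  size: tuple[int, int, int]) -> np.ndarray:
    """Linear indices of a cuboid block of in-space voxels (ground truth)."""
    idx = grid.index_volume[corner[0]:corner[0] + size[0],
                            corner[1]:corner[1] + size[1],
                            corner[2]:corner[2] + size[2]]
    idx = idx[idx >= 0]
    if idx.size != np.prod(size):
        raise ValueError("planted block extends outside the in-space region")
    return np.sort(idx.ravel())


def simulate_atrophy(
    X: np.ndarray,
    labels: np.ndarray,
    mask_voxels: np.ndarray,
    fraction: float,
    case_label=1,
) -> np.ndarray:
    """Scale the case group's signal in `mask_voxels` by (1 - fraction).

    Controls are untouched. Models regional signal loss (atrophy); detection
    experiments compare recovered voxels against `mask_voxels` as truth.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    X = np.array(X, dtype=float, copy=True)
    labels = np.asarray(labels)
    mask_voxels = np.asarray(mask_voxels, dtype=np.int64)
    if mask_voxels.size and mask_voxels.max() >= X.shape[0]:
        raise ValueError("mask voxel outside the search space")
    case = np.nonzero(labels == case_label)[0]
    X[np.ix_(mask_voxels, case)] *= 1.0 - fraction
    return X
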