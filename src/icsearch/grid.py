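"""Voxel search space: 3D lattice, mask handling, and neighborhood queries.

The search operates on the set of *in-space* voxels (nonzero voxels of a 3D
mask). Each in-space voxel gets a linear index assigned in lexicographic
(i, j, k) array order; that order also defines every deterministic tie-break
used downstream. Adjacency is configurable as 6- (faces), 18- (faces+edges)
or 26-connectivity (faces+edges+corners).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

CONNECTIVITIES = (6, 18, 26)


def connectivity_offsets(connectivity: int) -> np.ndarray:
    """Integer (di, dj, dk) offsets for a voxel neighborhood.

    6 keeps offsets at city-block distance 1, 18 adds edge neighbors,
    26 the full 3x3x3 shell minus the center.
    """
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}, got {connectivity}")
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(x) for x in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offsets.append(d)
    return np.asarray(offsets, dtype=np.int64)


@dataclass
class VoxelGrid:
    """In-space voxel lattice with a fixed linear indexing.

    Attributes
    ----------
    shape : tuple of int
        (nx, ny, nz) of the enclosing volume.
    in_space : ndarray of bool, shape (nx, ny, nz)
        True for voxels inside the search mask.
    connectivity : int
        6, 18 or 26.
    affine : ndarray or None
        Voxel-to-world affine carried along from NIfTI input, if any.
    coords : ndarray of int, shape (p, 3)
        Grid coordinates of in-space voxels in linear-index order
        (lexicographic array order).
    """

    shape: tuple[int, int, int]
    in_space: np.ndarray
    connectivity: int = 26
    affine: np.ndarray | None = None
    coords: np.ndarray = field(init=False)
    index_volume: np.ndarray = field(init=False)
    _neighbor_lists: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.in_space = np.asarray(self.in_space, dtype=bool)
        if self.in_space.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        if not self.in_space.any():
            raise ValueError("empty search space: mask has no nonzero voxels")
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
        # np.argwhere scans in C order == lexicographic (i, j, k)
        self.coords = np.argwhere(self.in_space)
        self.index_volume = np.full(self.shape, -1, dtype=np.int64)
        self.index_volume[tuple(self.coords.T)] = np.arange(len(self.coords))
        self._neighbor_lists = self._build_neighbor_lists()

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def _build_neighbor_lists(self) -> list[np.ndarray]:
        offsets = connectivity_offsets(self.connectivity)
        nbrs: list[list[int]] = [[] for _ in range(self.n_voxels)]
        shape = np.asarray(self.shape)
        for off in offsets:
            shifted = self.coords + off
            valid = np.all((shifted >= 0) & (shifted < shape), axis=1)
            idx = np.nonzero(valid)[0]
            j = self.index_volume[tuple(shifted[idx].T)]
            ok = j >= 0
            for i, jj in zip(idx[ok], j[ok]):
                nbrs[i].append(int(jj))
        return [np.array(sorted(v), dtype=np.int64) for v in nbrs]

    def neighbors(self, voxel: int) -> np.ndarray:
        """Linear indices of in-space voxels adjacent to `voxel`."""
        return self._neighbor_lists[voxel]

    def cluster_neighbors(
        self,
        members: np.ndarray,
        excluded: np.ndarray | None = None,
    ) -> np.ndarray:
        """All in-space voxels adjacent to >=1 member, minus members and `excluded`.

        `excluded` is the anti-loop set: voxels removed by the immediately
        preceding prune, ineligible for the next expansion only.
        """
        members = np.asarray(members, dtype=np.int64)
        mask = np.zeros(self.n_voxels, dtype=bool)
        for m in members:
            mask[self._neighbor_lists[m]] = True
        mask[members] = False
        if excluded is not None and len(excluded):
            mask[np.asarray(excluded, dtype=np.int64)] = False
        return np.nonzero(mask)[0]

    def sphere(self, center: int, radius: float) -> np.ndarray:
        """In-space voxels within Euclidean distance `radius` of `center`.

        Includes the center itself; truncated at the mask boundary (standard
        searchlight convention).
        """
        c = self.coords[center]
        r = int(np.floor(radius))
        lo = np.maximum(c - r, 0)
        hi = np.minimum(c + r + 1, np.asarray(self.shape))
        block = self.index_volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        pts = np.argwhere(block >= 0) + lo
        d2 = ((pts - c) ** 2).sum(axis=1)
        keep = pts[d2 <= radius * radius + 1e-9]
        return np.sort(self.index_volume[tuple(keep.T)])

    def is_connected(self, members: np.ndarray) -> bool:
        """Whether `members` form a single connected component under the grid's
        connectivity. Pruning may disconnect a cluster; the search keeps the
        set but flags this."""
        members = np.asarray(members, dtype=np.int64)
        if len(members) <= 1:
            return True
        in_set = np.zeros(self.n_voxels, dtype=bool)
        in_set[members] = True
        seen = np.zeros(self.n_voxels, dtype=bool)
        stack = [int(members[0])]
        seen[members[0]] = True
        count = 1
        while stack:
            v = stack.pop()
            for u in self._neighbor_lists[v]:
                if in_set[u] and not seen[u]:
                    seen[u] = True
                    count += 1
                    stack.append(int(u))
        return count == len(members)


def build_grid(
    mask: np.ndarray,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> VoxelGrid:
    """Build a :class:`VoxelGrid` from a 3D mask (any nonzero voxel is in-space)."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got {mask.ndim}D")
    return VoxelGrid(
        shape=tuple(mask.shape),
        in_space=mask != 0,
        connectivity=connectivity,
        affine=affine,
    )


def cluster_neighbors(
    grid: VoxelGrid,
    members: np.ndarray,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Functional alias for :meth:`VoxelGrid.cluster_neighbors`."""
    return grid.cluster_neighbors(members, excluded)
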