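"""Readers and writers: matrix/label TSV, NIfTI volumes, result tables.

TSV dialect: the activation matrix has a header row of voxel linear indices
and a first column of subject IDs; the label table has columns subject, label.
NIfTI masks treat any nonzero voxel as in-space and the input affine is
carried through to every written map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .evaluate import InformationMap
from .grid import VoxelGrid, build_grid
from .search import ICSResult


def save_matrix_tsv(path, X: np.ndarray, subjects=None) -> None:
    """Write a voxels x subjects matrix as a subjects-by-voxels TSV."""
    X = np.asarray(X)
    n = X.shape[1]
    ids = [f"sub-{i:04d}" for i in range(n)] if subjects is None else list(subjects)
    df = pd.DataFrame(X.T, index=pd.Index(ids, name="subject"),
                      columns=np.arange(X.shape[0]))
    df.to_csv(path, sep="\t")


def load_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Read the matrix TSV back as (voxels x subjects, subject IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float).T, list(df.index.astype(str))


def save_labels_tsv(path, labels, subjects=None) -> None:
    labels = np.asarray(labels)
    ids = ([f"sub-{i:04d}" for i in range(len(labels))]
           if subjects is None else list(subjects))
    pd.DataFrame({"subject": ids, "label": labels}).to_csv(path, sep="\t",
                                                           index=False)


def load_labels_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["label"].to_numpy()


def load_mask(path, connectivity: int = 26) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return build_grid(data, connectivity=connectivity, affine=img.affine)


def load_subjects(paths, mask_path, connectivity: int = 26):
    """Time-average 4D NIfTI images within a mask into a voxels x subjects matrix.

    All images must share shape and affine with the mask; the offending file
    is named otherwise.
    """
    grid = load_mask(mask_path, connectivity=connectivity)
    columns = []
    for path in paths:
        img = nib.load(str(path))
        if img.shape[:3] != grid.shape:
            raise ValueError(f"shape mismatch with mask: {path}")
        if grid.affine is not None and not np.allclose(img.affine, grid.affine):
            raise ValueError(f"affine mismatch with mask: {path}")
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., None]
        columns.append(data[tuple(grid.coords.T)].mean(axis=1))
    return np.column_stack(columns), grid


def map_to_volume(scores: np.ndarray, grid: VoxelGrid,
                  fill: float = 0.0) -> np.ndarray:
    vol = np.full(grid.shape, fill, dtype=float)
    vol[tuple(grid.coords.T)] = scores
    return vol


def write_map_nifti(path, scores: np.ndarray, grid: VoxelGrid) -> None:
    affine = grid.affine if grid.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(map_to_volume(scores, grid), affine), str(path))


def load_map_nifti(path, grid: VoxelGrid) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    return data[tuple(grid.coords.T)]


def overlap_map(result: ICSResult, grid: VoxelGrid) -> np.ndarray:
    """Per-voxel visualization value resolving overlaps: each voxel shows the
    highest information among the clusters containing it (higher-quality
    clusters overshadow lower ones)."""
    info = result.information_map()
    values = np.full(grid.n_voxels, np.nan)
    for c, v in zip(result.clusters, info):
        if np.isnan(v):
            continue
        m = c.members
        cur = values[m]
        values[m] = np.where(np.isnan(cur) | (v > cur), v, cur)
    return values


def save_interaction_tsv(path, cache) -> None:
    """Write the computed pairwise-MI entries as a (voxel_i, voxel_j, mi)
    triplet TSV for interaction-matrix inspection."""
    trip = cache.to_triplets()
    pd.DataFrame(trip, columns=["voxel_i", "voxel_j", "mi"]).astype(
        {"voxel_i": int, "voxel_j": int}).to_csv(path, sep="\t", index=False)


def cluster_table(result: ICSResult, grid: VoxelGrid) -> pd.DataFrame:
    rows = []
    for c in result.clusters:
        i, j, k = grid.coords[c.origin]
        rows.append({
            "origin": c.origin, "x": i, "y": j, "z": k,
            "size": c.size, "relevance": c.relevance,
            "information": np.nan if c.information is None else c.information,
            "connected": c.connected,
            "members": ",".join(str(int(v)) for v in c.members),
        })
    return pd.DataFrame(rows, columns=["origin", "x", "y", "z", "size",
                                       "relevance", "information",
                                       "connected", "members"])


def write_outputs(result: ICSResult, maps: list[InformationMap],
                  grid: VoxelGrid, outdir) -> list[Path]:
    """Write the cluster table, per-method maps, overlap map and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    table = cluster_table(result, grid)
    path = outdir / "clusters.tsv"
    table.to_csv(path, sep="\t", index=False)
    written.append(path)

    path = outdir / "ics_relevance.nii.gz"
    write_map_nifti(path, result.relevance_map(), grid)
    written.append(path)

    info = result.information_map()
    if not np.isnan(info).all():
        path = outdir / "ics_information.nii.gz"
        write_map_nifti(path, np.nan_to_num(info, nan=0.0), grid)
        written.append(path)
        path = outdir / "ics_overlap.nii.gz"
        write_map_nifti(path, np.nan_to_num(overlap_map(result, grid), nan=0.0),
                        grid)
        written.append(path)

    for m in maps:
        path = outdir / f"{m.method}_map.nii.gz"
        write_map_nifti(path, m.scores, grid)
        written.append(path)

    path = outdir / "config.json"
    path.write_text(json.dumps({"config": result.config, "seed": result.seed},
                               indent=2, default=str))
    written.append(path)
    return written


def write_dataset(outdir, X: np.ndarray, labels: np.ndarray,
                  truth: np.ndarray, grid: VoxelGrid) -> list[Path]:
    """Write a synthetic dataset: matrix + labels TSV, mask and truth NIfTI,
    truth voxel-list TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_matrix_tsv(outdir / "matrix.tsv", X)
    save_labels_tsv(outdir / "labels.tsv", labels)
    affine = grid.affine if grid.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(grid.in_space.astype(np.uint8), affine),
             str(outdir / "mask.nii.gz"))
    truth_scores = np.zeros(grid.n_voxels)
    if len(truth):
        truth_scores[np.asarray(truth, dtype=np.int64)] = 1.0
    write_map_nifti(outdir / "truth.nii.gz", truth_scores, grid)
    pd.DataFrame({"voxel": np.asarray(truth, dtype=np.int64)}).to_csv(
        outdir / "truth.tsv", sep="\t", index=False)
    return [outdir / n for n in
            ("matrix.tsv", "labels.tsv", "mask.nii.gz", "truth.nii.gz",
             "truth.tsv")]
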