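"""Reading and writing the volumetric and tabular formats the pipeline touches.

Lesion masks, parcellations and statistic maps are NIfTI-1 volumes
(nibabel); covariates travel as delimited tables (pandas). All loaders
validate against the cohort grid and fail loudly, naming the offending file
or subject.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    AFFINE_ATOL,
    COVARIATES,
    CovariateTable,
    GridMismatchError,
    LesionCohort,
    Parcellation,
    VoxelGrid,
)

log = logging.getLogger(__name__)


def _grid_from_image(img: nib.Nifti1Image) -> VoxelGrid:
    return VoxelGrid(tuple(int(s) for s in img.shape[:3]), np.asarray(img.affine))


def load_lesion_masks(
    paths: Sequence[str | Path],
    ids: Sequence[str] | None = None,
) -> LesionCohort:
    """Assemble per-subject binary lesion volumes into a LesionCohort.

    All volumes must share shape and affine (within a small header-jitter
    tolerance). Any nonzero voxel counts as lesioned, so probabilistic or
    label masks are accepted.

    Parameters
    ----------
    paths:
        One NIfTI file per subject; column order follows this list.
    ids:
        Subject identifiers matching ``paths``; defaults to file stems.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no lesion mask paths given")
    if ids is None:
        ids = [p.name.removesuffix(".gz").removesuffix(".nii") for p in paths]
    if len(ids) != len(paths):
        raise ValueError("ids and paths have different lengths")

    grid: VoxelGrid | None = None
    columns = []
    for path, sid in zip(paths, ids):
        img = nib.load(str(path))
        g = _grid_from_image(img)
        if grid is None:
            grid = g
        elif not grid.same_as(g, atol=AFFINE_ATOL):
            raise GridMismatchError(
                f"volume {path} (shape {g.shape}) does not match the cohort grid "
                f"(shape {grid.shape}, affine tolerance {AFFINE_ATOL})"
            )
        data = np.asanyarray(img.dataobj)
        col = (data != 0).reshape(-1).astype(np.uint8)
        n_set = int(col.sum())
        if n_set == 0:
            raise ValueError(f"empty lesion mask for subject {sid!r} ({path})")
        if n_set == col.size:
            raise ValueError(f"lesion covers every voxel for subject {sid!r} ({path})")
        log.info("subject %s: %d lesion voxels", sid, n_set)
        columns.append(col)

    assert grid is not None
    return LesionCohort(grid, list(ids), np.column_stack(columns))


def load_covariates(
    path: str | Path,
    subject_order: Sequence[str] | None = None,
    id_column: str = "subject_id",
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    nihss_range_check: bool = True,
) -> CovariateTable:
    """Read a delimited covariate/outcome table and align it to a cohort.

    ``column_map`` maps canonical names (age, lesion_volume, followup_time,
    outcome) to the file's column headers. The delimiter is sniffed when not
    given. Outcome values outside the NIHSS 0-42 range trigger a warning,
    not an error, so other deficit scales remain usable.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, newline="") as fh:
            sample = fh.read(4096)
        delimiter = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    df = pd.read_csv(path, sep=delimiter)

    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in (id_column, *CovariateTable.REQUIRED)}
    rename = {src: dst for src, dst in rename.items() if src in df.columns}
    df = df.rename(columns=rename)

    if id_column not in df.columns and "subject_id" not in df.columns:
        raise ValueError(f"covariate table lacks an ID column {id_column!r}")
    idc = id_column if id_column in df.columns else "subject_id"
    df[idc] = df[idc].astype(str)
    df = df.set_index(idc)

    missing_cols = [c for c in CovariateTable.REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"covariate table missing column(s): {missing_cols}")

    for col in CovariateTable.REQUIRED:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r} for subject(s) "
                f"{bad.index.tolist()}"
            ) from exc

    if nihss_range_check:
        out = df["outcome"]
        oob = df.index[(out < 0) | (out > 42)].tolist()
        if oob:
            log.warning(
                "outcome outside NIHSS range 0-42 for subject(s) %s; "
                "values retained (range check is advisory)",
                oob,
            )

    table = CovariateTable(df[list(CovariateTable.REQUIRED)])
    if subject_order is not None:
        table = table.aligned_to(list(subject_order))
    return table


def load_parcellation(
    volume_path: str | Path,
    lut_path: str | Path,
    grid: VoxelGrid | None = None,
) -> Parcellation:
    """Load an integer-labelled atlas volume plus its two-column lookup table."""
    img = nib.load(str(volume_path))
    g = _grid_from_image(img)
    if grid is not None and not grid.same_as(g):
        raise GridMismatchError(
            f"parcellation {volume_path} is not on the cohort grid"
        )
    labels = np.rint(np.asanyarray(img.dataobj)).astype(np.int64).reshape(-1)

    names: dict[int, str] = {}
    lut = pd.read_csv(lut_path, sep=None, engine="python", header=None, comment="#")
    for _, row in lut.iterrows():
        label = int(row.iloc[0])
        if label == 0:
            continue
        names[label] = str(row.iloc[1])
    return Parcellation(g, labels, names)


def compute_lesion_volume(cohort: LesionCohort) -> np.ndarray:
    """Per-subject lesion volume in cm^3 (voxel count x voxel volume / 1000)."""
    counts = cohort.lesion_voxel_counts().astype(float)
    return counts * cohort.grid.voxel_volume_mm3 / 1000.0


def write_statistic_map(
    values: np.ndarray,
    mask: np.ndarray,
    grid: VoxelGrid,
    path: str | Path,
    mask_path: str | Path | None = None,
    fill: float = 0.0,
) -> None:
    """Write a per-voxel statistic restricted to a mask as a NIfTI volume.

    Background voxels are set to ``fill`` (default 0). Because 0 is a valid
    statistic, validity is defined by the companion binary mask volume
    written to ``mask_path`` (defaults to ``<path stem>_mask.nii.gz``), not
    by the fill value.
    """
    path = Path(path)
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    if mask.shape[0] != grid.n_voxels:
        raise ValueError("mask size does not match grid")
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.shape[0] == grid.n_voxels:
        values = values[mask]
    if values.shape[0] != int(mask.sum()):
        raise ValueError("values length matches neither the grid nor the mask")
    if not np.all(np.isfinite(values)):
        raise ValueError("statistic values must be finite on the mask")
    if mask.sum() == 0:
        log.warning("writing statistic map with empty mask: %s", path)

    vol = np.full(grid.n_voxels, fill, dtype=np.float32)
    vol[mask] = values.astype(np.float32)
    img = nib.Nifti1Image(vol.reshape(grid.shape), grid.affine)
    nib.save(img, str(path))

    if mask_path is None:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        mask_path = path.with_name(f"{stem}_mask.nii.gz")
    mimg = nib.Nifti1Image(mask.reshape(grid.shape).astype(np.uint8), grid.affine)
    nib.save(mimg, str(mask_path))


def read_statistic_map(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a statistic volume back as (flat float array, grid)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).reshape(-1).astype(float), _grid_from_image(img)


def write_mask_volumes(
    cohort: LesionCohort, out_dir: str | Path, prefix: str = "lesion_"
) -> list[Path]:
    """Write each cohort column as an individual binary NIfTI mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sid in enumerate(cohort.subject_ids):
        vol = cohort.lesions[:, j].reshape(cohort.grid.shape)
        img = nib.Nifti1Image(vol.astype(np.uint8), cohort.grid.affine)
        p = out_dir / f"{prefix}{sid}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    return paths
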