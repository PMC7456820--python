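"""Core in-memory containers shared across the pipeline.

All volumes live on a common :class:`VoxelGrid`. Lesion data is held as a
flat voxel x subject binary matrix so that the mass-univariate fits can be
expressed as dense linear algebra; conversion back to 3-D volumes goes
through the grid shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical covariate order used everywhere (design matrices, reports,
#: importance maps, tie-breaking).
COVARIATES: tuple[str, ...] = ("age", "lesion_volume", "followup_time")

#: Element-wise tolerance under which two affines count as the same grid.
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


@dataclass(frozen=True, eq=False)
class VoxelGrid:
    """Geometry of a common volumetric space.

    Parameters
    ----------
    shape:
        Number of voxels along each axis.
    affine:
        4x4 matrix mapping 0-based voxel indices to world coordinates (mm).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", affine)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.shape == other.shape and np.array_equal(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.tobytes()))

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine rotation block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        """Signed-volume magnitude of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_as(self, other: "VoxelGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size_mm: float = 1.0) -> "VoxelGrid":
        affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
        return cls(tuple(shape), affine)


@dataclass
class LesionCohort:
    """Stacked binary lesion masks over a common grid.

    ``lesions`` is a (V voxels x N subjects) uint8 matrix; column order
    matches ``subject_ids``. Every subject must have a non-empty,
    non-brain-filling lesion.
    """

    grid: VoxelGrid
    subject_ids: list[str]
    lesions: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject IDs must be unique")
        lesions = np.asarray(self.lesions)
        if lesions.ndim != 2:
            raise ValueError("lesions must be a 2-D voxel x subject matrix")
        if lesions.shape != (self.grid.n_voxels, len(self.subject_ids)):
            raise ValueError(
                f"lesion matrix shape {lesions.shape} does not match grid "
                f"({self.grid.n_voxels} voxels) x {len(self.subject_ids)} subjects"
            )
        if not np.isin(lesions, (0, 1)).all():
            raise ValueError("lesion matrix must be binary")
        counts = lesions.sum(axis=0)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise ValueError(
                "empty lesion mask for subject(s): "
                + ", ".join(self.subject_ids[i] for i in empty)
            )
        full = np.flatnonzero(counts == lesions.shape[0])
        if full.size:
            raise ValueError(
                "lesion covers every voxel for subject(s): "
                + ", ".join(self.subject_ids[i] for i in full)
            )
        self.lesions = lesions.astype(np.uint8, copy=False)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_voxels(self) -> int:
        return self.lesions.shape[0]

    def lesion_voxel_counts(self) -> np.ndarray:
        """Per-subject number of lesioned voxels."""
        return self.lesions.sum(axis=0).astype(int)


@dataclass
class CovariateTable:
    """Per-subject covariates and outcome, row-aligned to a LesionCohort.

    The outcome carries NIHSS semantics (integer 0-42) by convention but any
    real-valued deficit score is accepted; range checks are advisory.
    """

    data: pd.DataFrame  # index: subject id; columns: COVARIATES + outcome

    REQUIRED = COVARIATES + ("outcome",)

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"covariate table missing column(s): {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate subject IDs in covariate table")
        sub = self.data[list(self.REQUIRED)]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values for subject(s): {bad}")
        self.data = self.data.copy()
        self.data.index = self.data.index.map(str)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def covariate_matrix(self) -> np.ndarray:
        """N x 3 float array in canonical covariate order."""
        return self.data[list(COVARIATES)].to_numpy(dtype=float)

    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=float)

    def aligned_to(self, subject_ids: list[str]) -> "CovariateTable":
        """Reorder rows to the given subject order; error on missing IDs."""
        wanted = [str(s) for s in subject_ids]
        missing = [s for s in wanted if s not in self.data.index]
        if missing:
            raise ValueError(f"covariate table missing subject(s): {missing}")
        return CovariateTable(self.data.loc[wanted])


@dataclass
class Parcellation:
    """Integer-labelled atlas volume with a label -> region-name lookup."""

    grid: VoxelGrid
    labels: np.ndarray  # flat int array, length V; 0 = background
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        labels = labels.reshape(-1).astype(np.int64, copy=False)
        if labels.shape[0] != self.grid.n_voxels:
            raise ValueError("parcellation volume does not match its grid")
        if labels.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        present = {int(v) for v in np.unique(labels)} - {0}
        unnamed = sorted(present - set(self.names))
        if unnamed:
            raise ValueError(f"unnamed parcellation label(s): {unnamed}")
        if 0 in self.names:
            raise ValueError("label 0 is background and must not be named")
        self.labels = labels

    @property
    def region_labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        labs = np.unique(self.labels)
        return labs[labs != 0]
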