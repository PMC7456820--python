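import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from lesionmap import CovariateTable, LesionCohort, VoxelGrid


def make_cohort(
    lesions: np.ndarray,
    grid: VoxelGrid | None = None,
    voxel_size: float = 1.0,
    pad: bool = False,
) -> LesionCohort:
    """Build a LesionCohort from a (V, N) binary matrix on an isotropic grid.

    ``pad=True`` appends one extra voxel per subject with an otherwise empty
    mask (original voxel indices are preserved), so hand-built fixtures can
    focus on the voxels under test while satisfying the cohort invariants.
    """
    lesions = np.asarray(lesions, dtype=np.uint8)
    if pad:
        empty = np.flatnonzero(lesions.sum(axis=0) == 0)
        if empty.size:
            extra = np.zeros((empty.size, lesions.shape[1]), dtype=np.uint8)
            extra[np.arange(empty.size), empty] = 1
            lesions = np.vstack([lesions, extra])
    V, N = lesions.shape
    if grid is None:
        # smallest box shape (V, 1, 1)
        grid = VoxelGrid.isotropic((V, 1, 1), voxel_size)
    ids = [f"s{j:03d}" for j in range(N)]
    return LesionCohort(grid, ids, lesions)


def make_table(
    cohort: LesionCohort,
    age: np.ndarray,
    volume: np.ndarray,
    followup: np.ndarray,
    outcome: np.ndarray,
) -> CovariateTable:
    df = pd.DataFrame(
        {
            "age": np.asarray(age, dtype=float),
            "lesion_volume": np.asarray(volume, dtype=float),
            "followup_time": np.asarray(followup, dtype=float),
            "outcome": np.asarray(outcome, dtype=float),
        },
        index=pd.Index(cohort.subject_ids, name="subject_id"),
    )
    return CovariateTable(df)


def random_table(cohort: LesionCohort, rng: np.random.Generator,
                 outcome: np.ndarray | None = None) -> CovariateTable:
    n = cohort.n_subjects
    return make_table(
        cohort,
        age=rng.normal(68.6, 12.6, n),
        volume=rng.lognormal(3.0, 0.5, n),
        followup=rng.uniform(18, 168, n),
        outcome=rng.normal(10, 4, n) if outcome is None else outcome,
    )


def random_cohort(rng: np.random.Generator, n_voxels: int = 100,
                  n_subjects: int = 40) -> LesionCohort:
    """Random binary cohort where every voxel has 5..n-5 lesioned subjects."""
    lesions = (rng.random((n_voxels, n_subjects)) < 0.4).astype(np.uint8)
    for v in range(n_voxels):  # enforce testability and cohort invariants
        count = lesions[v].sum()
        if count < 5:
            lesions[v, rng.choice(n_subjects, 5 - count, replace=False)] = 1
        elif count > n_subjects - 5:
            on = np.flatnonzero(lesions[v])
            lesions[v, on[: count - (n_subjects - 5)]] = 0
    return make_cohort(lesions, pad=True)


def write_nifti(path, data, affine=None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241005)
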