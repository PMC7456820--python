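"""Per-covariate standardized-beta importance maps on surviving voxels.

At every voxel that survives the permutation threshold, each covariate's
fitted coefficient is standardized so that covariates measured in different
units become comparable:

    bs_{i,j} = b_{i,j} * sqrt( var(x_j) / MSE_i )

where var(x_j) is the sample variance of covariate j across subjects and
MSE_i the voxel's residual mean squared error. The magnitude |bs| of each
covariate's map is then linearly rescaled to [0, 1] over the surviving
voxels, giving one normalized importance map per covariate.

Two standardization conventions are available:

* ``covariate_variance`` (default): the formula above - scale by the
  covariate's spread relative to the voxel's residual noise;
* ``classical``: bs = b * sd(x_j) / sd(outcome), the textbook standardized
  regression coefficient (voxel-independent denominator).

Normalization works on |bs| because importance is a magnitude notion; the
signed raw maps are always kept alongside so no information is lost.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import CovariateTable, VoxelGrid
from .glm import VoxelFitMap

log = logging.getLogger(__name__)

CONVENTIONS = ("covariate_variance", "classical")


@dataclass
class ImportanceMaps:
    """Raw and [0,1]-normalized standardized-beta maps per covariate."""

    grid: VoxelGrid
    voxel_idx: np.ndarray                  # surviving voxels (flat indices)
    covariate_names: tuple[str, ...]
    raw: dict[str, np.ndarray]             # signed standardized betas
    normalized: dict[str, np.ndarray]      # in [0, 1]
    bounds: dict[str, tuple[float, float]]  # (min, max) of |bs| over survivors
    convention: str = "covariate_variance"
    n_excluded: int = 0                    # voxels dropped for MSE == 0

    @property
    def surviving_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.n_voxels, dtype=bool)
        mask[self.voxel_idx] = True
        return mask

    def metadata(self) -> dict:
        return {
            "convention": self.convention,
            "covariates": list(self.covariate_names),
            "normalization_bounds": {k: list(v) for k, v in self.bounds.items()},
            "n_surviving_voxels": int(self.voxel_idx.size),
            "n_excluded_zero_mse": self.n_excluded,
        }

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Min-max rescale |values| to [0, 1] over a nonempty set of voxels.

    A degenerate (constant-magnitude) map comes back as all zeros with a
    warning: there is no relative importance information in it.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty map")
    if not np.all(np.isfinite(values)):
        raise ValueError("map values must be finite")
    mag = np.abs(values)
    lo, hi = float(mag.min()), float(mag.max())
    if hi == lo:
        warnings.warn("degenerate importance map (constant magnitude); "
                      "normalized to all zeros", stacklevel=2)
        return np.zeros_like(mag)
    return (mag - lo) / (hi - lo)


def standardized_betas(
    fit: VoxelFitMap,
    surviving: np.ndarray,
    table: CovariateTable,
    convention: str = "covariate_variance",
) -> ImportanceMaps:
    """Compute raw and normalized importance maps on the surviving voxels.

    ``surviving`` is a flat boolean mask and must be a subset of the fit's
    testable mask. Voxels with a perfect fit (MSE = 0) have no defined
    standardized beta and are excluded with a logged count.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown standardization convention {convention!r}")
    surviving = np.asarray(surviving, dtype=bool).reshape(-1)
    if surviving.shape[0] != fit.grid.n_voxels:
        raise ValueError("surviving mask does not match the grid")
    testable = fit.testable_mask
    if np.any(surviving & ~testable):
        raise ValueError("surviving mask extends outside the testable mask")

    keep = surviving[fit.voxel_idx]
    zero_mse = keep & (fit.mse <= 0)
    n_excluded = int(zero_mse.sum())
    if n_excluded:
        log.info("excluded %d surviving voxel(s) with zero residual variance",
                 n_excluded)
    keep &= fit.mse > 0
    voxel_idx = fit.voxel_idx[keep]
    if voxel_idx.size == 0:
        raise ValueError("no surviving voxels with positive residual variance")

    mse = fit.mse[keep]
    names = tuple(n for n in fit.term_names if n != "lesion")
    out_sd = np.sqrt(fit.outcome_variance)
    raw: dict[str, np.ndarray] = {}
    normalized: dict[str, np.ndarray] = {}
    bounds: dict[str, tuple[float, float]] = {}
    for name in names:
        beta = fit.coef_for(name)[keep]
        var_x = fit.covariate_variances[name]
        if convention == "covariate_variance":
            bs = beta * np.sqrt(var_x / mse)
        else:
            bs = beta * np.sqrt(var_x) / out_sd
        raw[name] = bs
        mag = np.abs(bs)
        bounds[name] = (float(mag.min()), float(mag.max()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normalized[name] = normalize_map(bs)

    return ImportanceMaps(
        grid=fit.grid,
        voxel_idx=voxel_idx,
        covariate_names=names,
        raw=raw,
        normalized=normalized,
        bounds=bounds,
        convention=convention,
        n_excluded=n_excluded,
    )


def write_importance_maps(maps: ImportanceMaps, out_dir: str | Path) -> None:
    """One raw and one normalized NIfTI per covariate, plus mask + metadata."""
    from .cohort_io import write_statistic_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask = maps.surviving_mask
    for name in maps.covariate_names:
        safe = name.replace("*", "_x_")
        write_statistic_map(maps.raw[name], mask, maps.grid,
                            out_dir / f"importance_raw_{safe}.nii.gz",
                            mask_path=out_dir / "surviving_mask.nii.gz")
        write_statistic_map(maps.normalized[name], mask, maps.grid,
                            out_dir / f"importance_norm_{safe}.nii.gz",
                            mask_path=out_dir / "surviving_mask.nii.gz")
    maps.write_metadata(out_dir / "importance_metadata.json")
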