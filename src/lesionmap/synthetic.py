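"""Synthetic stroke-cohort generator with known ground truth.

Emulates a follow-up-imaging stroke cohort: contiguous lesion blobs grown
inside a vascular-territory mask, covariates drawn from the study-scale
distributions (age ~ N(68.6, 12.6^2) years, follow-up imaging time uniform
over 18 h - 7 d, lesion sizes log-normal at the tens-of-cm^3 scale), and an
outcome assembled from the same linear model the analysis fits:

    S_n = sum_r gamma_r * frac_{r,n} + b_age*age_n + b_vol*vol_n
          + b_fup*fup_n + eps_n,      eps ~ N(0, noise_sd^2)

where frac_{r,n} is the fraction of eloquent region r's voxels covered by
subject n's lesion, so partial hits yield partial deficits.

Optionally, lesion *placement* can be coupled to covariates: each subject
targets the eloquent region whose linked covariate is most extreme for them
(softmax with strength ``placement_coupling``). This creates voxel-level
lesion-covariate correlation - the mechanism that makes a covariate's
importance spatially specific - and gives downstream recovery tests a
ground-truth region-covariate assignment to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import COVARIATES, CovariateTable, LesionCohort, VoxelGrid
from .cohort_io import compute_lesion_volume


@dataclass(frozen=True)
class EloquentRegion:
    """A set of voxels whose lesioning degrades the outcome.

    ``linked_covariate`` (one of age / lesion_volume / followup_time, or
    None) marks the covariate tied to this region: it steers lesion
    placement toward the region when placement coupling is on, and scales
    the severity of a hit when ``modulation`` is nonzero - the effect of
    lesioning the region is gamma + modulation * z, with z the subject's
    standardized linked covariate. Together these make the covariate
    explain outcome variance specifically within this region.
    """

    voxels: tuple[int, ...]
    gamma: float
    name: str = ""
    linked_covariate: str | None = None
    modulation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", tuple(int(v) for v in self.voxels))
        if not self.voxels:
            raise ValueError("eloquent region must contain at least one voxel")
        if self.linked_covariate is not None and self.linked_covariate not in COVARIATES:
            raise ValueError(f"unknown linked covariate {self.linked_covariate!r}")
        if self.modulation != 0.0 and self.linked_covariate is None:
            raise ValueError("modulation requires a linked covariate")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic cohort."""

    grid: VoxelGrid
    n_subjects: int = 222
    seed: int = 0
    territory: tuple[int, ...] | None = None  # flat voxel indices; None = whole grid
    eloquent_regions: tuple[EloquentRegion, ...] = ()
    # direct covariate effects on the outcome (per year / per cm^3 / per hour)
    b_age: float = 0.05
    b_vol: float = 0.1
    b_fup: float = 0.005
    # covariate distributions (study-scale defaults)
    age_mean: float = 68.6
    age_sd: float = 12.6
    followup_min: float = 18.0   # hours
    followup_max: float = 168.0  # hours (7 days)
    # lesion size (voxel count) ~ LogNormal(size_log_mean, size_log_sd)
    size_log_mean: float = float(np.log(40.0))
    size_log_sd: float = 0.5
    size_min: int = 5
    size_max: int = 300
    placement_coupling: float = 0.0
    #: fraction of subjects whose lesion seeds uniformly in the territory
    #: even when placement coupling is on (keeps a lesion-free comparison
    #: group at eloquent voxels)
    background_fraction: float = 0.5
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        terr = self.territory_indices()
        if terr.size == 0:
            raise ValueError("territory mask is empty")
        if self.size_min > terr.size - 1:
            raise ValueError("minimum lesion size exceeds territory capacity")
        terr_set = set(terr.tolist())
        for r in self.eloquent_regions:
            if not set(r.voxels) <= terr_set:
                raise ValueError(f"eloquent region {r.name!r} outside the territory")

    def territory_indices(self) -> np.ndarray:
        if self.territory is None:
            return np.arange(self.grid.n_voxels)
        return np.asarray(sorted(set(int(v) for v in self.territory)), dtype=np.int64)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def native(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = {k: native(v) for k, v in dataclasses.asdict(self).items()}
        d["grid"] = {"shape": list(self.grid.shape), "affine": self.grid.affine.tolist()}
        d["territory"] = None if self.territory is None else list(self.territory)
        d["eloquent_regions"] = [
            {
                "voxels": list(r.voxels),
                "gamma": r.gamma,
                "name": r.name,
                "linked_covariate": r.linked_covariate,
                "modulation": r.modulation,
            }
            for r in self.eloquent_regions
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        g = d.pop("grid")
        grid = VoxelGrid(tuple(g["shape"]), np.asarray(g["affine"]))
        regions = tuple(
            EloquentRegion(
                tuple(r["voxels"]),
                float(r["gamma"]),
                r.get("name", ""),
                r.get("linked_covariate"),
                float(r.get("modulation", 0.0)),
            )
            for r in d.pop("eloquent_regions", [])
        )
        terr = d.pop("territory", None)
        return cls(
            grid=grid,
            territory=None if terr is None else tuple(terr),
            eloquent_regions=regions,
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Everything needed to check parameter recovery downstream."""

    gamma_map: np.ndarray                 # flat, per-voxel lesion effect
    effects: dict[str, float]             # b_age, b_vol, b_fup
    region_names: list[str]
    region_linked_covariates: list[str | None]
    region_fractions: np.ndarray          # R x N lesioned fraction per region
    target_regions: np.ndarray            # N, index into regions or -1
    noise: np.ndarray                     # N
    covariates: pd.DataFrame              # realized covariates + outcome

    def write(self, out_dir: str | Path, grid: VoxelGrid) -> None:
        from .cohort_io import write_statistic_map

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_statistic_map(
            self.gamma_map,
            self.gamma_map != 0,
            grid,
            out_dir / "true_gamma.nii.gz",
        )
        meta = {
            "effects": self.effects,
            "region_names": self.region_names,
            "region_linked_covariates": self.region_linked_covariates,
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))


def box_region(
    grid: VoxelGrid,
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
    gamma: float,
    name: str = "",
    linked_covariate: str | None = None,
    modulation: float = 0.0,
) -> EloquentRegion:
    """Convenience: an axis-aligned box of voxels as an eloquent region."""
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    vol = np.zeros(grid.shape, dtype=bool)
    vol[sl] = True
    return EloquentRegion(
        tuple(np.flatnonzero(vol.reshape(-1)).tolist()),
        gamma,
        name,
        linked_covariate,
        modulation,
    )


def default_spec(n_subjects: int = 222, seed: int = 0) -> SimulationSpec:
    """Study-scale defaults: 222 subjects on a coarse 10 mm grid.

    At 10 mm isotropic voxels one voxel is 1 cm^3, so the log-normal size
    model (median 40 voxels) lands lesion volumes in the tens of cm^3, and
    the ~1.2 L grid is about the volume of an adult brain.
    """
    grid = VoxelGrid.isotropic((10, 12, 10), voxel_size_mm=10.0)
    region = box_region(grid, (3, 4, 3), (3, 3, 3), gamma=8.0, name="eloquent-core")
    return SimulationSpec(grid=grid, n_subjects=n_subjects, seed=seed,
                          eloquent_regions=(region,))


def recovery_spec(seed: int, n_subjects: int = 250) -> SimulationSpec:
    """A designed scenario in which each covariate's importance localizes to
    a distinct eloquent region, giving downstream stages a known
    region-covariate assignment to recover.

    Construction: three small eloquent regions with equal lesion effect,
    each tied to one covariate; every covariate has a global direct effect
    on the outcome; lesion placement is *anti*-coupled to the linked
    covariate (negative coupling), so e.g. younger subjects preferentially
    lesion the age-linked region. Marginally, the placement-mediated lesion
    deficit then cancels part of the covariate's direct effect everywhere -
    except at the linked region's voxels, where the per-voxel model adjusts
    for the lesion indicator and unmasks the full direct effect (a classic
    suppressor structure). The linked covariate's standardized beta is
    therefore largest, after 0-1 normalization, exactly in its own region.
    """
    grid = VoxelGrid.isotropic((9, 9, 9), voxel_size_mm=10.0)
    regions = (
        box_region(grid, (1, 1, 1), (2, 2, 2), 15.0, "R-age", "age"),
        box_region(grid, (6, 1, 6), (2, 2, 2), 15.0, "R-vol", "lesion_volume"),
        box_region(grid, (1, 6, 6), (2, 2, 2), 15.0, "R-fup", "followup_time"),
    )
    return SimulationSpec(
        grid=grid,
        n_subjects=n_subjects,
        seed=seed,
        eloquent_regions=regions,
        b_age=0.2,
        b_vol=0.2,
        b_fup=0.06,
        size_log_mean=float(np.log(30.0)),
        size_log_sd=0.4,
        placement_coupling=-8.0,
        background_fraction=0.4,
        noise_sd=1.0,
    )


def fwer_null_spec(seed: int, n_subjects: int = 100) -> SimulationSpec:
    """Null-study conditions for family-wise error checks.

    A ~500-voxel territory (8x8x8 grid at 10 mm), 100 subjects with
    contiguous lesions (median 60 voxels, so most voxels reach the 5/5
    testability counts), no eloquent regions and no direct covariate
    effects: the outcome is pure noise, so the strong null holds exactly.
    """
    grid = VoxelGrid.isotropic((8, 8, 8), voxel_size_mm=10.0)
    return SimulationSpec(
        grid=grid,
        n_subjects=n_subjects,
        seed=seed,
        eloquent_regions=(),
        b_age=0.0,
        b_vol=0.0,
        b_fup=0.0,
        size_log_mean=float(np.log(60.0)),
        size_log_sd=0.4,
        size_max=200,
        noise_sd=3.0,
    )


def recovery_parcellation(spec: SimulationSpec) -> "Parcellation":
    """Parcellation labelling each eloquent region of a spec (1, 2, ...)."""
    from .containers import Parcellation

    labels = np.zeros(spec.grid.n_voxels, dtype=np.int64)
    names: dict[int, str] = {}
    for k, region in enumerate(spec.eloquent_regions, start=1):
        labels[np.asarray(region.voxels)] = k
        names[k] = region.name or f"region-{k}"
    return Parcellation(spec.grid, labels, names)


# ---------------------------------------------------------------------------
# lesion growth

def _neighbor_table(shape: tuple[int, int, int]) -> np.ndarray:
    """(V, 6) table of 6-connected flat neighbor indices, -1 off-grid."""
    V = int(np.prod(shape))
    idx = np.arange(V).reshape(shape)
    nb = np.full((V, 6), -1, dtype=np.int64)
    nb[idx[1:, :, :].reshape(-1), 0] = idx[:-1, :, :].reshape(-1)
    nb[idx[:-1, :, :].reshape(-1), 1] = idx[1:, :, :].reshape(-1)
    nb[idx[:, 1:, :].reshape(-1), 2] = idx[:, :-1, :].reshape(-1)
    nb[idx[:, :-1, :].reshape(-1), 3] = idx[:, 1:, :].reshape(-1)
    nb[idx[:, :, 1:].reshape(-1), 4] = idx[:, :, :-1].reshape(-1)
    nb[idx[:, :, :-1].reshape(-1), 5] = idx[:, :, 1:].reshape(-1)
    return nb


def _grow_lesion(
    rng: np.random.Generator,
    territory_mask: np.ndarray,
    neighbors: np.ndarray,
    seed_voxel: int,
    target_size: int,
) -> np.ndarray:
    """Randomized 6-connected region growing; returns flat lesion indices.

    Growth stops early only if the territory component is exhausted, so the
    lesion is always a single connected component inside the territory.
    """
    in_lesion = np.zeros(territory_mask.shape[0], dtype=bool)
    in_frontier = np.zeros_like(in_lesion)
    lesion = [seed_voxel]
    in_lesion[seed_voxel] = True
    frontier: list[int] = []
    for nb in neighbors[seed_voxel]:
        if nb >= 0 and territory_mask[nb]:
            frontier.append(int(nb))
            in_frontier[nb] = True
    while len(lesion) < target_size and frontier:
        k = int(rng.integers(len(frontier)))
        vox = frontier[k]
        frontier[k] = frontier[-1]
        frontier.pop()
        in_frontier[vox] = False
        in_lesion[vox] = True
        lesion.append(vox)
        for nb in neighbors[vox]:
            if nb >= 0 and territory_mask[nb] and not in_lesion[nb] and not in_frontier[nb]:
                frontier.append(int(nb))
                in_frontier[nb] = True
    return np.asarray(lesion, dtype=np.int64)


# ---------------------------------------------------------------------------
# cohort generation

def _standardized_link_values(
    spec: SimulationSpec,
    age: np.ndarray,
    fup: np.ndarray,
    log_size: np.ndarray,
) -> dict[str, np.ndarray]:
    """Z-scores of each covariate under its generative distribution."""
    u_sd = (spec.followup_max - spec.followup_min) / np.sqrt(12.0)
    u_mean = 0.5 * (spec.followup_min + spec.followup_max)
    return {
        "age": (age - spec.age_mean) / spec.age_sd,
        "followup_time": (fup - u_mean) / u_sd,
        "lesion_volume": (log_size - spec.size_log_mean) / spec.size_log_sd,
    }


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[LesionCohort, CovariateTable, GroundTruth]:
    """Generate one cohort; bit-identical outputs under a fixed seed.

    One root seed sequence is split into a covariate stream, a noise stream
    and one lesion-growth stream per subject, so results do not depend on
    evaluation order.
    """
    root = np.random.SeedSequence(spec.seed)
    cov_ss, noise_ss, *subj_ss = root.spawn(2 + spec.n_subjects)
    cov_rng = np.random.default_rng(cov_ss)

    n = spec.n_subjects
    terr_idx = spec.territory_indices()
    terr_mask = np.zeros(spec.grid.n_voxels, dtype=bool)
    terr_mask[terr_idx] = True
    neighbors = _neighbor_table(spec.grid.shape)

    # covariate draws (mutually independent by construction)
    age = cov_rng.normal(spec.age_mean, spec.age_sd, size=n)
    while np.any(age <= 0):  # truncate at 0 by resampling
        bad = age <= 0
        age[bad] = cov_rng.normal(spec.age_mean, spec.age_sd, size=int(bad.sum()))
    fup = cov_rng.uniform(spec.followup_min, spec.followup_max, size=n)
    log_size = cov_rng.normal(spec.size_log_mean, spec.size_log_sd, size=n)
    cap = min(spec.size_max, terr_idx.size - 1)
    sizes = np.clip(np.rint(np.exp(log_size)).astype(int), spec.size_min, cap)

    # placement: uniform seed voxel, or covariate-steered region targeting
    zvals = _standardized_link_values(spec, age, fup, log_size)
    linked = [r for r in spec.eloquent_regions if r.linked_covariate is not None]
    target_regions = np.full(n, -1, dtype=int)
    region_index = {id(r): i for i, r in enumerate(spec.eloquent_regions)}

    lesions = np.zeros((spec.grid.n_voxels, n), dtype=np.uint8)
    for s in range(n):
        rng = np.random.default_rng(subj_ss[s])
        if (
            spec.placement_coupling != 0
            and linked
            and rng.random() >= spec.background_fraction
        ):
            logits = np.array(
                [spec.placement_coupling * zvals[r.linked_covariate][s] for r in linked]
            )
            p = np.exp(logits - logits.max())
            p /= p.sum()
            choice = int(rng.choice(len(linked), p=p))
            region = linked[choice]
            target_regions[s] = region_index[id(region)]
            seed_voxel = int(rng.choice(np.asarray(region.voxels)))
        else:
            seed_voxel = int(terr_idx[rng.integers(terr_idx.size)])
        vox = _grow_lesion(rng, terr_mask, neighbors, seed_voxel, int(sizes[s]))
        lesions[vox, s] = 1

    ids = [f"sub-{s + 1:04d}" for s in range(n)]
    cohort = LesionCohort(spec.grid, ids, lesions)
    vol = compute_lesion_volume(cohort)

    # outcome via the generative linear model
    R = len(spec.eloquent_regions)
    frac = np.zeros((R, n))
    lesion_effect = np.zeros(n)
    for i, r in enumerate(spec.eloquent_regions):
        frac[i] = lesions[np.asarray(r.voxels)].mean(axis=0)
        strength = r.gamma
        if r.modulation != 0.0:
            strength = strength + r.modulation * zvals[r.linked_covariate]
        lesion_effect += strength * frac[i]
    noise = np.random.default_rng(noise_ss).normal(0.0, spec.noise_sd, size=n)
    outcome = (
        lesion_effect
        + spec.b_age * age
        + spec.b_vol * vol
        + spec.b_fup * fup
        + noise
    )

    df = pd.DataFrame(
        {
            "age": age,
            "lesion_volume": vol,
            "followup_time": fup,
            "outcome": outcome,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    table = CovariateTable(df)

    gamma_map = np.zeros(spec.grid.n_voxels)
    for r in spec.eloquent_regions:
        gamma_map[np.asarray(r.voxels)] += r.gamma
    truth = GroundTruth(
        gamma_map=gamma_map,
        effects={"age": spec.b_age, "lesion_volume": spec.b_vol,
                 "followup_time": spec.b_fup},
        region_names=[r.name for r in spec.eloquent_regions],
        region_linked_covariates=[r.linked_covariate for r in spec.eloquent_regions],
        region_fractions=frac,
        target_regions=target_regions,
        noise=noise,
        covariates=df.copy(),
    )
    return cohort, table, truth


def null_cohort(
    spec: SimulationSpec, keep_covariate_effects: bool = False
) -> tuple[LesionCohort, CovariateTable, GroundTruth]:
    """A cohort whose outcome is independent of the lesions (all gamma = 0).

    By default the direct covariate effects are zeroed too, so the outcome
    is pure noise and the strong null (outcome independent of lesions and
    covariates jointly) holds exactly - the right regime for family-wise
    error checks. Pass ``keep_covariate_effects=True`` to retain b_age et
    al.; note lesion volume is lesion-derived, so that variant is null only
    for the lesion term conditional on covariates.
    """
    regions = tuple(
        dataclasses.replace(r, gamma=0.0, modulation=0.0)
        for r in spec.eloquent_regions
    )
    updates: dict = {"eloquent_regions": regions}
    if not keep_covariate_effects:
        updates.update(b_age=0.0, b_vol=0.0, b_fup=0.0)
    return simulate_cohort(dataclasses.replace(spec, **updates))
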