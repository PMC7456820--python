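"""End-to-end pipeline: collinearity screen -> voxel-wise GLM -> permutation
threshold -> importance maps -> regional clustering.

Every stage writes its artifacts into the run directory, and a manifest
records the effective configuration, the software version, the seed, and a
SHA-256 checksum of every output file, so a run can be audited and
reproduced. Identical config + seed gives bit-identical CSV/JSON outputs
(NIfTI maps are float32-rounded on write).
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort_io import (
    compute_lesion_volume,
    load_covariates,
    load_lesion_masks,
    load_parcellation,
    write_statistic_map,
)
from .collinearity import R_FLAG_DEFAULT, VIF_FLAG_DEFAULT, screen
from .glm import DesignSpec, fit_voxelwise_glm, lesion_t_map
from .importance import standardized_betas, write_importance_maps
from .permutation import apply_threshold, permutation_max_t
from .regional import (
    dominant_covariate,
    hierarchical_cluster,
    overlap_filter,
    regional_means,
    write_cluster_result,
)

log = logging.getLogger(__name__)

STAGES = ("collinearity", "fit", "threshold", "importance", "regional")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class BlockingCollinearityError(RuntimeError):
    """Raised when the VIF screen blocks and --force was not given."""


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    mask_paths: list[str]
    covariate_table: str
    output_dir: str
    parcellation_volume: str | None = None
    parcellation_lut: str | None = None
    id_column: str = "subject_id"
    column_map: dict = field(default_factory=dict)
    # design
    include_interactions: bool = False
    include_intercept: bool = True
    min_lesion_count: int = 5
    min_nonlesion_count: int = 5
    # collinearity
    r_threshold: float = R_FLAG_DEFAULT
    vif_threshold: float = VIF_FLAG_DEFAULT
    # permutation (defaults follow the published procedure)
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    one_sided: bool = True
    # importance
    importance_convention: str = "covariate_variance"
    # regional
    overlap_mode: str = "percentile"
    overlap_value: float = 50.0
    linkage: str = "average"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            include_interactions=self.include_interactions,
            include_intercept=self.include_intercept,
            min_lesion_count=self.min_lesion_count,
            min_nonlesion_count=self.min_nonlesion_count,
        )

    def resolved_mask_paths(self) -> list[str]:
        paths: list[str] = []
        for entry in self.mask_paths:
            hits = sorted(globmod.glob(entry))
            paths.extend(hits if hits else [entry])
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    stop_after: str = "regional",
    force: bool = False,
) -> Path:
    """Execute the pipeline stages in order, writing into the run directory.

    ``stop_after`` truncates the stage sequence, so each stage is
    independently invocable. A blocking collinearity flag halts the run
    (exit path) unless ``force`` is set. Partial outputs are retained with a
    FAILED marker when a stage raises.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    completed: list[str] = []
    stage = "setup"
    try:
        mask_paths = config.resolved_mask_paths()
        for p in (*mask_paths, config.covariate_table):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        cohort = load_lesion_masks(mask_paths)
        table = load_covariates(
            config.covariate_table,
            subject_order=cohort.subject_ids,
            id_column=config.id_column,
            column_map=config.column_map,
        )
        spec = config.design_spec()

        # -- collinearity -------------------------------------------------
        stage = "collinearity"
        report = screen(table, r_threshold=config.r_threshold,
                        vif_threshold=config.vif_threshold)
        report.to_json(out / "collinearity.json")
        (out / "collinearity.txt").write_text(report.to_text())
        completed.append(stage)
        if report.blocking and not force:
            raise BlockingCollinearityError(
                "covariate VIF exceeds the blocking threshold "
                f"({config.vif_threshold}); rerun with --force to proceed"
            )
        if stage == stop_after:
            return _finish(out, config, completed)

        # -- fit -----------------------------------------------------------
        stage = "fit"
        fit = fit_voxelwise_glm(cohort, table, spec)
        emap = lesion_t_map(fit)
        testable = fit.testable_mask
        write_statistic_map(fit.lesion_t, testable, cohort.grid,
                            out / "lesion_t.nii.gz",
                            mask_path=out / "testable_mask.nii.gz")
        write_statistic_map(fit.mse, testable, cohort.grid,
                            out / "mse.nii.gz",
                            mask_path=out / "testable_mask.nii.gz")
        for k, name in enumerate(fit.term_names):
            safe = name.replace("*", "_x_")
            write_statistic_map(fit.coef[:, k], testable, cohort.grid,
                                out / f"beta_{safe}.nii.gz",
                                mask_path=out / "testable_mask.nii.gz")
        (out / "fit_metadata.json").write_text(json.dumps({
            "df": fit.df,
            "covariate_variances": fit.covariate_variances,
            "outcome_variance": fit.outcome_variance,
            "n_testable": int(fit.voxel_idx.size),
            "n_dropped_rank_deficient": fit.n_dropped,
            "lesion_volumes_cm3": compute_lesion_volume(cohort).tolist(),
        }, indent=2))
        completed.append(stage)
        if stage == stop_after:
            return _finish(out, config, completed)

        # -- threshold -----------------------------------------------------
        stage = "threshold"
        if config.seed is None:
            raise ValueError("permutation stage requires an explicit seed")
        perm = permutation_max_t(
            cohort, table, spec,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=config.seed,
            one_sided=config.one_sided,
        )
        perm.write_null_sample(out / "null_max_t.csv")
        emap = apply_threshold(emap, perm)
        n_surviving = int(emap.surviving_mask.sum())
        (out / "threshold.json").write_text(json.dumps({
            "threshold": perm.threshold,
            "n_permutations": perm.n_permutations,
            "alpha": perm.alpha,
            "seed": perm.seed,
            "method": perm.method,
            "one_sided": config.one_sided,
            "n_surviving_voxels": n_surviving,
        }, indent=2))
        completed.append(stage)
        if stage == stop_after:
            return _finish(out, config, completed)

        # -- importance ----------------------------------------------------
        stage = "importance"
        surviving = emap.surviving_mask
        if not surviving.any():
            log.warning("no surviving voxels; skipping importance and "
                        "regional stages")
            completed.append(stage)
            return _finish(out, config, completed)
        maps = standardized_betas(fit, surviving, table,
                                  convention=config.importance_convention)
        write_importance_maps(maps, out)
        completed.append(stage)
        if stage == stop_after:
            return _finish(out, config, completed)

        # -- regional --------------------------------------------------
        stage = "regional"
        if config.parcellation_volume is None:
            log.warning("no parcellation supplied; regional stage skipped")
        else:
            parc = load_parcellation(config.parcellation_volume,
                                     config.parcellation_lut,
                                     grid=cohort.grid)
            regional = regional_means(maps, parc)
            filtered = overlap_filter(regional, mode=config.overlap_mode,
                                      value=config.overlap_value)
            annotated = dominant_covariate(filtered) if filtered.n_regions \
                else filtered.data
            annotated.to_csv(out / "regional_importance.csv", index=False)
            if filtered.n_regions >= 2:
                result = hierarchical_cluster(filtered, method=config.linkage)
                write_cluster_result(result, out)
            else:
                log.warning("fewer than 2 regions after overlap filter; "
                            "clustering skipped")
        completed.append(stage)
        return _finish(out, config, completed)
    except BlockingCollinearityError:
        _finish(out, config, completed)
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        _finish(out, config, completed)
        raise PipelineError(stage, exc) from exc
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _finish(out: Path, config: RunConfig, completed: list[str]) -> Path:
    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "software": {"name": "lesionmap", "version": __version__},
        "settings": dataclasses.asdict(config),
        "seed": config.seed,
        "stages_completed": completed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
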