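# lesionmap

Voxel-wise lesion-symptom mapping (VLSM) with per-covariate importance maps.

Given a cohort of binary lesion masks on a common grid and a per-subject
table of clinical covariates plus a deficit score, `lesionmap`:

1. **screens the covariates** for multicollinearity (pairwise Spearman
   correlations and variance inflation factors, with a blocking VIF ≥ 5
   gate);
2. **fits a mass-univariate GLM** at every testable voxel —
   `outcome ~ intercept + lesion + age + lesion_volume + followup_time`
   (optional interaction terms) — and extracts the lesion-term t-score as
   the voxel's *eloquence*;
3. **controls family-wise error** with max-t permutation thresholding:
   the outcome is permuted across subjects, the maximum lesion t over all
   voxels is recorded per permutation, and the (1 − α) quantile of that
   null distribution becomes the map-wide significance threshold;
4. **standardizes the covariate coefficients** at each surviving voxel
   (β·√(var(x)/MSE)) and min-max normalizes their magnitudes to [0, 1],
   giving one relative-importance map per covariate;
5. **aggregates importance over an atlas parcellation**, filters regions by
   surviving-mask overlap, assigns each region its dominant covariate, and
   groups regional importance profiles by agglomerative hierarchical
   clustering.

A synthetic-cohort simulator with exact ground truth (contiguous randomized
region-growing lesions, configurable eloquent regions and covariate
effects) supports end-to-end validation without patient data.

## Command-line usage

```bash
# generate a synthetic cohort (spec must state an explicit seed)
lesionmap simulate spec.yaml cohort/

# full pipeline from a config file
lesionmap run config.yaml

# or stage by stage (each stage re-runs the prefix it depends on)
lesionmap check-collinearity config.yaml
lesionmap fit config.yaml
lesionmap threshold config.yaml --seed 7 --n-perm 1000 --alpha 0.05
lesionmap importance config.yaml
lesionmap regional config.yaml
```

A minimal `config.yaml`:

```yaml
mask_paths: ["cohort/masks/*.nii.gz"]     # one binary NIfTI per subject
covariate_table: cohort/covariates.csv    # subject_id, age, lesion_volume,
                                          # followup_time, outcome
output_dir: results/run1
parcellation_volume: atlas.nii.gz         # integer labels, 0 = background
parcellation_lut: atlas_lut.csv           # two columns: label, name
n_permutations: 1000
seed: 7
```

Exit codes: 0 success, 2 blocking collinearity (rerun with `--force` to
proceed anyway), 3 stage failure. Every run writes a `manifest.json` with
the effective settings, the seed, and a SHA-256 checksum of each output,
so runs are auditable; identical config + seed reproduces thresholds,
surviving-voxel counts and all CSV outputs bit-identically.

## Worked example (Python API)

The `recovery_spec` scenario simulates three eloquent regions, each tied
to one covariate, so the ground-truth assignment is known:

```python
import numpy as np
from lesionmap import (
    recovery_spec, simulate_cohort, screen, fit_voxelwise_glm,
    permutation_max_t, lesion_t_map, apply_threshold, standardized_betas,
    recovery_parcellation, regional_means, dominant_covariate,
)

spec = recovery_spec(seed=7)            # 250 subjects, 9x9x9 grid at 10 mm
cohort, table, truth = simulate_cohort(spec)

report = screen(table)                  # max VIF 1.024 -> not blocking
fit = fit_voxelwise_glm(cohort, table)  # 537 testable voxels, df = 245

perm = permutation_max_t(cohort, table, n_permutations=1000, seed=7)
print(perm.threshold)                   # 4.013
emap = apply_threshold(lesion_t_map(fit), perm)
print(emap.surviving_mask.sum())        # 26 surviving voxels

maps = standardized_betas(fit, emap.surviving_mask, table)
regional = regional_means(maps, recovery_parcellation(spec))
print(dominant_covariate(regional))
```

Output (mean normalized importance per region):

```
 name  overlap    age  lesion_volume  followup_time       dominant
R-age        8  0.864          0.477          0.126            age
R-vol        5  0.096          0.945          0.109  lesion_volume
R-fup        8  0.158          0.150          0.862  followup_time
```

All three regions recover their ground-truth covariate
(`truth.region_linked_covariates`).

## Layout

```
src/lesionmap/
  containers.py    VoxelGrid, LesionCohort, CovariateTable, Parcellation
  cohort_io.py     NIfTI/CSV loading and writing
  collinearity.py  Spearman + VIF screen
  glm.py           voxel-wise OLS (shared-design residualization)
  permutation.py   max-t permutation thresholding
  importance.py    standardized-beta importance maps
  regional.py      atlas aggregation + hierarchical clustering
  synthetic.py     ground-truth cohort simulator
  pipeline.py      staged runner with manifest/checksums
  cli.py           click command-line interface
docs/methods.md    statistical methods note and design rationale
scripts/acceptance.py   the two release-gating targets
```

See `docs/methods.md` for the model in full notation, the standardization
convention, permutation details, the simulator design (including why the
recovery scenario uses anti-coupled lesion placement), and limitations.
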