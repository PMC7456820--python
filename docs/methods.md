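# Methods

This note states the statistical model the package implements, the
conventions chosen where the literature is ambiguous, and the design of the
synthetic validation scenarios.

## 1. Voxel-wise model

For voxel *i* and subject *s* with binary lesion status `L_is`, the package
fits the ordinary-least-squares model

```
outcome_s = b0_i + b_lesion,i * L_is
          + b_age,i * age_s
          + b_vol,i * lesion_volume_s
          + b_fup,i * followup_time_s
          + e_is
```

optionally extended with `age x lesion_volume` and
`lesion_volume x followup_time` interaction terms. The lesion-term t-score

```
t_i = b_lesion,i / SE(b_lesion,i)
```

is the voxel's *eloquence*: large positive t means lesioning the voxel is
associated with a worse deficit score after adjusting for the covariates.

**Testable voxels.** A voxel enters the analysis only if at least
`min_lesion_count` subjects are lesioned there and at least
`min_nonlesion_count` are spared (both default 5). Voxels whose lesion
column is (numerically) a linear combination of the covariate block are
additionally dropped as rank-deficient and counted.

**Computation.** The covariate block `Z = [1, age, vol, fup]` is identical
across voxels; only the lesion column changes. The implementation
QR-orthogonalizes `Z` once, residualizes every lesion column and the
outcome against it, and obtains each voxel's lesion coefficient, residual
variance and t-score from the residualized quantities
(Frisch–Waugh–Lovell). This is algebraically exact OLS — the test suite
verifies agreement with a naive pseudo-inverse solver to 1e-8 — and it
reduces a permutation pass over all voxels to one matrix product, which is
what makes desk-scale family-wise-error simulations (tens of thousands of
whole-map refits) run in seconds.

## 2. Max-t permutation threshold

Under the strong null hypothesis — the outcome is exchangeable across
subjects and independent of lesion anatomy and covariates — permuting the
outcome vector while holding the design fixed generates the null
distribution of the *study-wide maximum* lesion t-score. The map-wide
threshold is the (1 − α) quantile of that distribution; any observed t at
or above it is significant with family-wise error at most α.

Conventions (all configurable, defaults stated):

* **What is permuted:** the outcome vector alone (simple permutation).
* **Quantile definition:** the `ceil((1 − α)·M)`-th order statistic of the
  M permutation maxima — the conservative choice, so the marginal FWER is
  ≤ α rather than ≈ α.
* **Observed statistic:** *not* appended to the null sample by default;
  `include_observed=True` switches to the (M + 1) convention used for
  exact p-values.
* **Sidedness:** one-sided (maximum of signed t, deficit-increasing
  direction) by default; `one_sided=False` uses max |t|.
* **Reproducibility:** permutation *b* is generated directly from
  `(seed, b)` (counter-based seeding), so results are independent of batch
  size or execution order; permutations are applied in a canonical
  sorted-subject-ID ordering, so jointly reordering the input subjects
  cannot change the threshold. For n ≤ 8 subjects an exhaustive
  enumeration mode replaces Monte Carlo sampling; the test suite checks it
  against a hand-enumerated 720-permutation null.

Empirically (acceptance target t1), across 200 null cohorts of 100
subjects with ~500 testable voxels, the realized FWER at α = 0.05 is about
0.04–0.07, inside three binomial standard errors of the nominal level and
consistent with the conservative quantile convention.

## 3. Standardized-beta importance maps

At each voxel surviving the permutation threshold, every covariate's
coefficient is standardized so that covariates in different units become
comparable. The default convention is

```
bs_ij = b_ij * sqrt( var(x_j) / MSE_i )
```

— the coefficient scaled by the covariate's sample variance relative to
the voxel's residual variance. A coefficient's standardized magnitude is
therefore the (signed square root of the) F-statistic scale on which that
covariate competes with the residual noise at that voxel.

The formulation commonly written as β·sd(x)/sd(y) (denominator the
*outcome* standard deviation, voxel-independent) is available as
`convention="classical"`. The two differ only by a per-voxel monotone
factor; the package defaults to the residual-variance reading because it
lets the same covariate rank differently at voxels with different
unexplained variance, which is the behaviour an importance *map* is meant
to express. Both are invariant to positive affine rescaling of a covariate
(verified to 1e-8 in the tests), so unit choices (hours vs days, mm³ vs
cm³) never change the maps.

For each covariate, |bs| is min-max rescaled to [0, 1] over the surviving
voxels ("relative importance"); the signed raw maps are always written
alongside, and the normalization bounds are recorded in the metadata so
the transform is invertible. A constant-magnitude map carries no relative
information and is normalized to all zeros with a warning. Voxels with
zero residual variance have no defined standardized beta and are excluded
with a logged count.

## 4. Regional aggregation and clustering

Normalized importance is averaged within each atlas region's overlap with
the surviving mask. Regions are then filtered by overlap — either an
absolute voxel count or a percentile of the overlap distribution (default:
50th percentile, a median cut) — because means over a handful of voxels
are noise. Each remaining region is assigned its *dominant covariate*
(arg-max of the mean normalized importance; ties are flagged and broken by
the canonical covariate order age → lesion_volume → followup_time), and
the region × covariate profiles are grouped by agglomerative hierarchical
clustering (Euclidean distance, average linkage by default; complete,
single and Ward available). Clustering is deterministic given the table;
the tests pin a hand-traced 3-row average-linkage computation and the
height-zero first merge of duplicate profiles.

## 5. Collinearity screen

Before any fitting, the three covariates are screened on the *design
alone* (the outcome plays no role):

* pairwise Spearman rank correlations, with |r| ≥ 0.1 flagged as
  informational;
* variance inflation factors `VIF_j = 1 / (1 − R²_j)`, where R²_j comes
  from regressing covariate j on the other two with an intercept. VIF ≥ 5
  is a *blocking* flag: the pipeline halts (exit code 2) unless `--force`
  is given, because a standardized-beta comparison between near-collinear
  covariates is not interpretable.

VIFs are cross-checked against `statsmodels` in the test suite.

## 6. Synthetic cohort simulator

Lesions are grown as single 6-connected components by randomized frontier
growth inside an optional territory mask, with log-normal target sizes. On
the default 10 mm isotropic grid one voxel is 1 cm³, so the size model
(median 40 voxels) lands lesion volumes in the tens of cm³ and a
~1,200-voxel grid approximates an adult brain volume. Covariates are drawn
as age ~ Normal(68.6, 12.6²), follow-up ~ Uniform(18 h, 168 h), and lesion
volume is computed from the generated mask (so it is a real, not assumed,
covariate). The outcome is

```
S_s = sum_r (gamma_r + modulation_r * z_s) * frac_rs
    + b_age * age_s + b_vol * vol_s + b_fup * fup_s + noise
```

where `frac_rs` is the fraction of eloquent region r lesioned in subject
s and `z_s` the subject's standardized linked-covariate value. All
randomness flows from a single spec seed through spawned per-subject
streams, so cohorts are bit-reproducible and two regions' draws never
interact.

**Default scale.** `default_spec()` uses 222 subjects — a realistic
single-centre registry size at which ~1,100 of the grid's voxels reach the
5/5 testability counts — with one 27-voxel eloquent region.

**The recovery scenario** (`recovery_spec`) is designed so that each
covariate's importance *localizes* to a distinct region, which is the
property the regional stage claims to detect. This requires care: giving a
region's deficit a covariate-modulated gain, or coupling lesion placement
*positively* to a covariate, does not move the adjusted per-voxel
covariate coefficient — in a pooled OLS the covariate coefficient's
estimand is essentially voxel-independent, and positive placement coupling
actually *suppresses* the coefficient at the linked region (part of the
covariate's marginal association is explained away by the lesion term).
The scenario that works inverts this into a designed suppressor structure:
every covariate has a global direct effect on the outcome, and lesion
placement is *anti*-coupled to the linked covariate (e.g. younger subjects
preferentially lesion the age-linked region). Marginally, the
placement-mediated lesion deficit cancels part of the covariate's direct
effect; at the linked region's voxels the model adjusts for the lesion
indicator and unmasks the full direct effect, so the covariate's
standardized beta peaks exactly there. Acceptance target: the dominant
covariate matches the ground-truth assignment in ≥ 90% of regions over 100
simulations (observed: 98%, 294/300 regions).

**The null scenario** (`fwer_null_spec`) uses an 8×8×8 territory
(~500 testable voxels at n = 100) with no eloquent regions and no
covariate effects, so the strong null holds exactly and the empirical FWER
of the whole fit-and-threshold path can be measured.

## 7. Limitations

* The GLM is mass-univariate: each voxel is modelled independently, and
  nothing corrects for the spatial correlation of lesions beyond the max-t
  procedure's implicit handling of dependence.
* The simulator validates *internal* consistency (the pipeline recovers
  what the generator planted); it cannot establish that real clinical
  covariates behave like the suppressor construction, only that the
  machinery detects localized covariate structure when it exists.
* The permutation test assumes outcome exchangeability under the null;
  strong covariate-outcome dependence makes the simple (non-residualized)
  permutation conservative rather than exact.
* Min-max normalization makes importance *relative to the surviving mask
  of the same run*; normalized values are not comparable across runs with
  different thresholds (the raw maps and recorded bounds are).
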