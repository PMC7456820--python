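"""Mass-univariate voxel-wise general linear models.

At each voxel i the outcome is regressed, by ordinary least squares, on an
intercept, the binary lesion indicator L_i, and the shared covariates (age,
lesion volume, follow-up imaging time; optionally age x volume and volume x
follow-up interactions):

    S = b0 + b1*L_i + b2*age + b3*vol + b4*fup + eps

The lesion-term t-score t_i = b1 / SE(b1) quantifies how eloquent voxel i
is: higher t means a lesion there is associated with a worse outcome.

Because the design is identical across voxels except for the lesion column,
the fits share precomputation via the Frisch-Waugh-Lovell decomposition:
the covariate block Z is orthogonalized once (QR), every lesion column and
the outcome are residualized against it, and the lesion coefficient,
residual variance and t-score fall out of one matrix product per outcome
vector. The results are exact OLS, voxel for voxel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import COVARIATES, CovariateTable, LesionCohort, VoxelGrid

log = logging.getLogger(__name__)

#: Squared-norm threshold below which a residualized lesion column counts as
#: lying in the covariate span (rank-deficient voxel, dropped from the fit).
_RANK_TOL = 1e-8

#: Interaction columns added when DesignSpec.include_interactions is set.
INTERACTIONS: tuple[tuple[str, str], ...] = (
    ("age", "lesion_volume"),
    ("lesion_volume", "followup_time"),
)


@dataclass(frozen=True)
class DesignSpec:
    """Which columns enter the per-voxel model and which voxels are testable."""

    covariates: tuple[str, ...] = COVARIATES
    include_interactions: bool = False
    include_intercept: bool = True
    min_lesion_count: int = 5
    min_nonlesion_count: int = 5

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")
        if self.min_lesion_count < 1 or self.min_nonlesion_count < 1:
            raise ValueError("minimum lesion/non-lesion counts must be >= 1")

    def term_names(self) -> tuple[str, ...]:
        """Non-intercept design columns, lesion first."""
        terms = ["lesion", *self.covariates]
        if self.include_interactions:
            terms += [f"{a}*{b}" for a, b in INTERACTIONS if a in self.covariates
                      and b in self.covariates]
        return tuple(terms)


@dataclass
class VoxelFitMap:
    """Per-voxel OLS results on the testable mask.

    ``coef`` holds the non-intercept coefficients (lesion first, matching
    ``term_names``); the intercept, when fitted, is kept separately.
    """

    grid: VoxelGrid
    design: DesignSpec
    voxel_idx: np.ndarray        # flat indices of testable voxels, length T
    coef: np.ndarray             # T x p, columns = term_names
    intercept: np.ndarray | None
    lesion_t: np.ndarray         # T
    mse: np.ndarray              # T, residual mean squared error
    df: int                      # residual degrees of freedom, shared
    covariate_variances: dict[str, float]   # sample variance (ddof=1) per term
    outcome_variance: float
    n_dropped: int = 0           # rank-deficient voxels removed

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.design.term_names()

    @property
    def testable_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.n_voxels, dtype=bool)
        mask[self.voxel_idx] = True
        return mask

    def coef_for(self, term: str) -> np.ndarray:
        return self.coef[:, self.term_names.index(term)]


@dataclass
class EloquenceMap:
    """Lesion-term t-scores, with a threshold set by the permutation stage."""

    grid: VoxelGrid
    voxel_idx: np.ndarray
    t: np.ndarray
    threshold: float | None = None

    @property
    def testable_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.n_voxels, dtype=bool)
        mask[self.voxel_idx] = True
        return mask

    @property
    def surviving_mask(self) -> np.ndarray:
        """Flat boolean mask of voxels with t >= threshold."""
        if self.threshold is None:
            raise ValueError("no threshold set; run the permutation stage first")
        mask = np.zeros(self.grid.n_voxels, dtype=bool)
        mask[self.voxel_idx[self.t >= self.threshold]] = True
        return mask


def testable_voxel_mask(cohort: LesionCohort, spec: DesignSpec) -> np.ndarray:
    """Flat boolean mask of voxels with enough lesioned and spared subjects.

    A voxel enters the mass-univariate analysis only if at least
    ``min_lesion_count`` subjects are lesioned there and at least
    ``min_nonlesion_count`` are not; otherwise the lesion contrast is too
    unbalanced to test.
    """
    counts = cohort.lesions.sum(axis=1)
    n = cohort.n_subjects
    mask = (counts >= spec.min_lesion_count) & (
        n - counts >= spec.min_nonlesion_count
    )
    if not mask.any():
        warnings.warn("no testable voxels under the current design", stacklevel=2)
    return mask


def build_covariate_block(table: CovariateTable, spec: DesignSpec) -> np.ndarray:
    """The shared (non-lesion) design columns: intercept, covariates, interactions."""
    cols = []
    names = []
    if spec.include_intercept:
        cols.append(np.ones(table.n_subjects))
        names.append("intercept")
    data = {c: table.data[c].to_numpy(dtype=float) for c in spec.covariates}
    for c in spec.covariates:
        cols.append(data[c])
        names.append(c)
    if spec.include_interactions:
        for a, b in INTERACTIONS:
            if a in data and b in data:
                cols.append(data[a] * data[b])
                names.append(f"{a}*{b}")
    return np.column_stack(cols)


@dataclass
class PreparedDesign:
    """Shared precomputation for fitting many outcome vectors fast."""

    grid: VoxelGrid
    design: DesignSpec
    voxel_idx: np.ndarray   # testable, rank-sufficient voxels (T)
    Q: np.ndarray           # N x pz orthonormal basis of the covariate block
    pinvZ: np.ndarray       # pz x N pseudo-inverse of the covariate block
    L_res: np.ndarray       # N x T residualized lesion columns
    ss: np.ndarray          # T, squared norms of L_res columns
    df: int
    n_dropped: int

    @property
    def n_subjects(self) -> int:
        return self.Q.shape[0]

    def lesion_t(self, y: np.ndarray) -> np.ndarray:
        """Lesion-term t-scores for one outcome vector (length N)."""
        return self.lesion_t_many(np.asarray(y, dtype=float)[:, None])[:, 0]

    def lesion_t_many(self, Y: np.ndarray) -> np.ndarray:
        """Lesion-term t-scores for a batch of outcomes.

        Y is N x B; returns a T x B matrix of t-scores (exact OLS per
        voxel/outcome via the shared residualization).
        """
        Y_res = Y - self.Q @ (self.Q.T @ Y)
        num = self.L_res.T @ Y_res                     # T x B
        yss = np.einsum("ij,ij->j", Y_res, Y_res)      # B
        rss = np.maximum(yss[None, :] - num**2 / self.ss[:, None], 0.0)
        denom = np.sqrt(self.ss[:, None] * rss / self.df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        # a zero-residual (perfect) fit yields an unbounded t
        t[~np.isfinite(t)] = np.inf * np.sign(num[~np.isfinite(t)])
        return t


def prepare_design(
    cohort: LesionCohort, table: CovariateTable, spec: DesignSpec
) -> PreparedDesign:
    """Residualize every testable lesion column against the covariate block."""
    if table.subject_ids != cohort.subject_ids:
        raise ValueError("covariate table is not aligned to the cohort")
    mask = testable_voxel_mask(cohort, spec)
    voxel_idx = np.flatnonzero(mask)
    n = cohort.n_subjects

    Z = build_covariate_block(table, spec)
    pz = Z.shape[1]
    if np.linalg.matrix_rank(Z) < pz:
        raise ValueError("covariate block is rank deficient")
    df = n - pz - 1  # the lesion column counts as one more term
    if df < 1:
        raise ValueError(f"not enough subjects (n={n}) for {pz + 1} design columns")

    Q, _ = np.linalg.qr(Z)
    pinvZ = np.linalg.pinv(Z)
    L = cohort.lesions[voxel_idx].T.astype(float)      # N x T
    L_res = L - Q @ (Q.T @ L)
    ss = np.einsum("ij,ij->j", L_res, L_res)

    ok = ss > _RANK_TOL * np.maximum(1.0, L.sum(axis=0))
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d rank-deficient voxel(s) whose lesion column lies "
                 "in the covariate span", n_dropped)
    return PreparedDesign(
        grid=cohort.grid,
        design=spec,
        voxel_idx=voxel_idx[ok],
        Q=Q,
        pinvZ=pinvZ,
        L_res=L_res[:, ok],
        ss=ss[ok],
        df=df,
        n_dropped=n_dropped,
    )


def fit_voxelwise_glm(
    cohort: LesionCohort, table: CovariateTable, spec: DesignSpec | None = None
) -> VoxelFitMap:
    """Fit the per-voxel GLM at every testable voxel.

    Returns all coefficients (lesion first), the lesion t-score, the
    residual mean squared error and the shared residual degrees of freedom.
    """
    spec = spec or DesignSpec()
    prep = prepare_design(cohort, table, spec)
    y = table.outcome()

    y_res = y - prep.Q @ (prep.Q.T @ y)
    num = prep.L_res.T @ y_res
    beta_lesion = num / prep.ss
    rss = np.maximum(float(y_res @ y_res) - num**2 / prep.ss, 0.0)
    mse = rss / prep.df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_lesion / np.sqrt(mse / prep.ss)
    t[~np.isfinite(t)] = np.inf * np.sign(beta_lesion[~np.isfinite(t)])

    # remaining coefficients by back-substitution:
    # beta_Z(voxel) = pinvZ @ (y - L_voxel * beta_lesion)
    L = cohort.lesions[prep.voxel_idx].T.astype(float)
    base = prep.pinvZ @ y                              # pz
    G = prep.pinvZ @ L                                 # pz x T
    beta_Z = base[:, None] - G * beta_lesion[None, :]  # pz x T

    if spec.include_intercept:
        intercept = beta_Z[0]
        others = beta_Z[1:]
    else:
        intercept = None
        others = beta_Z
    coef = np.column_stack([beta_lesion, others.T])

    variances = {}
    Z_full = build_covariate_block(table, spec)
    offset = 1 if spec.include_intercept else 0
    for k, name in enumerate(spec.term_names()[1:]):
        variances[name] = float(np.var(Z_full[:, offset + k], ddof=1))
    return VoxelFitMap(
        grid=cohort.grid,
        design=spec,
        voxel_idx=prep.voxel_idx,
        coef=coef,
        intercept=intercept,
        lesion_t=t,
        mse=mse,
        df=prep.df,
        covariate_variances=variances,
        outcome_variance=float(np.var(y, ddof=1)),
        n_dropped=prep.n_dropped,
    )


def lesion_t_map(fit: VoxelFitMap) -> EloquenceMap:
    """Extract the eloquence (lesion t-score) map from a fit."""
    if fit.voxel_idx.size == 0:
        warnings.warn("empty testable mask: eloquence map has no voxels",
                      stacklevel=2)
    return EloquenceMap(fit.grid, fit.voxel_idx.copy(), fit.lesion_t.copy())
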