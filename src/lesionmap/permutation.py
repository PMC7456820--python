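"""Max-statistic permutation thresholding for family-wise error control.

Under the strong null (outcome exchangeable across subjects, independent of
lesions and covariates), permuting the outcome vector while holding the
design fixed and recording the maximum lesion t-score over all testable
voxels yields the null distribution of the study-wide maximum. The
(1 - alpha) quantile of that distribution is the map-wide threshold: any
observed t above it is significant with family-wise error at most alpha.

Conventions (documented defaults, configurable):

* the outcome alone is permuted (simple permutation, not residual-based);
  this tests the strong joint null, which is what map thresholding needs;
* the threshold is the ceil((1-alpha) * n_permutations)-th order statistic
  of the null sample - conservative, so FWER <= alpha marginally;
* the observed statistic is not added to the null sample by default;
  ``include_observed`` enables the +1 convention used for exact p-values.

Permutations come from a counter-based stream: permutation b is generated
from (seed, b) directly, so the sequence is reproducible and independent of
chunking or parallel order. Permutations are applied in a canonical
(sorted-subject-ID) ordering, which makes the threshold invariant to
jointly reordering the input subjects.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .containers import CovariateTable, LesionCohort
from .glm import DesignSpec, EloquenceMap, PreparedDesign, prepare_design

_MIN_PERMUTATIONS = 100
_EXHAUSTIVE_MAX_N = 8


@dataclass
class PermutationResult:
    n_permutations: int
    alpha: float
    max_t: np.ndarray      # null sample of per-permutation maxima
    threshold: float
    seed: int | None
    method: str = "monte_carlo"   # or "exhaustive"
    include_observed: bool = False

    def write_null_sample(self, path: str | Path) -> None:
        np.savetxt(path, self.max_t, header="max_t", comments="")


def _threshold_from_sample(max_t: np.ndarray, alpha: float) -> float:
    """The ceil((1-alpha)*M)-th order statistic (1-indexed, ascending)."""
    m = max_t.size
    k = int(math.ceil((1.0 - alpha) * m))
    k = min(max(k, 1), m)
    return float(np.sort(max_t)[k - 1])


def _permutation_stream(seed: int, n: int, count: int):
    """Counter-based permutations: permutation b depends only on (seed, b)."""
    for b in range(count):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        yield rng.permutation(n)


def permutation_max_t(
    cohort: LesionCohort,
    table: CovariateTable,
    spec: DesignSpec | None = None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "monte_carlo",
    include_observed: bool = False,
    one_sided: bool = True,
    batch_size: int = 256,
    _prepared: PreparedDesign | None = None,
) -> PermutationResult:
    """Build the max-t null distribution and its (1 - alpha) threshold.

    ``one_sided`` records the maximum of the signed t (deficit-increasing
    direction); set it False for max |t| (two-sided control).
    ``method="exhaustive"`` enumerates all n! outcome permutations (small
    cohorts only) and ignores ``seed``/``n_permutations``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    spec = spec or DesignSpec()
    prep = _prepared or prepare_design(cohort, table, spec)
    if prep.voxel_idx.size == 0:
        raise ValueError("testable mask is empty; nothing to threshold")
    n = cohort.n_subjects
    y = table.outcome()

    # canonical subject ordering: permutation indices live in sorted-ID space
    order = np.argsort(np.asarray(cohort.subject_ids))
    y_canon = y[order]

    if method == "exhaustive":
        if n > _EXHAUSTIVE_MAX_N:
            raise ValueError(
                f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_MAX_N}"
            )
        perms = (np.asarray(p) for p in itertools.permutations(range(n)))
        total = math.factorial(n)
    elif method == "monte_carlo":
        if n_permutations < _MIN_PERMUTATIONS:
            raise ValueError(
                f"need at least {_MIN_PERMUTATIONS} permutations for a usable "
                f"null at conventional alpha"
            )
        if seed is None:
            raise ValueError("a seed is required for Monte Carlo permutations")
        perms = _permutation_stream(int(seed), n, n_permutations)
        total = n_permutations
    else:
        raise ValueError(f"unknown permutation method {method!r}")

    max_t = np.empty(total)
    done = 0
    batch = []
    for perm in perms:
        y_new = np.empty(n)
        y_new[order] = y_canon[perm]
        batch.append(y_new)
        if len(batch) == batch_size:
            done = _flush(prep, batch, max_t, done, one_sided)
            batch = []
    if batch:
        done = _flush(prep, batch, max_t, done, one_sided)
    assert done == total

    if include_observed:
        obs = prep.lesion_t(y)
        obs_max = float(obs.max() if one_sided else np.abs(obs).max())
        max_t = np.append(max_t, obs_max)

    threshold = _threshold_from_sample(max_t, alpha)
    return PermutationResult(
        n_permutations=total,
        alpha=alpha,
        max_t=max_t,
        threshold=threshold,
        seed=seed if method == "monte_carlo" else None,
        method=method,
        include_observed=include_observed,
    )


def _flush(prep, batch, out, done, one_sided) -> int:
    Y = np.column_stack(batch)
    T = prep.lesion_t_many(Y)
    vals = T.max(axis=0) if one_sided else np.abs(T).max(axis=0)
    out[done:done + len(batch)] = vals
    return done + len(batch)


def apply_threshold(emap: EloquenceMap, result: PermutationResult) -> EloquenceMap:
    """Record the permutation threshold on an eloquence map.

    The surviving mask becomes {testable voxels with t >= threshold}.
    """
    out = replace(emap, threshold=result.threshold)
    if not (out.t >= result.threshold).any():
        warnings.warn("no voxel survives the permutation threshold", stacklevel=2)
    return out
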