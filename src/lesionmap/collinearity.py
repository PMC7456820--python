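"""Multicollinearity screening of the covariates before voxel-wise modeling.

Two diagnostics: pairwise Spearman rank correlations (average-rank ties,
two-sided p-values) and variance inflation factors from auxiliary
regressions with intercept, VIF_j = 1 / (1 - R^2_j). Pairs with |r_s| at or
above the informational threshold (default 0.1) are flagged; covariates
with VIF at or above the blocking threshold (default 5.0, the conventional
no-multicollinearity criterion) block the pipeline unless overridden.

VIF is a property of the design alone: although the screen accompanies a
model that predicts the clinical outcome, the auxiliary regressions never
involve the outcome, and the report says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import COVARIATES, CovariateTable

R_FLAG_DEFAULT = 0.1   # informational |r_s| threshold
VIF_FLAG_DEFAULT = 5.0  # blocking threshold

#: R^2 above this in an auxiliary regression counts as perfect collinearity.
_PERFECT_R2 = 1.0 - 1e-12


@dataclass
class CollinearityReport:
    covariate_names: list[str]
    spearman: np.ndarray          # k x k, unit diagonal
    spearman_p: np.ndarray        # k x k
    vif: np.ndarray | None = None  # k, may contain inf
    r_threshold: float = R_FLAG_DEFAULT
    vif_threshold: float = VIF_FLAG_DEFAULT
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_vif: list[tuple[str, float]] = field(default_factory=list)

    @property
    def blocking(self) -> bool:
        """True when any covariate exceeds the VIF threshold."""
        return bool(self.flagged_vif)

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariate_names,
            "spearman": self.spearman.tolist(),
            "spearman_p": self.spearman_p.tolist(),
            "vif": None if self.vif is None else [float(v) for v in self.vif],
            "r_threshold": self.r_threshold,
            "vif_threshold": self.vif_threshold,
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "flagged_vif": [list(p) for p in self.flagged_vif],
            "blocking": self.blocking,
            "note": "VIF computed from the covariate design alone; "
                    "the outcome plays no role in auxiliary regressions.",
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        k = len(self.covariate_names)
        lines = ["Collinearity screen", "===================", "",
                 "Spearman rank correlations (r_s / p):"]
        for i in range(k):
            for j in range(i + 1, k):
                lines.append(
                    f"  {self.covariate_names[i]} vs {self.covariate_names[j]}: "
                    f"r_s = {self.spearman[i, j]:+.3f} (p = {self.spearman_p[i, j]:.3g})"
                )
        if self.vif is not None:
            lines.append("")
            lines.append("Variance inflation factors (design-only):")
            for name, v in zip(self.covariate_names, self.vif):
                lines.append(f"  {name}: VIF = {v:.3f}")
        lines.append("")
        if self.flagged_pairs:
            lines.append(f"FLAG (informational, |r_s| >= {self.r_threshold}):")
            for a, b, r in self.flagged_pairs:
                lines.append(f"  {a} vs {b}: r_s = {r:+.3f}")
        if self.flagged_vif:
            lines.append(f"FLAG (blocking, VIF >= {self.vif_threshold}):")
            for name, v in self.flagged_vif:
                lines.append(f"  {name}: VIF = {v:.3f}")
        if not self.flagged_pairs and not self.flagged_vif:
            lines.append("No flags: covariates look mutually unrelated.")
        return "\n".join(lines)


def _covariate_array(table: CovariateTable) -> tuple[np.ndarray, list[str]]:
    return table.covariate_matrix(), list(COVARIATES)


def spearman_matrix(
    table: CovariateTable, r_threshold: float = R_FLAG_DEFAULT
) -> CollinearityReport:
    """Pairwise Spearman correlations with two-sided p-values."""
    X, names = _covariate_array(table)
    n, k = X.shape
    if n < 3:
        raise ValueError("Spearman screen needs at least 3 subjects")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    r = np.eye(k)
    p = np.zeros((k, k))
    flagged = []
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.spearmanr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            if abs(res.statistic) >= r_threshold:
                flagged.append((names[i], names[j], float(res.statistic)))
    return CollinearityReport(names, r, p, r_threshold=r_threshold,
                              flagged_pairs=flagged)


def vif(
    table: CovariateTable,
    vif_threshold: float = VIF_FLAG_DEFAULT,
    r_threshold: float = R_FLAG_DEFAULT,
) -> CollinearityReport:
    """Variance inflation factors via auxiliary regressions with intercept.

    Perfect collinearity (auxiliary R^2 = 1 within tolerance) yields an
    infinite VIF and a flag, not an exception.
    """
    X, names = _covariate_array(table)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("VIF needs more subjects than covariates plus one")
    report = spearman_matrix(table, r_threshold=r_threshold)
    vifs = np.empty(k)
    flagged = []
    for j in range(k):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")
        r2 = 1.0 - float(resid @ resid) / tss
        vifs[j] = np.inf if r2 >= _PERFECT_R2 else 1.0 / (1.0 - r2)
        if vifs[j] >= vif_threshold:
            flagged.append((names[j], float(vifs[j])))
    report.vif = vifs
    report.vif_threshold = vif_threshold
    report.flagged_vif = flagged
    return report


def screen(
    table: CovariateTable,
    r_threshold: float = R_FLAG_DEFAULT,
    vif_threshold: float = VIF_FLAG_DEFAULT,
) -> CollinearityReport:
    """Full screen: Spearman matrix plus VIFs in one report."""
    return vif(table, vif_threshold=vif_threshold, r_threshold=r_threshold)
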