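"""Atlas-based aggregation of importance maps and hierarchical clustering.

Voxel-level normalized importance is averaged within each atlas region's
overlap with the surviving mask; regions whose overlap is too small to be
informative are filtered out (absolute voxel-count threshold or a
percentile of the overlap distribution, the latter mirroring a median
cut); the remaining region x covariate profiles are grouped by
agglomerative clustering (Euclidean distance, average linkage by default)
so that regions where the same covariate dominates cluster together.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import GridMismatchError, Parcellation
from .importance import ImportanceMaps

LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class RegionalImportanceTable:
    """Region x covariate matrix of mean normalized importance."""

    data: pd.DataFrame          # columns: label, name, overlap, <covariates...>
    covariate_names: tuple[str, ...]

    def __post_init__(self) -> None:
        required = ["label", "name", "overlap", *self.covariate_names]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"regional table missing column(s): {missing}")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return len(self.data)

    def profiles(self) -> np.ndarray:
        """Region x covariate matrix for clustering."""
        return self.data[list(self.covariate_names)].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix, (R-1) x 4
    labels: list[int]            # region labels in table row order
    method: str
    metric: str

    @property
    def leaf_order(self) -> list[int]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage,
                            columns=["child1", "child2", "height", "size"])

    def to_json_tree(self) -> dict:
        """Nested-dict rendering of the dendrogram."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return {"region": self.labels[node.id]}
            return {
                "height": node.dist,
                "children": [walk(node.left), walk(node.right)],
            }

        return walk(tree)

    def flat_clusters(self, cut_height: float) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=cut_height, criterion="distance")


def regional_means(
    maps: ImportanceMaps, parc: Parcellation, surviving: np.ndarray | None = None
) -> RegionalImportanceTable:
    """Mean normalized importance over each region's surviving voxels.

    Regions with zero overlap with the surviving mask are omitted; the
    per-region overlap voxel count is recorded for the downstream filter.
    """
    if not parc.grid.same_as(maps.grid):
        raise GridMismatchError("parcellation grid does not match the maps")
    if surviving is None:
        surv_idx = maps.voxel_idx
    else:
        surviving = np.asarray(surviving, dtype=bool).reshape(-1)
        if surviving.shape[0] != maps.grid.n_voxels:
            raise GridMismatchError("surviving mask does not match the grid")
        keep = surviving[maps.voxel_idx]
        surv_idx = maps.voxel_idx[keep]

    labels_at = parc.labels[surv_idx]
    rows = []
    # map position within maps.voxel_idx for value lookup
    if surviving is None:
        values = {n: maps.normalized[n] for n in maps.covariate_names}
        pos = np.arange(surv_idx.size)
    else:
        values = {n: maps.normalized[n][surviving[maps.voxel_idx]]
                  for n in maps.covariate_names}
        pos = np.arange(surv_idx.size)

    for label in np.unique(labels_at):
        if label == 0:
            continue
        sel = pos[labels_at == label]
        row = {
            "label": int(label),
            "name": parc.names[int(label)],
            "overlap": int(sel.size),
        }
        for n in maps.covariate_names:
            row[n] = float(values[n][sel].mean())
        rows.append(row)
    if not rows:
        warnings.warn("no atlas region overlaps the surviving mask", stacklevel=2)
        df = pd.DataFrame(columns=["label", "name", "overlap",
                                   *maps.covariate_names])
    else:
        df = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    return RegionalImportanceTable(df, maps.covariate_names)


def overlap_filter(
    table: RegionalImportanceTable,
    mode: str = "percentile",
    value: float = 50.0,
) -> RegionalImportanceTable:
    """Drop regions whose surviving-mask overlap is too small.

    ``mode="absolute"`` keeps rows with overlap >= value voxels;
    ``mode="percentile"`` keeps rows at or above the given percentile of the
    overlap distribution (linear interpolation between order statistics).
    The default mirrors a median (50th-percentile) cut.
    """
    if table.n_regions == 0:
        raise ValueError("regional table is empty")
    overlaps = table.data["overlap"].to_numpy(dtype=float)
    if mode == "absolute":
        cutoff = float(value)
    elif mode == "percentile":
        if not 0.0 <= value <= 100.0:
            raise ValueError("percentile must be in [0, 100]")
        cutoff = float(np.percentile(overlaps, value))
    else:
        raise ValueError(f"unknown overlap filter mode {mode!r}")
    kept = table.data[overlaps >= cutoff].reset_index(drop=True)
    if kept.empty:
        warnings.warn("overlap filter removed every region; clustering will "
                      "be skipped", stacklevel=2)
    return RegionalImportanceTable(kept, table.covariate_names)


def hierarchical_cluster(
    table: RegionalImportanceTable,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of regional covariate-importance profiles.

    Deterministic given the table: scipy's linkage resolves ties by the
    lowest pair index, so identical inputs give identical merge sequences.
    """
    if method not in LINKAGES:
        raise ValueError(f"unsupported linkage {method!r}; choose from {LINKAGES}")
    if table.n_regions < 2:
        raise ValueError("clustering needs at least 2 regions")
    X = table.profiles()
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return ClusterResult(
        linkage=Z,
        labels=table.data["label"].tolist(),
        method=method,
        metric=metric,
    )


def dominant_covariate(table: RegionalImportanceTable) -> pd.DataFrame:
    """Per-region argmax covariate, ties broken by canonical covariate order.

    Returns the table plus ``dominant`` and ``tie`` columns; a tie flag is
    raised whenever the maximum is attained by more than one covariate.
    """
    if table.n_regions == 0:
        raise ValueError("regional table is empty")
    X = table.profiles()
    best = X.argmax(axis=1)  # first max = canonical order tie-break
    ties = (X == X.max(axis=1, keepdims=True)).sum(axis=1) > 1
    out = table.data.copy()
    out["dominant"] = [table.covariate_names[i] for i in best]
    out["tie"] = ties
    return out


def write_cluster_result(result: ClusterResult, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.merges_frame().to_csv(out_dir / "linkage.csv", index=False)
    (out_dir / "dendrogram.json").write_text(
        json.dumps({"method": result.method, "metric": result.metric,
                    "leaf_order": result.leaf_order,
                    "tree": result.to_json_tree()}, indent=2)
    )


def plot_importance_heatmap(
    table: RegionalImportanceTable,
    result: ClusterResult,
    path: str | Path,
) -> None:
    """Optional dendrogram-ordered heatmap of regional importance (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = hierarchy.leaves_list(result.linkage)
    X = table.profiles()[order]
    names = table.data["name"].to_numpy()[order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(8, max(3, 0.3 * len(order))),
        gridspec_kw={"width_ratios": [1, 3]},
    )
    hierarchy.dendrogram(result.linkage, orientation="left", ax=ax_d,
                         no_labels=True)
    im = ax_h.imshow(X, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax_h.set_yticks(range(len(order)), labels=names, fontsize=6)
    ax_h.set_xticks(range(len(table.covariate_names)),
                    labels=table.covariate_names, rotation=45, ha="right")
    fig.colorbar(im, ax=ax_h, label="mean normalized importance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
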