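import json

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from lesionmap import (
    COVARIATES,
    GridMismatchError,
    ImportanceMaps,
    Parcellation,
    RegionalImportanceTable,
    VoxelGrid,
    dominant_covariate,
    hierarchical_cluster,
    overlap_filter,
    regional_means,
)
from lesionmap.regional import write_cluster_result


def make_maps(grid, voxel_idx, normalized):
    """Fabricate ImportanceMaps with given normalized values per covariate."""
    voxel_idx = np.asarray(voxel_idx)
    raw = {k: np.asarray(v, dtype=float) for k, v in normalized.items()}
    return ImportanceMaps(
        grid=grid,
        voxel_idx=voxel_idx,
        covariate_names=tuple(normalized),
        raw=raw,
        normalized={k: np.asarray(v, dtype=float) for k, v in normalized.items()},
        bounds={k: (0.0, 1.0) for k in normalized},
    )


def make_parc(grid, labels, names=None):
    labels = np.asarray(labels)
    if names is None:
        present = sorted({int(v) for v in np.unique(labels)} - {0})
        names = {v: f"region-{v}" for v in present}
    return Parcellation(grid, labels, names)


def profile_table(profiles, overlaps=None):
    profiles = np.asarray(profiles, dtype=float)
    r = profiles.shape[0]
    overlaps = [10] * r if overlaps is None else list(overlaps)
    df = pd.DataFrame({
        "label": np.arange(1, r + 1),
        "name": [f"region-{i}" for i in range(1, r + 1)],
        "overlap": overlaps,
    })
    for j, name in enumerate(COVARIATES):
        df[name] = profiles[:, j]
    return RegionalImportanceTable(df, COVARIATES)


class TestRegionalMeans:
    def test_hand_computed_two_region_means(self):
        grid = VoxelGrid.isotropic((6, 1, 1))
        maps = make_maps(grid, [0, 1, 2, 3], {
            "age": [0.2, 0.4, 0.8, 1.0],
            "lesion_volume": [1.0, 0.0, 0.5, 0.5],
        })
        parc = make_parc(grid, [1, 1, 2, 2, 0, 0])
        table = regional_means(maps, parc)
        assert table.data["label"].tolist() == [1, 2]
        assert table.data["overlap"].tolist() == [2, 2]
        row1 = table.data.set_index("label").loc[1]
        assert row1["age"] == pytest.approx(0.3)
        assert row1["lesion_volume"] == pytest.approx(0.5)
        row2 = table.data.set_index("label").loc[2]
        assert row2["age"] == pytest.approx(0.9)
        assert row2["lesion_volume"] == pytest.approx(0.5)

    def test_constant_map_gives_constant_means(self):
        grid = VoxelGrid.isotropic((8, 1, 1))
        maps = make_maps(grid, np.arange(8), {"age": np.full(8, 0.7)})
        parc = make_parc(grid, [1, 1, 2, 2, 2, 3, 3, 3])
        table = regional_means(maps, parc)
        np.testing.assert_allclose(table.data["age"], 0.7)

    def test_zero_overlap_region_omitted(self):
        grid = VoxelGrid.isotropic((4, 1, 1))
        maps = make_maps(grid, [0, 1], {"age": [0.1, 0.9]})
        parc = make_parc(grid, [1, 1, 2, 2])  # region 2 has no survivors
        table = regional_means(maps, parc)
        assert table.data["label"].tolist() == [1]

    def test_no_overlap_at_all_warns(self):
        grid = VoxelGrid.isotropic((4, 1, 1))
        maps = make_maps(grid, [0, 1], {"age": [0.1, 0.9]})
        parc = make_parc(grid, [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="no atlas region"):
            table = regional_means(maps, parc)
        assert table.n_regions == 0

    def test_grid_mismatch_rejected(self):
        maps = make_maps(VoxelGrid.isotropic((4, 1, 1)), [0], {"age": [0.5]})
        parc = make_parc(VoxelGrid.isotropic((5, 1, 1)), [0, 0, 1, 1, 1])
        with pytest.raises(GridMismatchError):
            regional_means(maps, parc)


class TestOverlapFilter:
    def test_absolute_mode_example(self):
        table = profile_table(np.eye(3), overlaps=[100, 400, 900])
        kept = overlap_filter(table, mode="absolute", value=400)
        assert kept.data["overlap"].tolist() == [400, 900]

    def test_percentile_mode_median_cut(self):
        # median of (100, 400, 900) is 400 -> the two largest survive
        table = profile_table(np.eye(3), overlaps=[100, 400, 900])
        kept = overlap_filter(table, mode="percentile", value=50.0)
        assert kept.data["overlap"].tolist() == [400, 900]

    def test_zero_threshold_is_identity(self):
        table = profile_table(np.eye(3), overlaps=[5, 9, 2])
        kept = overlap_filter(table, mode="absolute", value=0)
        pd.testing.assert_frame_equal(kept.data, table.data)

    def test_idempotent(self):
        table = profile_table(np.eye(4), overlaps=[10, 40, 90, 5])
        once = overlap_filter(table, mode="absolute", value=40)
        twice = overlap_filter(once, mode="absolute", value=40)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_filter_everything_warns(self):
        table = profile_table(np.eye(3), overlaps=[1, 2, 3])
        with pytest.warns(UserWarning, match="removed every region"):
            kept = overlap_filter(table, mode="absolute", value=100)
        assert kept.n_regions == 0

    def test_validation(self):
        table = profile_table(np.eye(3))
        with pytest.raises(ValueError, match="percentile"):
            overlap_filter(table, mode="percentile", value=150)
        with pytest.raises(ValueError, match="mode"):
            overlap_filter(table, mode="median", value=1)


class TestClustering:
    def test_three_row_average_linkage_hand_trace(self):
        """A=(0,0,0), B=(1,0,0), C=(0,2.5,0): A,B merge at height 1, then the
        pair joins C at the average of d(A,C)=2.5 and d(B,C)=sqrt(7.25)."""
        table = profile_table([[0, 0, 0], [1, 0, 0], [0, 2.5, 0]])
        result = hierarchical_cluster(table, method="average")
        Z = result.linkage
        assert Z.shape == (2, 4)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx((2.5 + np.sqrt(7.25)) / 2)
        assert result.flat_clusters(cut_height=1.5).tolist() == [1, 1, 2]

    def test_duplicate_rows_merge_first_at_height_zero(self):
        table = profile_table([[0.5, 0.5, 0.0], [0.9, 0.1, 0.2],
                               [0.5, 0.5, 0.0]])
        Z = hierarchical_cluster(table).linkage
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_row_permutation_leaves_cophenetic_distances_unchanged(self, rng):
        profiles = rng.random((8, 3))
        table = profile_table(profiles)
        base = hierarchical_cluster(table)

        perm = rng.permutation(8)
        permuted = profile_table(profiles[perm])
        other = hierarchical_cluster(permuted)

        def coph_by_label(result, table):
            d = hierarchy.cophenet(result.linkage)
            from scipy.spatial.distance import squareform

            M = squareform(d)
            labels = table.data["label"].tolist()
            return {
                frozenset((profiles_key(table, i), profiles_key(table, j))):
                    M[i, j]
                for i in range(len(labels)) for j in range(i + 1, len(labels))
            }

        def profiles_key(table, i):
            return tuple(np.round(table.profiles()[i], 12))

        a = coph_by_label(base, table)
        b = coph_by_label(other, permuted)
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-10)

    def test_needs_two_regions(self):
        table = profile_table([[0.1, 0.2, 0.3]])
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(table)

    def test_unknown_linkage_rejected(self):
        table = profile_table(np.eye(3))
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(table, method="centroid-ish")

    def test_written_outputs(self, tmp_path):
        table = profile_table([[0, 0, 0], [1, 0, 0], [0, 2.5, 0]])
        result = hierarchical_cluster(table)
        write_cluster_result(result, tmp_path)
        tree = json.loads((tmp_path / "dendrogram.json").read_text())
        assert tree["method"] == "average"
        assert sorted(tree["leaf_order"]) == [1, 2, 3]
        linkage_df = pd.read_csv(tmp_path / "linkage.csv")
        assert list(linkage_df.columns) == ["child1", "child2", "height", "size"]


class TestDominantCovariate:
    def test_argmax_per_region(self):
        table = profile_table([
            [0.9, 0.1, 0.0],   # age dominant
            [0.2, 0.8, 0.1],   # lesion_volume dominant
            [0.1, 0.2, 0.7],   # followup_time dominant
        ])
        out = dominant_covariate(table)
        assert out["dominant"].tolist() == list(COVARIATES)
        assert not out["tie"].any()

    def test_tie_flag_and_canonical_order_break(self):
        table = profile_table([[0.5, 0.5, 0.1]])
        out = dominant_covariate(table)
        assert out["dominant"].tolist() == ["age"]  # canonical-order break
        assert out["tie"].tolist() == [True]

    def test_empty_table_rejected(self):
        table = profile_table(np.eye(3))
        empty = RegionalImportanceTable(table.data.iloc[0:0], COVARIATES)
        with pytest.raises(ValueError, match="empty"):
            dominant_covariate(empty)


@pytest.fixture
def rng():
    return np.random.default_rng(77)
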