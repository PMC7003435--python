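import numpy as np
import pandas as pd
import pytest

from connectosync import reach_probability as rp
from connectosync.exceptions import (
    DegenerateTractError,
    MappingError,
    ThresholdError,
)

from conftest import brute_force_reach, random_label_grid


def slab_volume():
    """3x3x3 grid: white matter at z=0, one ROI slab at z in {1, 2}."""
    vol = np.zeros((3, 3, 3), dtype=np.int32)
    vol[:, :, 0] = 1
    vol[:, :, 1:] = 2
    return rp.LabelVolume(values=vol)


class TestBoundaryMask:
    def test_slab_mask_is_first_roi_layer(self):
        labels = slab_volume()
        mask = rp.boundary_mask(labels, 2)
        assert mask.sum() == 9
        assert mask[:, :, 1].all()
        assert not mask[:, :, 2].any()  # interior ROI voxels excluded

    def test_single_voxel_next_to_wm_included(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[0, 0, 0] = 1
        vol[0, 0, 1] = 2
        labels = rp.LabelVolume(values=vol)
        mask = rp.boundary_mask(labels, 2)
        assert mask[0, 0, 1] and mask.sum() == 1

    def test_diagonal_neighbour_needs_26_connectivity(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[0, 0, 0] = 1
        vol[1, 1, 1] = 2
        labels = rp.LabelVolume(values=vol)
        assert rp.boundary_mask(labels, 2, connectivity=6).sum() == 0
        assert rp.boundary_mask(labels, 2, connectivity=26).sum() == 1

    def test_unknown_roi_raises(self):
        with pytest.raises(MappingError):
            rp.boundary_mask(slab_volume(), 99)


class TestReachProbability:
    def test_all_mass_on_single_mask_voxel(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[0, 0, 0] = 1
        vol[0, 0, 1] = 2
        labels = rp.LabelVolume(values=vol)
        counts = np.zeros((3, 3, 3), dtype=np.int64)
        counts[0, 0, 1] = 100
        row = rp.reach_probability(
            rp.TractPathVolume("t", counts), labels, [2]
        )
        assert row[2] == 1.0

    def test_no_mass_in_any_mask_gives_zeros(self):
        labels = slab_volume()
        counts = np.zeros((3, 3, 3), dtype=np.int64)
        counts[:, :, 0] = 5  # all in white matter
        row = rp.reach_probability(rp.TractPathVolume("t", counts), labels)
        assert (row == 0).all()

    def test_hand_computed_example(self):
        # counts: two mask voxels 30 and 10, one WM voxel 60 -> per-voxel
        # 0.3, 0.1 and reach = mean over the 2-voxel mask = 0.2
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[0, 0, 0] = 1
        vol[0, 0, 1] = 2
        vol[0, 1, 0] = 1
        vol[0, 1, 1] = 2
        labels = rp.LabelVolume(values=vol)
        counts = np.zeros((3, 3, 3), dtype=np.int64)
        counts[0, 0, 1] = 30
        counts[0, 1, 1] = 10
        counts[0, 0, 0] = 60
        row = rp.reach_probability(
            rp.TractPathVolume("t", counts), labels, [2]
        )
        assert row[2] == pytest.approx(0.2)

    def test_degenerate_tract_raises_with_name(self):
        labels = slab_volume()
        counts = np.zeros((3, 3, 3), dtype=np.int64)
        counts[2, 2, 2] = 7  # interior ROI voxel: outside trimmed support
        with pytest.raises(DegenerateTractError, match="mytract"):
            rp.reach_probability(
                rp.TractPathVolume("mytract", counts), labels
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        labels = random_label_grid(rng, shape=(5, 5, 5), n_rois=3)
        counts = rng.integers(0, 20, size=(5, 5, 5)).astype(np.int64)
        tract = rp.TractPathVolume("t", counts)
        rois = labels.roi_labels
        support = rp.trimmed_support(labels, rois)
        if counts[support].sum() == 0:
            pytest.skip("degenerate draw")
        fast = rp.reach_probability(tract, labels, rois)
        slow = brute_force_reach(tract, labels, rois)
        pd.testing.assert_series_equal(
            fast.sort_index(), slow.sort_index(), check_names=False
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        labels = random_label_grid(rng, shape=(5, 5, 5), n_rois=3)
        counts = rng.integers(0, 20, size=(5, 5, 5)).astype(np.int64)
        row1 = rp.reach_probability(rp.TractPathVolume("t", counts), labels)
        row7 = rp.reach_probability(
            rp.TractPathVolume("t", counts * 7), labels
        )
        pd.testing.assert_series_equal(row1, row7)

    def test_normalized_mass_fractions_sum_to_one(self, tract_volumes, label_volume):
        # over the trimmed support the per-voxel values form a probability
        # distribution: mask-partition sums plus the WM remainder reach 1
        tract = tract_volumes[0]
        support = rp.trimmed_support(label_volume)
        norm = tract.counts[support].astype(float)
        assert norm.sum() / norm.sum() == pytest.approx(1.0)
        row = rp.reach_probability(tract, label_volume)
        total_mask_fraction = 0.0
        for roi in label_volume.roi_labels:
            mask = rp.boundary_mask(label_volume, roi)
            total_mask_fraction += row[roi] * mask.sum()
        wm = label_volume.values == label_volume.wm_label
        wm_fraction = tract.counts[wm].sum() / tract.counts[support].sum()
        assert total_mask_fraction + wm_fraction == pytest.approx(1.0)


class TestConnectionThreshold:
    def test_fixed_cutoff_counts_connections(self):
        m = pd.DataFrame([[0.0, 0.001, 0.003]], index=["t"], columns=[2, 3, 4])
        conn = rp.connection_threshold(m, mode="fixed", cutoff=0.002)
        assert conn.n_connections == 1

    def test_raising_cutoff_monotone(self, reach_matrix):
        counts = [
            rp.connection_threshold(
                reach_matrix, mode="fixed", cutoff=c
            ).n_connections
            for c in (0.001, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_ecdf_reflection_recovers_planted_set(
        self, reach_matrix, small_config
    ):
        conn = rp.connection_threshold(reach_matrix, mode="ecdf_reflection")
        found = {
            (t, r)
            for t in conn.connected.index
            for r in conn.connected.columns
            if conn.connected.loc[t, r]
        }
        planted = {(t, r) for t, r, _ in small_config.planted_connections}
        assert found == planted
        assert conn.gumbel_fit is not None

    def test_all_zero_matrix_raises(self):
        m = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(ThresholdError):
            rp.connection_threshold(m)

    def test_fixed_mode_requires_cutoff(self, reach_matrix):
        with pytest.raises(ValueError):
            rp.connection_threshold(reach_matrix, mode="fixed", cutoff=None)


class TestClassifyRegionPairs:
    @staticmethod
    def conn_from(bool_df):
        return rp.ConnectionSet(cutoff=0.5, connected=bool_df, mode="fixed")

    def test_empty_connectome_all_not_bound(self):
        conn = self.conn_from(
            pd.DataFrame(False, index=["t1"], columns=[2, 3, 4])
        )
        rmap = pd.DataFrame(
            {"region_id": ["A", "B", "C"], "roi_id": [2, 3, 4]}
        )
        classes = rp.classify_region_pairs(conn, rmap, ad_tracts=())
        assert classes.counts[rp.NOT_BOUND] == 3
        assert classes.counts[rp.TRACT_BOUND] == 0

    def test_seventeen_regions_give_136_pairs(self):
        rois = list(range(2, 19))
        conn = self.conn_from(
            pd.DataFrame(False, index=["t1"], columns=rois)
        )
        rmap = pd.DataFrame(
            {"region_id": [f"R{i:02d}" for i in range(17)], "roi_id": rois}
        )
        classes = rp.classify_region_pairs(conn, rmap, ad_tracts=())
        assert len(classes.pairs) == 136

    def test_single_ad_tract_pair(self):
        df = pd.DataFrame(False, index=["t1"], columns=[2, 3, 4])
        df.loc["t1", 2] = True
        df.loc["t1", 3] = True
        conn = self.conn_from(df)
        rmap = pd.DataFrame(
            {"region_id": ["A", "B", "C"], "roi_id": [2, 3, 4]}
        )
        classes = rp.classify_region_pairs(conn, rmap, ad_tracts=("t1",))
        assert classes.counts[rp.AD_TRACT_BOUND] == 1
        assert classes.counts[rp.NOT_BOUND] == 2
        assert classes.klass("B", "A") == rp.AD_TRACT_BOUND  # symmetric

    def test_classes_partition_all_pairs(self, reach_matrix, small_config):
        from connectosync import synthetic_data as syn

        conn = rp.connection_threshold(reach_matrix, mode="ecdf_reflection")
        classes = rp.classify_region_pairs(
            conn, syn.default_region_map(small_config), ad_tracts=("tract01",)
        )
        n = small_config.n_regions
        assert sum(classes.counts.values()) == n * (n - 1) // 2

    def test_unmapped_region_raises(self):
        conn = self.conn_from(
            pd.DataFrame(False, index=["t1"], columns=[2, 3])
        )
        rmap = pd.DataFrame({"region_id": ["A", "B"], "roi_id": [2, 99]})
        with pytest.raises(MappingError):
            rp.classify_region_pairs(conn, rmap, ad_tracts=())
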