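import numpy as np
import pytest

import petmap as pm
from petmap import clusters as cl
from petmap.statmap import StatMap

import oracles


def _zmap(grid, values, mask=None):
    if mask is None:
        mask = pm.BrainMask(grid, np.ones(grid.shape, dtype=bool))
    return StatMap(values, "z", grid, mask)


class TestExtractClusters:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_flood_fill_oracle(self, g16, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(30):
            values = rng.standard_normal(g16.shape) * 2.0
            report = cl.extract_clusters(_zmap(g16, values), 3.0, connectivity)
            expected = oracles.flood_fill_clusters(values > 3.0, connectivity)
            got = [frozenset(map(tuple, c.voxel_indices))
                   for c in report.clusters]
            assert sorted(got, key=sorted) == sorted(expected, key=sorted)

    def test_strict_threshold(self, g16):
        values = np.zeros(g16.shape)
        values[4, 4, 4] = 3.0          # exactly at threshold: excluded
        values[8, 8, 8] = 3.0001
        report = cl.extract_clusters(_zmap(g16, values), 3.0)
        assert report.n_clusters == 1
        assert report.clusters[0].peak_voxel == (8, 8, 8)

    def test_single_voxel_cluster(self, g16):
        values = np.zeros(g16.shape)
        values[2, 3, 4] = 5.0
        report = cl.extract_clusters(_zmap(g16, values), 3.0)
        assert report.clusters[0].size_voxels == 1
        assert report.clusters[0].peak_mm == tuple(
            g16.voxel_to_world((2, 3, 4)))

    def test_peak_tie_is_lexicographic(self, g16):
        values = np.zeros(g16.shape)
        values[5, 5, 5] = 4.0
        values[5, 5, 6] = 4.0          # same value, one cluster
        report = cl.extract_clusters(_zmap(g16, values), 3.0)
        assert report.clusters[0].peak_voxel == (5, 5, 5)

    def test_invalid_connectivity(self, g16):
        with pytest.raises(ValueError):
            cl.extract_clusters(_zmap(g16, np.zeros(g16.shape)), 3.0, 4)

    def test_report_sorted_by_size(self, g16):
        values = np.zeros(g16.shape)
        values[1:3, 1:3, 1:3] = 5.0    # 8 voxels
        values[10, 10, 10] = 5.0       # 1 voxel
        report = cl.extract_clusters(_zmap(g16, values), 3.0)
        assert [c.size_voxels for c in report.clusters] == [8, 1]
        assert report.total_size == 9
        assert report.max_cluster_size == 8


class TestClassifyAndPeak:
    def test_classification_is_strict(self, g16):
        grid = pm.VolumeGrid.centered((16, 16, 16), (2.0, 2.0, 2.0))
        values = np.zeros(grid.shape)
        values.flat[:250] = 5.0        # one 250-voxel slab cluster
        report = cl.extract_clusters(_zmap(grid, values), 3.0)
        assert report.max_cluster_size == 250
        assert cl.classify_scan(report) == "negative"
        values.flat[250] = 5.0
        report = cl.extract_clusters(_zmap(grid, values), 3.0)
        assert cl.classify_scan(report) == "positive"

    def test_threshold_mismatch_rejected(self, g16):
        report = cl.extract_clusters(_zmap(g16, np.zeros(g16.shape)), 2.0)
        with pytest.raises(ValueError):
            cl.classify_scan(report, z_threshold=3.0)

    def test_peak_info_matches_argmax(self, g16):
        rng = np.random.default_rng(11)
        values = rng.standard_normal(g16.shape) * 2.5
        report = cl.extract_clusters(_zmap(g16, values), 3.0)
        if report.clusters:
            peak_value, peak_mm = cl.peak_info(report)
            supra = np.where(values > 3.0, values, -np.inf)
            assert peak_value == pytest.approx(supra.max())
            idx = np.unravel_index(np.argmax(supra), values.shape)
            assert peak_mm == tuple(g16.voxel_to_world(idx))

    def test_peak_info_empty_report(self, g16):
        report = cl.extract_clusters(_zmap(g16, np.zeros(g16.shape)), 3.0)
        with pytest.raises(ValueError):
            cl.peak_info(report)


class TestOverlap:
    def test_identical_masks(self, rng):
        m = rng.random((10, 10, 10)) > 0.5
        out = cl.overlap_stats(m, m)
        assert out["fractions"] == [1.0, 1.0]
        assert out["dice"] == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        out = cl.overlap_stats(a, b)
        assert out["common_size"] == 0
        assert out["dice"] == 0.0

    def test_set_arithmetic_oracle(self, rng):
        for _ in range(20):
            masks = [rng.random((9, 9, 9)) > 0.4 for _ in range(3)]
            got = cl.overlap_stats(*masks)
            expected = oracles.overlap_sets(*masks)
            assert got == expected

    def test_needs_two_masks(self):
        with pytest.raises(ValueError):
            cl.overlap_stats(np.ones((8, 8, 8), dtype=bool))


class TestWilcoxon:
    def test_exact_p_matches_enumeration(self):
        a = [120.0, 340.0, 90.0, 410.0, 260.0, 75.0]
        b = [100.0, 300.0, 140.0, 380.0, 305.0, 60.0]   # tie-free |differences|
        _w, p = cl.compare_cluster_sizes(a, b)
        expected = oracles.wilcoxon_exact_p(
            [x - y for x, y in zip(a, b)])
        assert p == pytest.approx(expected, abs=1e-12)

    def test_degenerate_and_validation(self):
        with pytest.raises(ValueError):
            cl.compare_cluster_sizes([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            cl.compare_cluster_sizes([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError):
            cl.compare_cluster_sizes([1] * 6, [2] * 5)
        with pytest.raises(ValueError):
            cl.compare_cluster_sizes([1] * 6, [2] * 6, paired=False)


class TestLabelPeak:
    def test_named_regions(self, small_grid):
        from petmap import phantom
        atlas = phantom.make_atlas(small_grid)
        striatum = phantom.STRIATUM["center"]
        assert cl.label_peak(striatum, atlas) == "striatum"
        assert cl.label_peak((400.0, 0.0, 0.0), atlas) == "outside"
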