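import numpy as np
import pytest
from scipy import stats

import petmap as pm
from petmap import refdb, statmap
from petmap.statmap import (DegenerateDataError, MetaMismatchError, StatMap,
                            ThresholdResult)

import oracles


def _volumes(grid, rng, n, loc=80.0, scale=5.0):
    return [pm.BrainVolume(grid, loc + scale * rng.standard_normal(grid.shape))
            for _ in range(n)]


@pytest.fixture
def small_db(g16, rng, full_mask):
    return refdb.build_reference(_volumes(g16, rng, 10), full_mask)


class TestZScoreMap:
    def test_matches_loop_oracle(self, g16, rng, full_mask, small_db):
        patient = _volumes(g16, rng, 1)[0]
        zmap = statmap.zscore_map(patient, small_db, cap=None)
        expected = oracles.zscore_loop(small_db.mean.data,
                                       small_db.stddev.data,
                                       patient.data, full_mask.data)
        assert np.max(np.abs(zmap.values - expected)) < 1e-12

    def test_cap_clips_both_directions(self, g16, full_mask, small_db):
        patient = small_db.mean.with_data(
            small_db.mean.data - 100.0 * small_db.stddev.data)
        zmap = statmap.zscore_map(patient, small_db, cap=5.0)
        assert zmap.max_in_mask() == 5.0
        hyper = small_db.mean.with_data(
            small_db.mean.data + 100.0 * small_db.stddev.data)
        zmap2 = statmap.zscore_map(hyper, small_db, cap=5.0)
        assert zmap2.values.min() == -5.0

    def test_default_cap_is_7_9(self):
        assert statmap.DEFAULT_Z_CAP == 7.9

    def test_invalid_cap(self, small_db):
        with pytest.raises(ValueError):
            statmap.zscore_map(small_db.mean, small_db, cap=0.0)

    def test_meta_mismatch(self, small_db):
        small_db.meta["fwhm_mm"] = 10.0
        with pytest.raises(MetaMismatchError):
            statmap.zscore_map(small_db.mean, small_db,
                               patient_meta={"fwhm_mm": 8.0})


class TestSingleSubjectT:
    def test_matches_loop_oracle(self, g16, rng, full_mask):
        controls = _volumes(g16, rng, 8)
        patient = _volumes(g16, rng, 1)[0]
        tmap = statmap.single_subject_tmap(patient, controls, full_mask)
        expected = oracles.single_subject_t_loop(
            patient.data, [c.data for c in controls], full_mask.data)
        assert tmap.df == 7
        assert np.max(np.abs(tmap.values - expected)) < 1e-12

    def test_needs_two_controls(self, g16, rng, full_mask):
        vols = _volumes(g16, rng, 1)
        with pytest.raises(ValueError):
            statmap.single_subject_tmap(vols[0], vols, full_mask)


class TestTToZ:
    def test_quadrature_value(self):
        assert statmap.t_to_z(2.0, 36) == pytest.approx(
            oracles.t_to_z_quadrature(2.0, 36), abs=1e-6)

    def test_odd(self):
        for t in (0.5, 1.7, 4.0, 9.0):
            assert statmap.t_to_z(-t, 12) == pytest.approx(
                -statmap.t_to_z(t, 12), abs=1e-12)

    def test_monotone_and_finite_far_tail(self):
        ts = np.linspace(-50, 50, 101)
        zs = statmap.t_to_z(ts, 100)
        assert np.all(np.isfinite(zs))
        assert np.all(np.diff(zs) > 0)

    def test_df_validation(self):
        with pytest.raises(ValueError):
            statmap.t_to_z(1.0, 0)

    def test_tmap_to_zmap_preserves_peak_location(self, g16, rng, full_mask):
        controls = _volumes(g16, rng, 8)
        patient = _volumes(g16, rng, 1)[0]
        tmap = statmap.single_subject_tmap(patient, controls, full_mask)
        zmap = statmap.tmap_to_zmap(tmap)
        assert np.argmax(tmap.values) == np.argmax(zmap.values)
        assert zmap.kind == "z"

    def test_tmap_to_zmap_rejects_zmaps(self, g16, full_mask):
        zmap = StatMap(np.zeros(g16.shape), "z", g16, full_mask)
        with pytest.raises(ValueError):
            statmap.tmap_to_zmap(zmap)


class TestGroupMaps:
    def test_paired_matches_loop_oracle(self, g16, rng, full_mask):
        a = _volumes(g16, rng, 6)
        b = _volumes(g16, rng, 6)
        tmap = statmap.paired_ttest_map(a, b, full_mask)
        expected = oracles.paired_t_loop([v.data for v in a],
                                         [v.data for v in b], full_mask.data)
        assert tmap.df == 5
        assert np.max(np.abs(tmap.values - expected)) < 1e-10

    def test_paired_degenerate(self, g16, rng, full_mask):
        a = _volumes(g16, rng, 4)
        with pytest.raises(DegenerateDataError):
            statmap.paired_ttest_map(a, a, full_mask)

    def test_paired_length_mismatch(self, g16, rng, full_mask):
        with pytest.raises(ValueError):
            statmap.paired_ttest_map(_volumes(g16, rng, 3),
                                     _volumes(g16, rng, 4), full_mask)

    def test_two_sample_matches_loop_oracle(self, g16, rng, full_mask):
        a = _volumes(g16, rng, 7)
        b = _volumes(g16, rng, 5)
        tmap = statmap.group_two_sample_tmap(a, b, full_mask)
        expected = oracles.two_sample_t_loop([v.data for v in a],
                                             [v.data for v in b],
                                             full_mask.data)
        assert tmap.df == 10
        assert np.max(np.abs(tmap.values - expected)) < 1e-10

    def test_two_sample_sign_convention(self, g16, full_mask, rng):
        a = _volumes(g16, rng, 4, loc=100.0)
        b = _volumes(g16, rng, 4, loc=50.0)     # B lower -> hypometabolism
        tmap = statmap.group_two_sample_tmap(a, b, full_mask)
        assert tmap.values[full_mask.data].mean() > 0


class TestThresholding:
    def test_bonferroni_critical_value(self):
        crit = statmap.stat_threshold("t", 55, 0.001, "bonferroni", 10 ** 5)
        assert crit == pytest.approx(stats.t.isf(0.001 / 10 ** 5, 55), abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            statmap.stat_threshold("z", None, 0.0, "none", 10)
        with pytest.raises(ValueError):
            statmap.stat_threshold("z", None, 0.01, "fdr", 10)

    def test_threshold_map_may_be_empty(self, g16, full_mask):
        zmap = StatMap(np.zeros(g16.shape), "z", g16, full_mask)
        res = statmap.threshold_map(zmap, 0.001, "bonferroni")
        assert isinstance(res, ThresholdResult)
        assert res.n_voxels == 0

    def test_threshold_map_selects_exceedances(self, g16, full_mask):
        values = np.zeros(g16.shape)
        values[5, 5, 5] = 10.0
        zmap = StatMap(values, "z", g16, full_mask)
        res = statmap.threshold_map(zmap, 0.001)
        assert res.n_voxels == 1
        assert res.data[5, 5, 5]


class TestStatMapContainer:
    def test_kind_and_df_rules(self, g16, full_mask):
        with pytest.raises(ValueError):
            StatMap(np.zeros(g16.shape), "w", g16, full_mask)
        with pytest.raises(ValueError):
            StatMap(np.zeros(g16.shape), "t", g16, full_mask)        # missing df
        with pytest.raises(ValueError):
            StatMap(np.zeros(g16.shape), "z", g16, full_mask, df=5)  # z has no df

    def test_zeroed_outside_mask(self, g16):
        m = np.zeros(g16.shape, dtype=bool)
        m[2:6, 2:6, 2:6] = True
        smap = StatMap(np.ones(g16.shape), "z", g16, pm.BrainMask(g16, m))
        assert np.all(smap.values[~m] == 0.0)

    def test_negated_flips_sign_convention(self, g16, full_mask):
        smap = StatMap(np.ones(g16.shape), "z", g16, full_mask)
        neg = smap.negated()
        assert np.all(neg.values == -1.0)
        assert "hypermetabolism" in neg.sign_convention
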