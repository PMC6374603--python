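"""GLM feature selection: design matrices, first/group level, conjunction,
cluster correction, end-to-end mask pipelines."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mindtrack import boldsim as bs, designgen as dg, featselect as fs
from mindtrack.exceptions import (DesignError, InsufficientDataError,
                                  ParameterError, ShapeError)


def _toy_events():
    return pd.DataFrame({
        "onset": [2.0, 10.0, 20.0],
        "duration": [2.0, 2.0, 2.0],
        "trial_type": ["a", "a", "b"],
        "rt": [0.5, 0.9, 0.7],
    })


class TestDesignMatrix:
    def test_toy_boxcar_matches_discrete_convolution_oracle(self):
        """Hand convolution on a 0.1 s grid reproduces the 'a' column."""
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        X = fs.build_design_matrix(_toy_events(), sched, drift_order=0)
        dt = 0.1
        n = int(40 / dt)
        box = np.zeros(n)
        for o in (2.0, 10.0):
            box[int(o / dt):int((o + 2.0) / dt)] += 1.0
        hrf = bs._hrf_fine(dt)
        conv = np.array([sum(box[j - k] * hrf[k]
                             for k in range(min(j + 1, hrf.size)))
                         for j in np.arange(0, n, 10)])
        np.testing.assert_allclose(X.frame["a"].to_numpy(), conv, atol=1e-9)

    def test_constant_modulator_column_is_zero(self):
        ev = _toy_events()
        ev["rt"] = 0.7
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        with pytest.raises(DesignError):
            # all-zero modulator column is perfectly collinear -> flagged
            fs.build_design_matrix(ev, sched, modulators=[("a", "rt")])

    def test_missing_condition_warns_and_omits(self, caplog):
        ev = _toy_events()
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        with caplog.at_level("WARNING", logger="mindtrack.featselect"):
            X = fs.build_design_matrix(ev, sched, modulators=[("c", "rt")])
        assert "c" not in X.columns
        assert any("no events" in r.message for r in caplog.records)

    def test_rank_deficiency_names_columns(self):
        ev = pd.concat([_toy_events(), _toy_events().assign(trial_type="dup")])
        ev.loc[ev.trial_type == "dup", "trial_type"] = "a2"
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        with pytest.raises(DesignError, match="a2"):
            fs.build_design_matrix(ev, sched)

    def test_modulator_centered_before_convolution(self):
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        X = fs.build_design_matrix(_toy_events(), sched,
                                   modulators=[("a", "rt")])
        col = X.frame["a_x_rt"].to_numpy()
        # amplitudes (0.5, 0.9) centered to (-0.2, +0.2): early negative lobe
        assert col[:8].min() < 0 and col[8:16].max() > 0


def _bold_from_matrix(series, shape=(4, 4, 3), tr=1.0):
    """One signal voxel carrying `series`; the rest zero-mean noise."""
    rng = np.random.default_rng(0)
    mask = np.ones(shape, dtype=bool)
    data = 0.01 * rng.standard_normal((*shape, series.size))
    data[1, 1, 1] = series
    return bs.BoldSeries(data=data.astype(np.float32), tr=tr,
                         affine=np.eye(4), brain_mask=mask)


class TestFirstLevel:
    def test_noiseless_recovery_exact(self):
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        X = fs.build_design_matrix(_toy_events(), sched)
        series = 2.0 * X.frame["a"].to_numpy()
        bold = _bold_from_matrix(series)
        bold.data[1, 1, 1] = series        # exact, no noise at signal voxel
        eff, var = fs.fit_first_level(bold, X, {"a": 1.0}, prewhiten=False)
        assert eff[1, 1, 1] == pytest.approx(2.0, rel=1e-6)

    def test_time_permutation_destroys_effect(self):
        sched = dg.TrSchedule(tr=1.0, n_volumes=60)
        ev = _toy_events()
        X = fs.build_design_matrix(ev, sched)
        rng = np.random.default_rng(3)
        series = 2.0 * X.frame["a"].to_numpy() + 0.1 * rng.standard_normal(60)
        bold = _bold_from_matrix(series)
        eff, var = fs.fit_first_level(bold, X, {"a": 1.0}, prewhiten=False)
        t_obs = eff[1, 1, 1] / np.sqrt(var[1, 1, 1])
        perm = rng.permutation(60)
        bold_p = bs.BoldSeries(data=bold.data[..., perm], tr=1.0,
                               affine=np.eye(4), brain_mask=bold.brain_mask)
        eff_p, var_p = fs.fit_first_level(bold_p, X, {"a": 1.0},
                                          prewhiten=False)
        t_perm = eff_p[1, 1, 1] / np.sqrt(var_p[1, 1, 1])
        assert t_obs > 10 and abs(t_perm) < 4

    def test_bad_contrast_name_rejected(self):
        sched = dg.TrSchedule(tr=1.0, n_volumes=40)
        X = fs.build_design_matrix(_toy_events(), sched)
        bold = _bold_from_matrix(np.zeros(40))
        with pytest.raises(DesignError):
            fs.fit_first_level(bold, X, {"nonexistent": 1.0})

    def test_too_few_timepoints(self):
        sched = dg.TrSchedule(tr=1.0, n_volumes=6)
        ev = _toy_events().iloc[:1]
        X = fs.build_design_matrix(ev, sched, drift_order=2)
        bold = _bold_from_matrix(np.zeros(6))
        X.frame = pd.concat([X.frame] * 2, axis=1)
        with pytest.raises((InsufficientDataError, DesignError)):
            fs.fit_first_level(bold, X, np.zeros(X.frame.shape[1]))


class TestGroupLevel:
    def test_consistent_effects_grow_with_n(self, rng):
        mask = np.ones((5, 5, 3), dtype=bool)
        eff = np.ones((5, 5, 3))
        var = np.full((5, 5, 3), 0.5)
        z6 = fs.fit_group_level([eff] * 6, [var] * 6, mask).data[2, 2, 1]
        z12 = fs.fit_group_level([eff] * 12, [var] * 12, mask).data[2, 2, 1]
        assert 0 < z6 < z12

    def test_symmetric_effects_near_zero(self):
        mask = np.ones((4, 4, 2), dtype=bool)
        effs = [np.full(mask.shape, v) for v in (-2.0, -1.0, 1.0, 2.0)]
        vars_ = [np.full(mask.shape, 0.3)] * 4
        z = fs.fit_group_level(effs, vars_, mask).data
        assert np.abs(z).max() < 1e-8

    def test_matches_one_sample_t_in_dominant_tau_limit(self, rng):
        mask = np.ones((3, 3, 2), dtype=bool)
        k = 12
        y = rng.standard_normal((k, 1)) * np.ones((k, mask.sum()))
        y += 0.3 * rng.standard_normal((k, mask.sum()))
        effs = []
        for i in range(k):
            m = np.zeros(mask.shape)
            m[mask] = y[i]
            effs.append(m)
        vars_ = [np.full(mask.shape, 1e-8)] * k
        z = fs.fit_group_level(effs, vars_, mask).data[mask]
        t_stat = y.mean(axis=0) / (y.std(axis=0, ddof=1) / np.sqrt(k))
        np.testing.assert_allclose(z, t_stat * np.sqrt((k - 1) / k),
                                   rtol=0.15)

    def test_requires_three_subjects(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(InsufficientDataError):
            fs.fit_group_level([np.zeros(mask.shape)] * 2,
                               [np.ones(mask.shape)] * 2, mask)


class TestConjunction:
    def test_voxelwise_minimum(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        a = fs.StatMap(np.full(mask.shape, 3.0), 10, "a", mask)
        b = fs.StatMap(np.full(mask.shape, 5.0), 10, "b", mask)
        conj = fs.conjunction_min(a, b)
        assert np.all(conj.data == 3.0)
        assert np.all(conj.data <= a.data) and np.all(conj.data <= b.data)

    def test_threshold_equals_parent_intersection(self, rng):
        mask = np.ones((6, 6, 4), dtype=bool)
        a = fs.StatMap(rng.standard_normal(mask.shape) * 2, 10, "a", mask)
        b = fs.StatMap(rng.standard_normal(mask.shape) * 2, 10, "b", mask)
        thr = 1.5
        conj = fs.conjunction_min(a, b)
        np.testing.assert_array_equal(conj.data > thr,
                                      (a.data > thr) & (b.data > thr))

    def test_grid_mismatch(self):
        m1 = np.ones((2, 2, 1), dtype=bool)
        m2 = np.ones((3, 2, 1), dtype=bool)
        with pytest.raises(ShapeError):
            fs.conjunction_min(fs.StatMap(np.zeros(m1.shape), 5, "a", m1),
                               fs.StatMap(np.zeros(m2.shape), 5, "b", m2))


class TestClusterCorrect:
    @staticmethod
    def _null_inputs(rng, n_sub=8, shape=(10, 10, 6)):
        mask = np.zeros(shape, dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True
        effs = [rng.standard_normal(shape) * mask for _ in range(n_sub)]
        vars_ = [np.ones(shape) for _ in range(n_sub)]
        return effs, vars_, mask

    def test_single_blob_yields_one_cluster(self, rng):
        effs, vars_, mask = self._null_inputs(rng)
        for e in effs:
            e[3:7, 3:7, 2:4] += 6.0
        g = fs.fit_group_level(effs, vars_, mask)
        null = fs.SignFlipNull(effs, vars_, mask)
        m = fs.cluster_correct(g, 0.01, 0.05, null, n_perm=150, seed=0)
        assert len(m.provenance["cluster_sizes"]) == 1
        assert m.n_voxels >= 4 * 4 * 2 * 0.8

    def test_alpha_one_keeps_all_suprathreshold(self, rng):
        effs, vars_, mask = self._null_inputs(rng)
        g = fs.fit_group_level(effs, vars_, mask)
        null = fs.SignFlipNull(effs, vars_, mask)
        m = fs.cluster_correct(g, 0.05, 1.0, null, n_perm=100, seed=0)
        from scipy.stats import norm
        np.testing.assert_array_equal(
            m.mask, (g.data > norm.isf(0.05)) & mask)

    def test_empty_input_warns_not_raises(self, rng):
        effs, vars_, mask = self._null_inputs(rng)
        g = fs.fit_group_level(effs, vars_, mask)
        g.data[:] = 0.0
        null = fs.SignFlipNull(effs, vars_, mask)
        with pytest.warns(UserWarning, match="no suprathreshold"):
            m = fs.cluster_correct(g, 0.001, 0.05, null, n_perm=100, seed=0)
        assert m.n_voxels == 0

    def test_n_perm_floor(self, rng):
        effs, vars_, mask = self._null_inputs(rng)
        g = fs.fit_group_level(effs, vars_, mask)
        null = fs.SignFlipNull(effs, vars_, mask)
        with pytest.raises(ParameterError):
            fs.cluster_correct(g, 0.01, 0.05, null, n_perm=50)


def _dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestMaskPipelines:
    def test_dsa_mask_overlaps_truth(self, small_cohort):
        m = fs.make_dsa_mask(small_cohort, n_perm=150, seed=0)
        assert _dice(m.mask, small_cohort.truth.w_true_dsa != 0) > 0.3
        assert np.all(small_cohort.truth.brain_mask[m.mask])

    def test_dmr_mask_overlaps_truth(self, small_cohort):
        m = fs.make_dmr_mask(small_cohort, n_perm=150, seed=0)
        assert _dice(m.mask, small_cohort.truth.w_true_dmr != 0) > 0.3
        assert np.all(small_cohort.truth.brain_mask[m.mask])

    def test_null_rt_coupling_gives_near_empty_mask(self):
        """Without attention-RT coupling the RT-modulation contrast is null;
        the corrected mask should be (near-)empty in most replicates."""
        empty = 0
        reps = 10
        for rep in range(reps):
            params = bs.CohortParams(n_subjects=5, shape=(12, 12, 8),
                                     snr=1.5, seed=300 + rep,
                                     rt_coupling=0.0, tasks=("stroop",))
            coh = bs.simulate_cohort(params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fs.make_dsa_mask(coh, n_perm=150, seed=rep)
            brain_n = coh.truth.brain_mask.sum()
            empty += m.n_voxels <= 0.01 * brain_n
        assert empty >= 0.8 * reps

    def test_picture_only_signal_starves_conjunction(self):
        """If the representation pattern is expressed during pictures but
        not stories, the picture-AND-story conjunction mask is near-empty."""
        params = bs.CohortParams(n_subjects=6, shape=(12, 12, 8), snr=1.5,
                                 seed=77, dmr_modalities=("picture",),
                                 tasks=("representation",))
        coh = bs.simulate_cohort(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fs.make_dmr_mask(coh, n_perm=150, seed=0)
        assert m.n_voxels <= 0.01 * coh.truth.brain_mask.sum()

    def test_mask_provenance_round_trip(self, small_cohort, tmp_path):
        m = fs.make_dsa_mask(small_cohort, n_perm=150, seed=0)
        m.save(tmp_path / "mask.nii.gz")
        back = fs.FeatureMask.load(tmp_path / "mask.nii.gz")
        np.testing.assert_array_equal(back.mask, m.mask)
        assert back.provenance == m.provenance
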