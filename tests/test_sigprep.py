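import itertools

import numpy as np
import pytest

from rivaldec import sigprep
from rivaldec.paradigm import bnr_design, br_design, build_design, condition_labels
from rivaldec.simgen import SimConfig, canonical_hrf, simulate_bnr
from rivaldec.localizer import localize


class TestDetrendPoly:
    def test_exact_cubic_reduces_to_zero(self):
        t = np.arange(50, dtype=float)
        series = 3 - 0.5 * t + 0.01 * t ** 2 - 1e-4 * t ** 3
        np.testing.assert_allclose(sigprep.detrend_poly(series, 3), 0.0, atol=1e-9)

    def test_constant_series_goes_to_zero(self):
        np.testing.assert_allclose(sigprep.detrend_poly(np.full(20, 9.0), 2), 0.0, atol=1e-9)

    def test_projection_reduces_variance(self, rng):
        t = np.linspace(0, 1, 200)
        series = 5 * t ** 3 + rng.normal(size=200)
        out = sigprep.detrend_poly(series, 3)
        assert out.var() < series.var()

    def test_keep_mean_preserves_temporal_mean(self, rng):
        series = 100 + rng.normal(size=50)
        out = sigprep.detrend_poly(series, 3, keep_mean=True)
        assert out.mean() == pytest.approx(series.mean())

    def test_idempotent(self, rng):
        series = rng.normal(size=60)
        once = sigprep.detrend_poly(series, 3)
        twice = sigprep.detrend_poly(once, 3)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sigprep.detrend_poly(np.ones(4), 3)


def _best_two_partition_ss(X):
    """Exhaustive minimum within-cluster sum of squares over all 2-partitions."""
    n = X.shape[0]
    best = np.inf
    for assign in itertools.product([0, 1], repeat=n):
        assign = np.array(assign)
        if assign.sum() in (0, n):
            continue
        ss = 0.0
        for lab in (0, 1):
            grp = X[assign == lab]
            ss += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, ss)
    return best


class TestKmeansSelectVoxels:
    def test_signal_voxels_separated_from_noise(self, rng):
        hrf = canonical_hrf(1.0)
        box = np.convolve(np.tile([1.0] * 10 + [0.0] * 10, 5), hrf)[:100]
        signal = box - box.mean()
        X = np.vstack([signal + 0.05 * rng.normal(size=100) for _ in range(3)]
                      + [rng.normal(size=100) for _ in range(3)])
        retained, _ = sigprep.kmeans_select_voxels(X, seed=1)
        assert sorted(retained) == [0, 1, 2]

    def test_identical_voxels_all_retained_with_warning(self):
        X = np.tile(np.arange(10.0), (2, 1))
        with pytest.warns(UserWarning):
            retained, _ = sigprep.kmeans_select_voxels(X)
        assert len(retained) == 2

    def test_objective_matches_exhaustive_partition(self, rng):
        # enough restarts make Lloyd's algorithm attain the global optimum
        # on instances this small
        X = rng.normal(size=(8, 12))
        _, inertia = sigprep.kmeans_select_voxels(X, seed=0, n_init=200)
        assert inertia == pytest.approx(_best_two_partition_ss(X), rel=1e-6)

    def test_single_voxel_rejected(self):
        with pytest.raises(ValueError):
            sigprep.kmeans_select_voxels(np.ones((1, 10)))


class TestPointwiseOps:
    def test_percent_signal_change_example(self):
        np.testing.assert_allclose(
            sigprep.percent_signal_change(np.array([100.0, 110.0, 90.0])), [0, 10, -10]
        )

    def test_percent_signal_change_zero_mean_after(self, rng):
        out = sigprep.percent_signal_change(1000 + rng.normal(size=50))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)

    def test_percent_signal_change_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            sigprep.percent_signal_change(np.array([1.0, -1.0]))

    def test_global_subtract(self):
        np.testing.assert_allclose(
            sigprep.global_subtract(np.array([1.0, 2.0]), np.array([0.5, 0.5])), [0.5, 1.5]
        )
        with pytest.raises(ValueError):
            sigprep.global_subtract(np.ones(3), np.ones(4))

    @pytest.mark.parametrize("tr,delay,shift", [(3.0, 6.0, 2), (1.0, 6.0, 6), (1.0, 0.0, 0)])
    def test_bold_shift_sample_count(self, tr, delay, shift):
        x = np.arange(20.0)
        out = sigprep.bold_shift(x, tr, delay)
        if shift == 0:
            np.testing.assert_array_equal(out, x)
        else:
            np.testing.assert_array_equal(out[:-shift], x[shift:])
            np.testing.assert_array_equal(out[-shift:], x[-1])

    def test_bold_shift_aligns_lagged_response_with_labels(self):
        # a response lagging its driver by 6 s realigns under tr=1, delay=6
        driver = np.tile([1.0] * 10 + [0.0] * 10, 3)
        lagged = np.roll(driver, 6)
        realigned = sigprep.bold_shift(lagged, 1.0, 6.0)
        assert np.corrcoef(realigned, driver)[0, 1] > 0.9
        assert np.corrcoef(lagged, driver)[0, 1] < 0.5

    def test_bold_shift_overlong_rejected(self):
        with pytest.raises(ValueError):
            sigprep.bold_shift(np.ones(3), 1.0, 10.0)

    def test_split_task_rest_counts(self):
        br, bnr = br_design(), bnr_design()
        t, r = sigprep.split_task_rest(np.arange(600.0), br)
        assert (len(t), len(r)) == (300, 300)
        t, r = sigprep.split_task_rest(np.arange(200.0), bnr)
        assert (len(t), len(r)) == (100, 100)
        rest_only = build_design("BNR", 3.0, [("rest", 0, 30)])
        t, r = sigprep.split_task_rest(np.arange(10.0), rest_only)
        assert len(t) == 0 and len(r) == 10


class TestPrepareInputs:
    def _bnr_tcs(self, noise_pct=0.0, seed=0):
        regions = SimConfig().regions
        cfg = SimConfig(noise_sd_pct=noise_pct, region_noise_sd_pct=0.0, seed=seed)
        run = simulate_bnr(cfg)
        mats = [run.volumes[run.masks[r.label]] for r in regions]
        brain = run.volumes.reshape(-1, run.design.n_volumes).mean(axis=0)
        return sigprep.RoiTimecourses(
            roi_matrices=mats, roi_names=[r.label for r in regions],
            brain_mean=brain, tr=run.design.tr, design=run.design,
        )

    def test_face_column_signs_follow_conditions(self):
        prep = sigprep.prepare_inputs(self._bnr_tcs(), "BNR")
        face_rows = prep.target_matrix[:, 0] == 1
        ffa = prep.task_matrix[:, 0]  # FFA_r column
        assert ffa[face_rows].mean() > 0 > ffa[~face_rows].mean()

    def test_bnr_skips_kmeans_and_emits_one_hot_targets(self):
        prep = sigprep.prepare_inputs(self._bnr_tcs(), "BNR")
        for name, idx in prep.retained_voxels.items():
            assert len(idx) == len(np.argwhere(simulate_bnr(SimConfig()).masks[name]))
        assert prep.target_matrix.shape == (100, 2)
        np.testing.assert_array_equal(prep.target_matrix.sum(axis=1), 1.0)

    def test_task_columns_zero_mean(self, fitted_decoder):
        model, _ = fitted_decoder
        for prep in (model.bnr_inputs, model.br_inputs):
            np.testing.assert_allclose(prep.task_matrix.mean(axis=0), 0.0, atol=1e-8)

    def test_scale_invariance_of_prepared_matrix(self):
        tcs = self._bnr_tcs(noise_pct=0.5, seed=4)
        scaled = sigprep.RoiTimecourses(
            roi_matrices=[3.0 * m for m in tcs.roi_matrices],
            roi_names=tcs.roi_names, brain_mean=3.0 * tcs.brain_mean,
            tr=tcs.tr, design=tcs.design,
        )
        a = sigprep.prepare_inputs(tcs, "BNR").task_matrix
        b = sigprep.prepare_inputs(scaled, "BNR").task_matrix
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_constant_input_gives_all_zeros(self):
        design = build_design("BNR", 3.0, [("face", 0, 60), ("rest", 60, 60)])
        const = np.full((3, design.n_volumes), 500.0)
        tcs = sigprep.RoiTimecourses([const], ["r0"], np.full(design.n_volumes, 500.0),
                                     3.0, design)
        prep = sigprep.prepare_inputs(tcs, "BNR")
        np.testing.assert_allclose(prep.task_matrix, 0.0, atol=1e-9)

    def test_extract_timecourses_applies_slice_offset(self, synthetic_subject):
        _, bnr, br, _, _ = synthetic_subject
        roiset, _ = localize(bnr.volumes, bnr.design)
        tcs_bnr = sigprep.extract_timecourses(bnr.volumes, roiset, bnr.design, z_offset=0)
        tcs_br = sigprep.extract_timecourses(br.volumes, roiset, br.design, z_offset=7)
        assert len(tcs_br.roi_matrices) == len(tcs_bnr.roi_matrices)
        for a, b in zip(tcs_br.roi_matrices, tcs_bnr.roi_matrices):
            assert a.shape[0] == b.shape[0]  # same voxel counts across runs
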