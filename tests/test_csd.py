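"""CSD estimation: smoothing, differentiation, sink detection."""

import numpy as np
import pytest

from laminarid.core_io import (
    AnalysisConfig,
    DegenerateInputError,
    EventTrain,
    LfpRecording,
    ProbeLayout,
)
from laminarid.csd import (
    CsdResult,
    average_evoked_lfp,
    chunk_average,
    collapse_columns,
    compute_csd,
    detect_input_layer,
    interpolate_csd,
    second_spatial_derivative,
    smooth_gaussian_2d,
)
from laminarid.synthetic import GroundTruth, simulate_session


class TestAverageEvoked:
    def test_identical_trials(self, rng):
        trial = rng.normal(size=(4, 30))
        epochs = np.stack([trial] * 5)
        np.testing.assert_allclose(average_evoked_lfp(epochs), trial)

    def test_antisymmetric_pair_cancels(self, rng):
        v = rng.normal(size=(4, 30))
        assert not average_evoked_lfp(np.stack([v, -v])).any()

    def test_noise_shrinks_as_sqrt_trials(self, rng):
        signal = np.sin(np.linspace(0, 4 * np.pi, 200))[None, :]

        def rms_err(n):
            epochs = signal + rng.normal(size=(n, 1, 200))
            return np.sqrt(((average_evoked_lfp(epochs) - signal) ** 2).mean())

        # expected ratio sqrt(10/160) ~ 0.25; allow wide stochastic margin
        assert rms_err(160) < 0.6 * rms_err(10)


class TestCollapseColumns:
    def test_identical_columns(self, rng):
        layout = ProbeLayout.default(8)
        per_row = rng.normal(size=(4, 20))
        mat = per_row[layout.row_index]
        rows, depths = collapse_columns(mat, layout)
        np.testing.assert_allclose(rows, per_row)
        np.testing.assert_allclose(depths, [0, 20, 40, 60])

    def test_single_column_identity(self, rng):
        layout = ProbeLayout(channel_ids=range(5), x_um=np.zeros(5),
                             depth_um=np.arange(5) * 20.0, n_columns=1)
        mat = rng.normal(size=(5, 7))
        rows, _ = collapse_columns(mat, layout)
        np.testing.assert_allclose(rows, mat)

    def test_column_offset_halved(self, rng):
        layout = ProbeLayout.default(8)
        per_row = rng.normal(size=(4, 10))
        mat = per_row[layout.row_index].copy()
        mat[layout.x_um > 0] += 6.0  # constant offset on column 2
        rows, _ = collapse_columns(mat, layout)
        np.testing.assert_allclose(rows, per_row + 3.0)


class TestSmoothGaussian2d:
    def test_constant_unchanged(self):
        mat = np.full((20, 40), 2.5)
        out = smooth_gaussian_2d(mat, 9, 5.0, 2.0)
        np.testing.assert_allclose(out, mat, atol=1e-12)

    def test_impulse_yields_kernel(self):
        mat = np.zeros((41, 41))
        mat[20, 20] = 1.0
        out = smooth_gaussian_2d(mat, 11, 11.0, 2.0)
        assert out[20, 20] == out.max()
        assert out.sum() == pytest.approx(1.0)
        # symmetric in both axes around the impulse
        np.testing.assert_allclose(out, out[::-1, :], atol=1e-12)
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-12)

    def test_matches_dense_convolution(self, rng):
        """Separable implementation vs a direct dense 2D convolution."""
        mat = rng.normal(size=(8, 8))
        window, sd = 5, 1.3
        half = 3  # ceil(5/2)
        x = np.arange(-half, half + 1, dtype=float)
        k1 = np.exp(-0.5 * (x / sd) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(mat, half, mode="symmetric")
        expected = np.empty_like(mat)
        for i in range(8):
            for j in range(8):
                patch = padded[i : i + 2 * half + 1, j : j + 2 * half + 1]
                expected[i, j] = (patch * kernel[::-1, ::-1]).sum()
        out = smooth_gaussian_2d(mat, window, float(window), sd)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_window_larger_than_matrix_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian_2d(np.zeros((4, 10)), 9, 5.0, 2.0)


class TestChunkAverage:
    def test_group_count(self, rng):
        grouped, _ = chunk_average(rng.normal(size=(20, 5)), 10)
        assert grouped.shape == (2, 5)

    def test_group_size_one_identity(self, rng):
        mat = rng.normal(size=(7, 4))
        grouped, _ = chunk_average(mat, 1)
        np.testing.assert_allclose(grouped, mat)

    def test_groups_are_member_means(self, rng):
        mat = rng.normal(size=(30, 50))
        grouped, centers = chunk_average(mat, 10, np.arange(30) * 10.0)
        for g in range(3):
            np.testing.assert_allclose(grouped[g], mat[10 * g : 10 * g + 10].mean(0))
        np.testing.assert_allclose(centers, [45.0, 145.0, 245.0])

    def test_trailing_partial_group_dropped(self, rng):
        grouped, _ = chunk_average(rng.normal(size=(25, 5)), 10)
        assert grouped.shape[0] == 2


class TestSecondSpatialDerivative:
    def test_linear_profile_vanishes(self):
        v = np.outer(np.arange(10.0), np.ones(5)) * 3.0 + 2.0
        assert np.abs(second_spatial_derivative(v, 20.0)).max() < 1e-12

    def test_quadratic_profile_constant(self):
        z = np.arange(10.0)
        v = np.outer(z**2, np.ones(3))
        out = second_spatial_derivative(v, 1.0)
        np.testing.assert_allclose(out, -2.0)

    def test_matches_bruteforce_loop(self, rng):
        mat = rng.normal(size=(10, 5))
        h = 17.0
        expected = np.empty((8, 5))
        for i in range(1, 9):
            for j in range(5):
                expected[i - 1, j] = -(mat[i - 1, j] - 2 * mat[i, j] + mat[i + 1, j]) / h**2
        np.testing.assert_allclose(second_spatial_derivative(mat, h), expected,
                                   atol=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(DegenerateInputError):
            second_spatial_derivative(np.zeros((2, 5)), 20.0)


class TestComputeCsd:
    def _zero_rec(self):
        layout = ProbeLayout.default(64)
        return LfpRecording(data=np.zeros((64, 5000)), fs_hz=1000.0, layout=layout)

    def test_zero_recording_gives_zero_csd(self):
        cfg = AnalysisConfig()
        events = EventTrain([1.0, 2.0, 3.0])
        for method in ("gaussian", "chunk"):
            res = compute_csd(self._zero_rec(), events, cfg, method=method)
            assert not res.csd.any()
            assert detect_input_layer(res, cfg.response_window_s) is None

    def test_linearity_of_pipeline(self, rng):
        layout = ProbeLayout.default(32)
        events = EventTrain([1.0, 2.0])
        cfg = AnalysisConfig(smooth_window_ch=16)
        a = rng.normal(size=(32, 4000))
        b = rng.normal(size=(32, 4000))
        mk = lambda d: LfpRecording(data=d, fs_hz=1000.0, layout=layout)
        for method in ("gaussian", "chunk"):
            ra = compute_csd(mk(a), events, cfg, method=method)
            rb = compute_csd(mk(b), events, cfg, method=method)
            rab = compute_csd(mk(a + b), events, cfg, method=method)
            np.testing.assert_allclose(rab.csd, ra.csd + rb.csd, atol=1e-8)

    def test_noiseless_session_sink_location(self):
        """With all noise terms off, the CSD minimum sits at the planted
        sink depth to within one depth row for both smoothing variants."""
        gt = GroundTruth(seed=0, sink_depth_um=300.0, sink_width_um=80.0,
                         flip_depth_um=340.0, osc_amp_uv=0.0, noise_amp_uv=0.0,
                         channel_noise_uv=0.0, n_units=5)
        session = simulate_session(gt, n_trials=5, iti_s=2.0, duration_s=15.0,
                                   n_channels=64)
        cfg = AnalysisConfig()
        for method, pitch in (("gaussian", 20.0), ("chunk", 100.0)):
            res = compute_csd(session.rec, session.events, cfg, method=method)
            i_min = np.unravel_index(res.csd.argmin(), res.csd.shape)[0]
            assert abs(res.depth_axis_um[i_min] - gt.sink_depth_um) <= pitch + 1e-9

    def test_sink_negative_convention(self):
        """An LFP profile locally negative-going in depth yields CSD < 0."""
        layout = ProbeLayout.default(16)
        rows = layout.row_depths_um
        bump = -np.exp(-0.5 * ((rows - 70.0) / 30.0) ** 2)  # local minimum at 70 um
        data = np.zeros((16, 3000))
        sl = slice(1000, 1100)
        data[:, sl] = bump[layout.row_index][:, None]
        rec = LfpRecording(data=data, fs_hz=1000.0, layout=layout)
        res = compute_csd(rec, EventTrain([1.0]), AnalysisConfig(smooth_window_ch=8),
                          method="gaussian")
        j = np.argmin(np.abs(res.time_axis_s - 0.05))
        i = np.argmin(np.abs(res.depth_axis_um - 70.0))
        assert res.csd[i, j] < 0


class TestDetectInputLayer:
    def _result(self, csd, depths, t):
        return CsdResult(csd=csd, depth_axis_um=depths, time_axis_s=t,
                         method="chunk")

    def test_zero_csd_no_sink(self):
        t = np.arange(-100, 250) / 1000.0
        res = self._result(np.zeros((10, t.size)), np.arange(10) * 100.0, t)
        assert detect_input_layer(res) is None

    def test_earliest_of_two_sinks_wins(self, rng):
        t = np.arange(-100, 250) / 1000.0
        depths = np.arange(20) * 100.0
        csd = 0.01 * rng.normal(size=(20, t.size))
        shape = lambda onset: np.clip((t - onset) * 50, 0, 1)
        csd[15] -= 5.0 * shape(0.030)   # deep sink, earliest
        csd[8] -= 5.0 * shape(0.045)    # middle sink, later but same size
        est = detect_input_layer(self._result(csd, depths, t), threshold_k=4.0)
        assert est.onset_s == pytest.approx(0.030, abs=0.005)
        assert abs(est.depth_um - 1500.0) < 100.0

    def test_requires_baseline(self):
        t = np.arange(0, 250) / 1000.0
        res = self._result(np.zeros((5, t.size)), np.arange(5) * 100.0, t)
        with pytest.raises(ValueError, match="baseline"):
            detect_input_layer(res)


class TestInterpolateCsd:
    def _result(self, mat):
        return CsdResult(csd=mat, depth_axis_um=np.arange(mat.shape[0]) * 100.0,
                         time_axis_s=np.arange(mat.shape[1]) / 1000.0,
                         method="chunk")

    def test_factor_one_identity(self, rng):
        res = self._result(rng.normal(size=(6, 8)))
        out, d, t = interpolate_csd(res, 1)
        np.testing.assert_array_equal(out, res.csd)

    def test_bilinear_ramp_reproduced(self):
        d = np.arange(6.0)
        tt = np.arange(8.0)
        ramp = np.add.outer(2.0 * d, 3.0 * tt)
        res = self._result(ramp)
        out, dn, tn = interpolate_csd(res, 4)
        expected = 2.0 * (dn[:, None] / 100.0) + 3.0 * (tn[None, :] * 1000.0)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_original_nodes_preserved(self, rng):
        res = self._result(rng.normal(size=(7, 9)))
        out, _, _ = interpolate_csd(res, 3)
        np.testing.assert_allclose(out[::3, ::3], res.csd, atol=1e-9)

    def test_bad_factor(self, rng):
        with pytest.raises(ValueError):
            interpolate_csd(self._result(rng.normal(size=(5, 5))), 0)
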