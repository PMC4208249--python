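"""Smoothing, baseline normalization and autoscaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosekit import preprocess
from enosekit.containers import PreprocessingError, SensorArrayRecording
from oracles import sg_smooth_window_fits


def _recording(resistance, onset=100, end=650):
    return SensorArrayRecording(
        resistance=resistance, stimulus_onset=onset, stimulus_end=end
    )


class TestSavitzkyGolay:
    def test_reproduces_quadratic_exactly(self):
        t = np.linspace(0, 1, 400)
        q = 3 * t**2 - 2 * t + 1
        out = preprocess.savitzky_golay_smooth(q, poly_order=2, frame_size=11)
        assert np.allclose(out, q, atol=1e-9)

    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_reproduces_all_polynomials_up_to_fit_degree(self, degree):
        t = np.linspace(-2, 2, 300)
        poly = sum((i + 1) * t**d for i, d in enumerate(range(degree + 1)))
        out = preprocess.savitzky_golay_smooth(poly, 2, 101)
        interior = slice(50, -50)
        assert np.allclose(out[interior], poly[interior], atol=1e-9)

    def test_default_parameters_on_full_length_recording(self):
        sig = np.random.default_rng(0).normal(size=750)
        out = preprocess.savitzky_golay_smooth(sig)  # k=2, f=101
        assert out.shape == sig.shape

    def test_noise_variance_matches_window_fit_oracle(self, rng):
        # variance reduction factor of the LS fit: var_out = sigma^2 sum c_j^2,
        # measured against an independent per-window fit oracle
        sigma = 0.7
        sig = rng.normal(0.0, sigma, size=10_000)
        ours = preprocess.savitzky_golay_smooth(sig, 2, 31)
        oracle = sg_smooth_window_fits(sig, 2, 31)
        interior = slice(15, -15)
        assert np.allclose(ours[interior], oracle[interior], atol=1e-8)
        var_ratio = ours[interior].var() / sigma**2
        # analytic factor for k=2: coefficients of the projection row
        assert var_ratio == pytest.approx(oracle[interior].var() / sigma**2,
                                          rel=0.05)

    def test_matrix_input_smooths_each_sensor(self):
        t = np.linspace(0, 1, 200)
        grid = np.column_stack([t**2, 2 * t + 1])
        out = preprocess.savitzky_golay_smooth(grid, 2, 21)
        assert np.allclose(out[20:-20], grid[20:-20], atol=1e-9)

    @pytest.mark.parametrize(
        "order,frame,n", [(2, 10, 100), (11, 11, 100), (2, 101, 50)]
    )
    def test_invalid_parameters_rejected(self, order, frame, n):
        with pytest.raises(PreprocessingError):
            preprocess.savitzky_golay_smooth(np.zeros(n), order, frame)


class TestPercentResistance:
    def test_flat_signal_gives_zero(self):
        rec = _recording(np.full((200, 3), 50.0), onset=50, end=150)
        assert np.allclose(preprocess.percent_resistance(rec), 0.0)

    def test_analytic_values(self):
        # R0 = 100 during baseline; Rs = 200 -> +50%; Rs = 80 -> -25%
        r = np.full((200, 2), 100.0)
        r[100:, 0] = 200.0
        r[100:, 1] = 80.0
        rec = _recording(r, onset=100, end=200)
        out = preprocess.percent_resistance(rec)
        assert out[150, 0] == pytest.approx(50.0)
        assert out[150, 1] == pytest.approx(-25.0)

    def test_sign_agrees_with_fractional_response(self, small_dataset):
        recordings, _, _ = small_dataset
        rec = preprocess.smooth_recording(recordings[0])
        pct = preprocess.percent_resistance(rec)
        frac = preprocess.fractional_response(rec)
        steady = pct[rec.stimulus_end - 100:rec.stimulus_end].mean(axis=0)
        responding = np.abs(frac) > 1e-3
        assert np.all(np.sign(steady[responding]) == np.sign(frac[responding]))


class TestFractionalResponse:
    def test_flat_signal_gives_zero(self):
        rec = _recording(np.full((300, 4), 123.0), onset=100, end=250)
        assert np.allclose(preprocess.fractional_response(rec), 0.0)

    def test_analytic_plateau(self):
        r = np.full((300, 1), 100.0)
        r[100:, 0] = 150.0
        rec = _recording(r, onset=100, end=250)
        assert preprocess.fractional_response(rec)[0] == pytest.approx(0.5)

    def test_recovers_programmed_amplitude_from_noiseless_simulation(self):
        from enosekit import simulate

        cfg = simulate.dataset1_config(
            seed=3, n_sensors=64, noise_sd=0.0, dead_fraction=0.0,
            concentration_jitter=0.0, tau_rise=5.0,
        )
        rec = simulate.simulate_recording(cfg, mixture_index=0)
        mixture = cfg.mixtures[0]
        expected = np.array([
            sum(cfg.sensitivity(m, a) * ppm
                for a, ppm in mixture.concentrations_ppm.items())
            for m in cfg.material_map
        ])
        sm = preprocess.smooth_recording(rec)
        # with tau_rise = 5 s the plateau is fully developed well before the
        # steady window; keep both windows >= half a smoothing frame away
        # from the stimulus transients so the filter sees flat signal
        got = preprocess.fractional_response(
            sm, baseline_window=(0, 50), steady_window=(500, 600)
        )
        assert np.allclose(got, expected, atol=1e-6)

    def test_overlapping_windows_rejected(self):
        rec = _recording(np.full((300, 2), 10.0), onset=100, end=250)
        with pytest.raises(PreprocessingError):
            preprocess.fractional_response(
                rec, baseline_window=(0, 150), steady_window=(100, 200)
            )


class TestAutoscale:
    def test_constant_column_masked_to_zero(self):
        m = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        rm = preprocess.autoscale(m)
        assert rm.dead_mask.tolist() == [False, True]
        assert np.allclose(rm.values[:, 1], 0.0)

    def test_two_point_column_is_plus_minus_one(self):
        rm = preprocess.autoscale(np.array([[2.0], [8.0]]))
        assert np.allclose(np.sort(rm.values[:, 0]), [-1.0, 1.0])

    def test_idempotent_on_scaled_matrix(self, rng):
        m = rng.normal(size=(10, 6))
        once = preprocess.autoscale(m).values
        twice = preprocess.autoscale(once).values
        assert np.allclose(once, twice, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(PreprocessingError):
            preprocess.autoscale(np.ones((1, 3)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_mean_zero_unit_variance_invariant(self, seed):
        g = np.random.default_rng(seed)
        m = g.normal(size=(g.integers(2, 20), g.integers(1, 30)))
        rm = preprocess.autoscale(m)
        live = ~rm.dead_mask
        assert np.all(np.abs(rm.values[:, live].mean(axis=0)) < 1e-9)
        assert np.all(np.abs(rm.values[:, live].var(axis=0) - 1.0) < 1e-6)
        assert np.allclose(rm.values[:, rm.dead_mask], 0.0)

    def test_apply_reproduces_training_rows_and_masks_held_out(self, rng):
        m = rng.normal(size=(8, 5))
        m[:, 2] = 4.0  # dead column
        rm = preprocess.autoscale(m)
        assert np.allclose(rm.apply(m), rm.values)
        held_out = rng.normal(size=(3, 5))
        out = rm.apply(held_out)
        assert np.allclose(out[:, 2], 0.0)
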