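import numpy as np
import pytest
from hypothesis import given, strategies as st

from gradcpt import (
    compute_vtc,
    fluctuation_frequency,
    interpolate_rts,
    smooth_vtc,
    vtc_from_table,
)
from gradcpt.vtc import FWHM_TO_SIGMA, amplitude_spectrum

from conftest import make_trial_table


class TestInterpolation:
    def test_interior_gap_linear_midpoint(self):
        table = make_trial_table([0.5, None, 0.7])
        out = interpolate_rts(table)
        assert out["response_time"].tolist() == pytest.approx([0.5, 0.6, 0.7])
        assert out["rt_source"].tolist() == ["observed", "interpolated", "observed"]

    def test_leading_gap_takes_nearest_value(self):
        table = make_trial_table([None, 0.5, 0.7])
        out = interpolate_rts(table)
        assert out.loc[0, "response_time"] == pytest.approx(0.5)

    def test_trailing_gap_takes_nearest_value(self):
        table = make_trial_table([0.5, 0.7, None])
        out = interpolate_rts(table)
        assert out.loc[2, "response_time"] == pytest.approx(0.7)

    def test_all_present_unchanged(self):
        table = make_trial_table([0.5, 0.6, 0.7])
        out = interpolate_rts(table)
        assert out["response_time"].tolist() == [0.5, 0.6, 0.7]
        assert (out["rt_source"] == "observed").all()

    def test_too_few_observed_rejected(self):
        with pytest.raises(ValueError):
            interpolate_rts(make_trial_table([0.5, None, None]))


class TestZScoring:
    def test_simple_series(self):
        assert compute_vtc([1.0, 2.0, 3.0]) == pytest.approx([1.0, 0.0, 1.0])

    @given(
        st.lists(st.floats(0.1, 3.0), min_size=5, max_size=50),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, rts, a, b):
        rts = np.asarray(rts)
        if rts.std(ddof=1) < 1e-6:
            return
        base = compute_vtc(rts)
        assert compute_vtc(a * rts + b) == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            compute_vtc([0.5, 0.5, 0.5])

    def test_underlying_z_is_standardized(self):
        rng = np.random.default_rng(0)
        rts = rng.normal(0.6, 0.1, 400)
        z = (rts - rts.mean()) / rts.std(ddof=1)
        assert compute_vtc(rts) == pytest.approx(np.abs(z))


class TestSmoothing:
    def test_fwhm_to_sigma_conversion(self):
        assert 7.0 * FWHM_TO_SIGMA == pytest.approx(2.973, abs=1e-3)
        assert 7.0 * FWHM_TO_SIGMA / 0.8 == pytest.approx(3.716, abs=1e-3)

    def test_constant_input_unchanged_everywhere(self):
        out = smooth_vtc(np.full(100, 1.3), soa=0.8)
        assert out == pytest.approx(np.full(100, 1.3), abs=1e-12)

    def test_impulse_yields_kernel_peaked_at_impulse(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = smooth_vtc(x, soa=0.8)
        assert np.argmax(out) == 50
        sigma = 7.0 * FWHM_TO_SIGMA / 0.8
        expected_ratio = np.exp(-0.5 / sigma**2)
        assert out[51] / out[50] == pytest.approx(expected_ratio, rel=1e-6)

    def test_interior_dominated_mean_conservation(self):
        """A normalized kernel conserves the mean to 1e-10 when the series
        mass sits far enough from the edges for renormalization to be
        inactive."""
        rng = np.random.default_rng(1)
        x = np.zeros(500)
        x[50:-50] = np.abs(rng.normal(size=400))
        out = smooth_vtc(x, soa=0.8)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-10)

    def test_gaussian_transfer_function(self):
        """Gain above 0.8 at 0.032 Hz, below 0.05 at 0.2 Hz, per the
        analytic Gaussian transfer e^(-2 pi^2 sigma^2 f^2)."""
        soa = 0.8
        n = 4000
        t = np.arange(n) * soa
        for f, lo, hi in [(0.032, 0.8, 1.0), (0.2, 0.0, 0.05)]:
            x = np.sin(2 * np.pi * f * t)
            y = smooth_vtc(x, soa=soa)
            gain = np.sqrt(np.mean(y[100:-100] ** 2) / np.mean(x[100:-100] ** 2))
            sigma_s = 7.0 * FWHM_TO_SIGMA
            analytic = np.exp(-2 * np.pi**2 * sigma_s**2 * f**2)
            assert lo <= gain <= hi
            assert gain == pytest.approx(analytic, abs=0.02)

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_vtc(np.ones(10), soa=0.8, fwhm=0.0)


class TestFluctuationFrequency:
    def test_pure_sinusoid_at_bin_frequency_recovered_exactly(self):
        soa, n = 0.8, 500
        k = 13  # bin frequency k/(n*soa) = 0.0325 Hz
        f_true = k / (n * soa)
        t = np.arange(n) * soa
        x = 1.0 + 0.3 * np.sin(2 * np.pi * f_true * t)
        assert fluctuation_frequency([x], soa) == pytest.approx(f_true, abs=1e-12)

    def test_band_restriction_preserves_contained_peak(self):
        soa, n = 0.8, 500
        t = np.arange(n) * soa
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 0.0325 * t)
        full = fluctuation_frequency([x], soa, band=(0.005, 0.10))
        narrow = fluctuation_frequency([x], soa, band=(0.02, 0.04))
        assert full == narrow

    def test_cross_run_averaging_beats_single_run_noise(self):
        rng = np.random.default_rng(3)
        soa, n, f_true = 0.8, 500, 0.0325
        t = np.arange(n) * soa
        runs = [
            1.0 + 0.1 * np.sin(2 * np.pi * f_true * t) + 0.3 * rng.normal(size=n)
            for _ in range(8)
        ]
        est = fluctuation_frequency(runs, soa)
        assert est == pytest.approx(f_true, abs=1.0 / (n * soa))

    @pytest.mark.parametrize("band", [(0.0001, 0.05), (0.005, 5.0)])
    def test_unresolvable_band_rejected(self, band):
        with pytest.raises(ValueError):
            fluctuation_frequency([np.ones(100) + np.arange(100) % 3], 0.8, band=band)

    def test_estimator_bias_below_one_bin(self):
        """Median |estimate - f0| over 50 simulated sessions stays within
        one frequency bin at modulation depth 0.6."""
        from gradcpt import ObserverParams, assign_presses, make_schedule, simulate_observer

        errors = []
        for seed in range(50):
            vtcs = []
            for k in range(2):
                s = make_schedule(400.0, 0.8, 0.1, seed=900 * seed + k)
                p = ObserverParams(mod_depth=0.6, f0=0.032, seed=7000 + 2 * seed + k)
                table = assign_presses(s, simulate_observer(s, p))
                vtcs.append(vtc_from_table(table, soa=0.8).smoothed_vtc)
            errors.append(abs(fluctuation_frequency(vtcs, 0.8) - 0.032))
        assert np.median(errors) <= 1.0 / 400.0


def test_vtc_from_table_pipeline(noisy_session):
    _, _, table = noisy_session
    sv = vtc_from_table(table, soa=0.8)
    assert sv.n_trials == len(table)
    assert np.all(sv.raw_vtc >= 0)
    assert len(sv.smoothed_vtc) == sv.n_trials
    # smoothed series has less high-frequency energy than the raw one
    f, a_raw = amplitude_spectrum(sv.raw_vtc, 0.8)
    _, a_sm = amplitude_spectrum(sv.smoothed_vtc, 0.8)
    high = f > 0.2
    assert a_sm[high].sum() < 0.2 * a_raw[high].sum()
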