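"""FFT-NLLS estimation, detrending and the peak-interval oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lwdclock.rhythm import (
    ARRHYTHMIC,
    NoPeaksError,
    detrend,
    fft_nlls,
    peak_period_oracle,
)


def cosine(t, A=5.0, tau=24.0, phi=3.0):
    return A * np.cos(2 * np.pi * (t - phi) / tau)


T72 = np.arange(0.0, 72.0, 1.0)
T120 = np.arange(0.0, 120.0, 1.0)


class TestDetrend:
    def test_linear_ramp_removed_exactly(self):
        y = 2.0 + 0.5 * T72
        r = detrend(T72, y, order=1)
        assert np.abs(r).max() < 1e-8 * np.ptp(y)

    def test_cosine_survives_ramp_removal(self):
        y = cosine(T120) + 0.3 * T120
        r = detrend(T120, y, order=1)
        amp = np.sqrt(2 * np.mean(r**2))  # RMS amplitude of a pure cosine
        assert amp == pytest.approx(5.0, rel=0.01)

    def test_order_zero_on_centred_series_is_identity(self):
        y = cosine(T72)
        y = y - y.mean()
        assert np.allclose(detrend(T72, y, order=0), y, atol=1e-12)

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError):
            detrend(T72, np.zeros_like(T72), order=5)


class TestFftNlls:
    def test_noiseless_cosine_recovered_exactly(self):
        est = fft_nlls(T120, cosine(T120), period_bounds=(15, 40))
        assert est.is_rhythmic
        assert abs(est.period - 24.0) < 0.01
        assert est.rae < 0.01
        assert est.amplitude == pytest.approx(5.0, rel=1e-3)
        assert est.phase == pytest.approx(3.0, abs=0.05)

    def test_noisy_cosine_recovery(self):
        rng = np.random.default_rng(42)
        y = cosine(T72) + rng.normal(0, 0.05, T72.size)
        est = fft_nlls(T72, y)
        assert est.is_rhythmic
        assert est.period == pytest.approx(24.0, abs=0.1)
        assert est.phase == pytest.approx(3.0, abs=0.2)
        assert est.rae < 0.1

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        y = 10.0 + cosine(T120) + rng.normal(0, 0.2, T120.size)
        a = fft_nlls(T120, y)
        b = fft_nlls(T120, 7.5 * y)
        assert b.amplitude == pytest.approx(7.5 * a.amplitude, rel=1e-6)
        assert b.period == pytest.approx(a.period, rel=1e-6)
        assert b.phase == pytest.approx(a.phase, rel=1e-6)
        assert b.rae == pytest.approx(a.rae, rel=1e-6)

    def test_time_shift_moves_phase_not_period(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.1, T120.size)
        a = fft_nlls(T120, cosine(T120) + noise)
        b = fft_nlls(T120, cosine(T120, phi=3.0 + 5.0) + noise)
        assert b.period == pytest.approx(a.period, abs=0.05)
        assert (b.phase - a.phase) % a.period == pytest.approx(5.0, abs=0.2)

    def test_window_selection(self):
        t = np.arange(0.0, 120.0, 1.0)
        y = cosine(t)
        est = fft_nlls(t, y, window=(48.0, 120.0))
        assert est.window == (48.0, 120.0)
        assert est.period == pytest.approx(24.0, abs=0.05)

    def test_short_window_rejected(self):
        t = np.arange(0.0, 48.0, 1.0)
        with pytest.raises(ValueError):
            fft_nlls(t, cosine(t), period_bounds=(15, 40))

    def test_nonuniform_sampling_rejected(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 120, 100))
        with pytest.raises(ValueError):
            fft_nlls(t, np.sin(t))

    def test_white_noise_specificity(self):
        # noise-only traces must be flagged arrhythmic nearly always
        rng = np.random.default_rng(11)
        n_arr = sum(
            fft_nlls(T72, rng.normal(0, 1.0, T72.size)).verdict == ARRHYTHMIC
            for _ in range(100)
        )
        assert n_arr >= 95


class TestPeakOracle:
    def test_cosine_period(self):
        t = np.arange(0.0, 120.0, 0.1)
        assert peak_period_oracle(t, cosine(t)) == pytest.approx(24.0, abs=0.05)

    def test_damping_leaves_peak_spacing(self):
        t = np.arange(0.0, 120.0, 0.1)
        y = np.exp(-t / 200.0) * np.cos(2 * np.pi * t / 24.0)
        assert peak_period_oracle(t, y) == pytest.approx(24.0, abs=0.1)

    def test_too_few_peaks(self):
        t = np.arange(0.0, 40.0, 0.1)
        with pytest.raises(NoPeaksError):
            peak_period_oracle(t, cosine(t))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    tau=st.floats(20.0, 28.0),
    phi=st.floats(0.0, 24.0),
    amp=st.floats(0.5, 20.0),
)
def test_parameter_recovery_property(tau, phi, amp):
    """Any circadian cosine within the search bounds is recovered."""
    t = np.arange(0.0, 120.0, 1.0)
    rng = np.random.default_rng(1234)
    y = amp * np.cos(2 * np.pi * (t - phi) / tau) + rng.normal(0, amp / 20, t.size)
    est = fft_nlls(t, y, period_bounds=(15, 40))
    assert est.is_rhythmic
    assert abs(est.period - tau) < 0.2
    assert est.amplitude == pytest.approx(amp, rel=0.1)
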