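import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dorsalstream import analysis
from dorsalstream.analysis import (
    ALPHA,
    BandDefinition,
    CoherenceCurve,
    Spectrum,
    band_mean_coherence,
    bandpass,
    coherence,
    peak_frequency,
    plv,
    ppc,
    welch_psd,
)

FS = 500.0


def sine(freq, seconds=60.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        x = sine(25.0)
        y = bandpass(x, FS, 3, 60)
        core = slice(2000, -2000)  # ignore edge transients
        assert np.max(np.abs(y[core])) == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_tone_attenuated(self):
        x = sine(1.0)
        y = bandpass(x, FS, 3, 60)
        assert np.max(np.abs(y[2000:-2000])) < 0.1

    def test_dc_removed(self):
        y = bandpass(np.full(30000, 5.0), FS, 3, 60)
        assert np.max(np.abs(y[2000:-2000])) < 1e-6

    def test_zero_net_phase(self):
        # forward-backward filtering leaves an in-band tone phase-aligned
        x = sine(20.0)
        y = bandpass(x, FS, 3, 60)
        core = slice(5000, 25000)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) - (len(x[core]) - 1)
        assert lag == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sine(10), FS, 3, 300)


class TestWelch:
    def test_tone_peak_on_grid(self):
        spec = welch_psd(sine(10.0), FS)
        assert spec.freqs[np.argmax(spec.values)] == pytest.approx(10.0, abs=0.25)
        assert spec.meta["seg_len"] == 2000  # 4 s -> 0.25 Hz resolution

    def test_parseval_scaling_of_tone(self):
        # the PSD integrates to the signal power (amp^2 / 2)
        spec = welch_psd(sine(10.0, seconds=120), FS)
        total = np.trapezoid(spec.values, spec.freqs)
        assert total == pytest.approx(0.5, rel=0.02)

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, int(600 * FS))
        spec = welch_psd(x, FS)
        sel = (spec.freqs >= 3) & (spec.freqs <= 60)
        level = spec.values[sel]
        # theoretical density: 2 * var / fs (one-sided)
        assert np.mean(level) == pytest.approx(2 / FS, rel=0.05)
        assert level.max() / level.min() < 2.0

    def test_series_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), FS)

    def test_power_nonnegative(self):
        spec = welch_psd(np.random.default_rng(1).normal(size=8000), FS)
        assert np.all(spec.values >= 0)


class TestCoherence:
    def test_identical_signals_fully_coherent(self):
        x = np.random.default_rng(2).normal(size=int(60 * FS))
        curve = coherence(x, x, FS)
        assert np.allclose(curve.values, 1.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, int(60 * FS)))
        a = coherence(x, y, FS)
        b = coherence(y, x, FS)
        assert np.allclose(a.values, b.values)
        assert np.all((a.values >= 0) & (a.values <= 1))

    def test_independent_noise_bias_is_inverse_segment_count(self):
        """E[coherence] of independent channels ~ 1/n_segments (Monte Carlo)."""
        rng = np.random.default_rng(4)
        means = []
        for _ in range(5):
            x, y = rng.normal(size=(2, int(240 * FS)))
            curve = coherence(x, y, FS)
            means.append(curve.values.mean())
        n_seg = curve.meta["n_segments"]
        assert np.mean(means) == pytest.approx(1.0 / n_seg, rel=0.35)

    def test_fewer_than_two_segments_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            coherence(np.zeros(2500), np.zeros(2500), FS)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coherence(np.zeros(5000), np.zeros(6000), FS)


class TestBandUtilities:
    def grid_curve(self, values):
        freqs = np.arange(0, len(values)) * 0.25
        return CoherenceCurve(freqs, np.asarray(values, float))

    def test_constant_curve_mean(self):
        curve = self.grid_curve([0.5] * 200)
        assert band_mean_coherence(curve, 10, 20) == 0.5

    def test_band_endpoints_inclusive(self):
        values = np.zeros(200)
        values[98:104] = 1.0  # 24.5 .. 25.75 Hz
        curve = self.grid_curve(values)
        # 24.5, 24.75, 25.0, 25.25 -> all four grid points equal 1
        assert band_mean_coherence(curve, 24.5, 25.25) == 1.0

    def test_empty_band_rejected(self):
        curve = self.grid_curve(np.ones(200))
        with pytest.raises(ValueError, match="overlap"):
            band_mean_coherence(curve, 60.1, 60.2)

    @given(st.integers(0, 6))
    def test_band_mean_monotone_under_domination(self, shift):
        rng = np.random.default_rng(shift)
        base = rng.uniform(0, 0.5, 200)
        hi = base + rng.uniform(0, 0.5, 200)
        lo_mean = band_mean_coherence(self.grid_curve(base), 5, 40)
        hi_mean = band_mean_coherence(self.grid_curve(hi), 5, 40)
        assert hi_mean >= lo_mean

    def test_peak_frequency_with_ties_prefers_lower(self):
        values = np.zeros(300)
        values[47] = 1.0   # 11.75 Hz
        spec = Spectrum(np.arange(300) * 0.25, values)
        assert peak_frequency(spec, 3, 60) == 11.75
        values[55] = 1.0   # tie at 13.75 Hz
        spec2 = Spectrum(np.arange(300) * 0.25, values)
        assert peak_frequency(spec2, 3, 60) == 11.75

    def test_peak_frequency_accepts_band_definition(self):
        values = np.zeros(300)
        values[40] = 2.0    # 10 Hz
        values[100] = 5.0   # 25 Hz, outside alpha
        spec = Spectrum(np.arange(300) * 0.25, values)
        assert peak_frequency(spec, ALPHA) == 10.0

    def test_band_definition_validation(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 12.0, 8.0)


class TestPhaseSynchrony:
    def test_identical_band_limited_signals(self):
        x = bandpass(np.random.default_rng(5).normal(size=int(30 * FS)), FS, 8, 12)
        assert plv(x, x) == pytest.approx(1.0)
        assert ppc(x, x) == pytest.approx(1.0)

    def test_constant_phase_lag_is_full_locking(self):
        x = sine(10.0, seconds=30)
        y = sine(10.0, seconds=30, phase=1.0)
        assert plv(x, y) == pytest.approx(1.0, abs=1e-3)

    def test_uniformly_drifting_phase_cancels(self):
        # 1 Hz frequency offset -> phase difference sweeps [0, 2pi) uniformly
        x = sine(10.0, seconds=30)
        y = sine(11.0, seconds=30)
        assert plv(x, y) < 0.05

    def test_independent_noise_near_zero_and_ppc_debiased(self):
        rng = np.random.default_rng(6)
        plvs, ppcs = [], []
        for _ in range(10):
            x = bandpass(rng.normal(size=int(20 * FS)), FS, 8, 12)
            y = bandpass(rng.normal(size=int(20 * FS)), FS, 8, 12)
            plvs.append(plv(x, y))
            ppcs.append(ppc(x, y))
        assert np.mean(plvs) < 0.1
        # PPC's expectation vanishes under independence; PLV's does not
        assert abs(np.mean(ppcs)) < np.mean(plvs) ** 2 + 5e-3

    def test_ppc_requires_two_samples(self):
        with pytest.raises(ValueError):
            ppc(np.ones(1), np.ones(1))
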