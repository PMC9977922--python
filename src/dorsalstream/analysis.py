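"""Filtering, spectral estimation, coherence and phase-synchrony metrics.

The analysis chain mirrors standard EEG practice for this kind of model
output: a zero-phase band-pass (order-5 Butterworth, 3-60 Hz) followed by
Welch's averaged modified periodogram with a Hamming window and 50%
overlap.  The default segment length of 4 s gives 0.25 Hz resolution at
the model's 500 Hz sampling rate, which is the grid every reported peak
frequency lies on.

Coherence between two channels is the magnitude-squared coherence
``lambda_xy(f) = |P_xy|^2 / (P_xx P_yy)`` with all spectra estimated by
the same Welch scheme; it lives in [0, 1] with 1 meaning a perfect
linear relation at that frequency.  The phase-locking value (PLV) and
its sample-size-debiased relative, pairwise phase consistency (PPC),
are provided as secondary phase-synchrony metrics based on analytic-
signal phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "ALPHA", "BETA", "GAMMA", "BANDS",
    "Spectrum",
    "CoherenceCurve",
    "bandpass",
    "welch_psd",
    "coherence",
    "average_spectra",
    "average_coherence",
    "band_mean_coherence",
    "peak_frequency",
    "plv",
    "ppc",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: need 0 < low < high")


ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 48.0)
BANDS = {b.name: b for b in (ALPHA, BETA, GAMMA)}


@dataclass(frozen=True)
class _Curve:
    freqs: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.freqs.shape != self.values.shape:
            raise ValueError("frequency grid and values must have equal shape")

    def band(self, f_lo: float, f_hi: float) -> np.ndarray:
        """Boolean mask of grid points with f_lo <= f <= f_hi (inclusive)."""
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not np.any(sel):
            raise ValueError(f"band [{f_lo}, {f_hi}] Hz does not overlap the grid")
        return sel


class Spectrum(_Curve):
    """Welch power spectral density on a uniform frequency grid."""


class CoherenceCurve(_Curve):
    """Magnitude-squared coherence on a uniform frequency grid."""


def bandpass(ts: np.ndarray, fs: float, f_lo: float = 3.0, f_hi: float = 60.0,
             order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The forward-backward application doubles the effective attenuation
    and cancels the phase response, so later phase metrics see no filter
    distortion.  Works on 1-D series or (n, channels) arrays.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= fs / 2:
        raise ValueError(f"high cutoff {f_hi} Hz must be below Nyquist {fs / 2} Hz")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ts, float), axis=0)


def _welch_args(fs: float, seg_len: int | None, overlap_fraction: float,
                window_name: str) -> dict:
    if seg_len is None:
        seg_len = int(round(4.0 * fs))  # 0.25 Hz resolution
    return dict(fs=fs, window=window_name, nperseg=seg_len,
                noverlap=int(round(overlap_fraction * seg_len)))


def welch_psd(ts: np.ndarray, fs: float, seg_len: int | None = None,
              overlap_fraction: float = 0.5,
              window_name: str = "hamming") -> Spectrum:
    """Welch PSD with Hamming window and 50% overlap by default."""
    ts = np.asarray(ts, float)
    kw = _welch_args(fs, seg_len, overlap_fraction, window_name)
    if ts.shape[0] < kw["nperseg"]:
        raise ValueError(
            f"series of length {ts.shape[0]} is shorter than one segment ({kw['nperseg']})")
    freqs, power = sps.welch(ts, **kw)
    return Spectrum(freqs, power,
                    meta=dict(seg_len=kw["nperseg"], noverlap=kw["noverlap"],
                              window=window_name, fs=fs))


def coherence(x: np.ndarray, y: np.ndarray, fs: float, seg_len: int | None = None,
              overlap_fraction: float = 0.5,
              window_name: str = "hamming") -> CoherenceCurve:
    """Magnitude-squared coherence |P_xy|^2 / (P_xx P_yy) of two channels."""
    x = np.asarray(x, float); y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    kw = _welch_args(fs, seg_len, overlap_fraction, window_name)
    step = kw["nperseg"] - kw["noverlap"]
    n_segments = max(0, 1 + (x.shape[0] - kw["nperseg"]) // step)
    if n_segments < 2:
        raise ValueError("need at least 2 Welch segments; coherence is degenerate at 1")
    freqs, coh = sps.coherence(x, y, **kw)
    return CoherenceCurve(freqs, coh,
                          meta=dict(seg_len=kw["nperseg"], noverlap=kw["noverlap"],
                                    window=window_name, fs=fs,
                                    n_segments=n_segments))


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Ensemble (across-run) average of PSDs on identical grids."""
    _check_grids(spectra)
    values = np.mean([s.values for s in spectra], axis=0)
    meta = dict(spectra[0].meta, n_average=len(spectra))
    return Spectrum(spectra[0].freqs, values, meta=meta)


def average_coherence(curves: Sequence[CoherenceCurve]) -> CoherenceCurve:
    """Ensemble average of per-run coherence curves."""
    _check_grids(curves)
    values = np.mean([c.values for c in curves], axis=0)
    meta = dict(curves[0].meta, n_average=len(curves))
    return CoherenceCurve(curves[0].freqs, values, meta=meta)


def pooled_coherence(xs: Sequence[np.ndarray], ys: Sequence[np.ndarray], fs: float,
                     seg_len: int | None = None, overlap_fraction: float = 0.5,
                     window_name: str = "hamming") -> CoherenceCurve:
    """Coherence with cross-/auto-spectra pooled over runs before the ratio.

    Alternative to averaging per-run curves: segments of all runs enter
    one common estimate, |sum P_xy|^2 / (sum P_xx sum P_yy).
    """
    kw = _welch_args(fs, seg_len, overlap_fraction, window_name)
    pxy = pxx = pyy = 0.0
    freqs = None
    for x, y in zip(xs, ys, strict=True):
        f, cxy = sps.csd(x, y, **kw)
        _, cxx = sps.welch(x, **kw)
        _, cyy = sps.welch(y, **kw)
        freqs = f
        pxy = pxy + cxy
        pxx = pxx + cxx
        pyy = pyy + cyy
    values = np.abs(pxy) ** 2 / (pxx * pyy)
    return CoherenceCurve(freqs, values,
                          meta=dict(seg_len=kw["nperseg"], window=window_name,
                                    fs=fs, pooled_runs=len(xs)))


def _check_grids(curves) -> None:
    if not curves:
        raise ValueError("need at least one curve")
    for c in curves[1:]:
        if not np.array_equal(c.freqs, curves[0].freqs):
            raise ValueError("curves are on different frequency grids")


def band_mean_coherence(curve: CoherenceCurve, f_lo: float, f_hi: float) -> float:
    """Arithmetic mean of coherence over grid points in [f_lo, f_hi] inclusive."""
    sel = curve.band(f_lo, f_hi)
    return float(np.mean(curve.values[sel]))


def peak_frequency(curve: _Curve, f_lo: float | BandDefinition | None = None,
                   f_hi: float | None = None) -> float:
    """Frequency of the maximum value within a band (ties -> lower frequency)."""
    if isinstance(f_lo, BandDefinition):
        f_lo, f_hi = f_lo.low, f_lo.high
    if f_lo is None:
        f_lo, f_hi = curve.freqs[0], curve.freqs[-1]
    sel = curve.band(f_lo, f_hi)
    # np.argmax returns the first maximum, i.e. the lowest frequency on ties
    return float(curve.freqs[sel][np.argmax(curve.values[sel])])


# ---------------------------------------------------------------------------
# Phase synchrony

def _phase_differences(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float); y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return np.angle(sps.hilbert(x)) - np.angle(sps.hilbert(y))


def plv(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-locking value: modulus of the mean unit phasor of the phase difference.

    Inputs should be band-limited (e.g. via :func:`bandpass`) so that the
    analytic-signal phase is meaningful.  1 means perfect phase locking,
    0 no consistent phase relation.
    """
    dphi = _phase_differences(x, y)
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def ppc(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise phase consistency: the debiased analogue of PLV**2.

    Computed as ``(|sum_j e^{i dphi_j}|^2 - n) / (n (n - 1))``, the
    unbiased estimator of the squared population phase-locking; its
    expectation is 0 for independent phases regardless of sample size,
    and its range is (-1/(n-1), 1].
    """
    dphi = _phase_differences(x, y)
    n = dphi.shape[0]
    if n < 2:
        raise ValueError("PPC requires at least 2 samples")
    s = np.abs(np.sum(np.exp(1j * dphi))) ** 2
    return float((s - n) / (n * (n - 1)))
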