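"""Global impedance waveform construction and FFT band decomposition.

Electrical impedance tomography (EIT) delivers a time series of reconstructed
impedance-change images (typically a 32x32 grid at 10 frames per second).
Summing the in-mask pixels of each frame yields the *global impedance
waveform*, a one-dimensional signal dominated by tidal breathing with a
smaller cardiac (perfusion-related) component riding on top.

This module decomposes that waveform in the frequency domain.  All public
frequencies are expressed in cycles per minute (cpm = Hz * 60).  The
respiration band is 2-40 cpm, split into a low band (2-25 cpm, normal
resting respiratory rates) and a high band (25-40 cpm); content above
40 cpm is attributed to perfusion, consistent with resting heart rates of
40-100 beats per minute.  Band areas are computed on the one-sided amplitude
spectrum by the trapezoidal rule, with the spectrum linearly interpolated at
the exact band edges so that the three band integrals add up exactly to the
integral over the whole 2 cpm-to-Nyquist range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EITFrameSequence",
    "ImpedanceSeries",
    "SpectralDecomposition",
    "extract_global_waveform",
    "select_stable_window",
    "compute_spectrum",
    "peak_respiratory_frequency",
    "split_ventilation_perfusion",
    "RESPIRATION_BAND_CPM",
    "LOW_HIGH_SPLIT_CPM",
    "VENTILATION_PERFUSION_SPLIT_CPM",
]

#: Respiration band limits in cycles/min.
RESPIRATION_BAND_CPM = (2.0, 40.0)
#: Boundary between the low- and high-frequency respiration sub-bands.
LOW_HIGH_SPLIT_CPM = 25.0
#: Fixed ventilation/perfusion cutoff in cycles/min.
VENTILATION_PERFUSION_SPLIT_CPM = 40.0


@dataclass
class ImpedanceSeries:
    """Uniformly sampled global impedance waveform.

    Parameters
    ----------
    values
        Impedance-change values (arbitrary units), one per sample.
    sample_rate_hz
        Sampling rate in Hz (frames per second of the EIT acquisition).
    plane_label
        Optional anatomical plane tag (``"upper"``, ``"middle"``, ``"lower"``).
    """

    values: np.ndarray
    sample_rate_hz: float
    plane_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("impedance series must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("impedance series contains non-finite values")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def nyquist_cpm(self) -> float:
        return self.sample_rate_hz * 60.0 / 2.0

    def slice(self, start: int, stop: int) -> "ImpedanceSeries":
        return replace(self, values=self.values[start:stop].copy())


@dataclass
class EITFrameSequence:
    """Time-ordered stack of square impedance-change grids with an ROI mask."""

    frames: np.ndarray  # (n_frames, side, side)
    sample_rate_hz: float
    roi_mask: np.ndarray  # boolean (side, side)
    plane_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, row, col) stack")
        if self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be square grids")
        if self.roi_mask.shape != self.frames.shape[1:]:
            raise ValueError(
                f"roi_mask shape {self.roi_mask.shape} does not match frame shape "
                f"{self.frames.shape[1:]}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass
class SpectralDecomposition:
    """One-sided amplitude spectrum with respiration/perfusion band integrals.

    ``amplitude[k]`` is the amplitude (not power) attributable to
    ``freqs_cpm[k]``: a unit-amplitude on-bin sinusoid contributes 1.0.
    Band edges follow the half-open convention [lo, hi); integrals are
    trapezoidal with the spectrum interpolated at the exact edges, which makes
    ``low + high + perfusion`` equal the total 2 cpm-to-Nyquist area exactly.
    """

    freqs_cpm: np.ndarray
    amplitude: np.ndarray
    band_edges_cpm: tuple  # (low_lo, low_hi, high_hi, perf_hi)
    low_integral: float
    high_integral: float
    perfusion_integral: float
    quantity: str = "amplitude"

    @property
    def total_integral(self) -> float:
        return self.low_integral + self.high_integral + self.perfusion_integral


def extract_global_waveform(seq: EITFrameSequence) -> ImpedanceSeries:
    """Sum in-mask pixels of each frame into the global impedance waveform."""
    if not seq.roi_mask.any():
        raise ValueError("ROI mask is empty: no pixels to integrate")
    values = seq.frames[:, seq.roi_mask].sum(axis=1)
    return ImpedanceSeries(values=values, sample_rate_hz=seq.sample_rate_hz,
                           plane_label=seq.plane_label)


def _trough_indices(values: np.ndarray, prominence: float) -> np.ndarray:
    troughs, _ = find_peaks(-values, prominence=prominence)
    return troughs


def select_stable_window(series: ImpedanceSeries, window_s: float = 60.0,
                         min_prominence_frac: float = 0.2) -> ImpedanceSeries:
    """Select the most stable contiguous window of ``window_s`` seconds.

    Candidate windows start at detected breath-cycle troughs of the
    ventilation (sub-40 cpm) channel.  Stability is scored as the variance of
    peak prominences within the candidate window; the earliest window wins
    ties.  Windows with fewer than two detected breaths score infinitely
    unstable.
    """
    n_win = int(round(window_s * series.sample_rate_hz))
    if n_win > series.n_samples:
        raise ValueError(
            f"series duration {series.duration_s:.1f} s is shorter than the requested "
            f"window of {window_s:.1f} s (need at least {n_win} samples)"
        )
    if n_win == series.n_samples:
        return series.slice(0, n_win)

    vent, _ = split_ventilation_perfusion(series, mode="fixed_40cpm")
    v = vent.values
    prominence = min_prominence_frac * float(np.ptp(v)) if np.ptp(v) > 0 else None
    starts = _trough_indices(v, prominence) if prominence else np.array([], dtype=int)
    starts = starts[starts + n_win <= series.n_samples]
    if starts.size == 0:
        step = max(1, int(round(series.sample_rate_hz)))
        starts = np.arange(0, series.n_samples - n_win + 1, step)

    scores = []
    for s in starts:
        seg = v[s:s + n_win]
        prom_seg = min_prominence_frac * float(np.ptp(seg))
        if prom_seg <= 0:
            scores.append(np.inf)
            continue
        _, props = find_peaks(seg, prominence=prom_seg)
        proms = props["prominences"]
        scores.append(float(np.var(proms)) if proms.size >= 2 else np.inf)
    scores = np.asarray(scores)
    # scores within float jitter of the minimum count as ties; earliest wins
    tol = 1e-9 * float(np.ptp(v)) ** 2
    best = scores.min()
    best_start = int(starts[np.flatnonzero(scores <= best + tol)[0]])
    return series.slice(best_start, best_start + n_win)


def _one_sided_amplitude(values: np.ndarray, sample_rate_hz: float):
    """Mean-removed one-sided amplitude spectrum; frequencies in cpm."""
    x = values - values.mean()
    n = x.size
    spec = np.fft.rfft(x)
    amp = np.abs(spec) * 2.0 / n
    amp[0] = np.abs(spec[0]) / n
    if n % 2 == 0:
        amp[-1] = np.abs(spec[-1]) / n
    freqs_cpm = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz) * 60.0
    return freqs_cpm, amp


def _band_area(freqs: np.ndarray, amp: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of ``amp`` over [lo, hi] with interpolated edges."""
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inner], [hi]))
    a = np.concatenate(([np.interp(lo, freqs, amp)], amp[inner],
                        [np.interp(hi, freqs, amp)]))
    return float(np.trapezoid(a, f))


def compute_spectrum(series: ImpedanceSeries, taper: str = "rectangular") -> SpectralDecomposition:
    """FFT the mean-removed waveform and integrate the three bands.

    Parameters
    ----------
    series
        Uniformly sampled impedance waveform; at least 16 samples.
    taper
        ``"rectangular"`` (default, plain FFT) or ``"hann"``.
    """
    if series.n_samples < 16:
        raise ValueError(f"need at least 16 samples, got {series.n_samples}")
    values = series.values
    if taper == "hann":
        values = (values - values.mean()) * np.hanning(values.size)
    elif taper != "rectangular":
        raise ValueError(f"unknown taper {taper!r}")
    freqs, amp = _one_sided_amplitude(values, series.sample_rate_hz)
    lo, split, vp = RESPIRATION_BAND_CPM[0], LOW_HIGH_SPLIT_CPM, VENTILATION_PERFUSION_SPLIT_CPM
    nyq = series.nyquist_cpm
    return SpectralDecomposition(
        freqs_cpm=freqs,
        amplitude=amp,
        band_edges_cpm=(lo, split, vp, nyq),
        low_integral=_band_area(freqs, amp, lo, split),
        high_integral=_band_area(freqs, amp, split, vp),
        perfusion_integral=_band_area(freqs, amp, vp, nyq),
    )


def peak_respiratory_frequency(spec: SpectralDecomposition) -> float:
    """Frequency (cpm) of the largest-amplitude bin within the 2-40 cpm band.

    Ties go to the lowest-frequency maximal bin.
    """
    lo, hi = RESPIRATION_BAND_CPM
    in_band = (spec.freqs_cpm >= lo) & (spec.freqs_cpm <= hi)
    if not in_band.any():
        raise ValueError("respiration band (2-40 cpm) contains no spectral bins")
    idx = np.flatnonzero(in_band)
    return float(spec.freqs_cpm[idx[np.argmax(spec.amplitude[idx])]])


def split_ventilation_perfusion(series: ImpedanceSeries, mode: str = "fixed_40cpm"):
    """Partition the waveform into ventilation and perfusion channels.

    The FFT bins strictly below the cutoff (excluding DC) form the
    ventilation channel; bins at or above the cutoff form the perfusion
    channel.  The partition is exact: ventilation + perfusion + mean
    reconstructs the input to floating precision.

    Parameters
    ----------
    mode
        ``"fixed_40cpm"`` uses the 40 cpm respiration/perfusion boundary;
        ``"adaptive_2p5x"`` uses 2.5x the peak respiratory frequency.

    Returns
    -------
    (ventilation, perfusion) : tuple of ImpedanceSeries
    """
    if mode == "fixed_40cpm":
        cutoff_cpm = VENTILATION_PERFUSION_SPLIT_CPM
    elif mode == "adaptive_2p5x":
        cutoff_cpm = 2.5 * peak_respiratory_frequency(compute_spectrum(series))
        if cutoff_cpm >= series.nyquist_cpm:
            raise ValueError(
                f"adaptive cutoff {cutoff_cpm:.1f} cpm is at or above the Nyquist "
                f"frequency {series.nyquist_cpm:.1f} cpm"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    x = series.values
    n = x.size
    spec = np.fft.rfft(x)
    freqs_cpm = np.fft.rfftfreq(n, d=1.0 / series.sample_rate_hz) * 60.0
    vent_bins = (freqs_cpm > 0) & (freqs_cpm < cutoff_cpm)
    perf_bins = freqs_cpm >= cutoff_cpm
    vent = np.fft.irfft(np.where(vent_bins, spec, 0), n=n)
    perf = np.fft.irfft(np.where(perf_bins, spec, 0), n=n)
    mk = lambda v: ImpedanceSeries(values=v, sample_rate_hz=series.sample_rate_hz,
                                   plane_label=series.plane_label)
    return mk(vent), mk(perf)
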