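"""Respiratory-cardiovascular coupling via VT-SBP mean square coherence.

Per-breath tidal volume (input) and per-beat systolic pressure (output)
are resampled to a common uniform grid; Welch auto-/cross-spectra give
the magnitude-squared coherence, which is averaged over a 0.1-Hz band
centered at the tidal-volume spectral peak in the low-frequency domain.
The analytic significance level for L averaged segments,
``1 - alpha**(1/(L-1))``, is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.interpolate import CubicSpline

from cardioresp.breath import BreathSeries
from cardioresp.core_io import SignalTrace
from cardioresp.hemo import BeatSeries

__all__ = [
    "CouplingResult",
    "breath_parameter_series",
    "beat_parameter_series",
    "coherence_vt_sbp",
]

#: search range (Hz) for the tidal-volume spectral peak
LF_DOMAIN = (0.01, 0.6)


@dataclass(frozen=True)
class CouplingResult:
    peak_freq: float                  # Hz, VT autospectrum argmax in the LF domain
    band: tuple[float, float]         # peak +/- 0.05 Hz
    mean_coherence: float             # mean C(f) over the band, in [0, 1]
    significance_level: float
    n_segments: int
    freqs: np.ndarray
    coherence: np.ndarray


def _interp_series(
    times: np.ndarray, values: np.ndarray, resample_rate: float, units: str, label: str
) -> SignalTrace:
    if times.size < 30:
        raise ValueError("need at least 30 points to build a parameter series")
    grid = np.arange(times[0], times[-1], 1.0 / resample_rate)
    if np.ptp(values) < 1e-12:
        out = np.zeros(grid.size)
    else:
        out = CubicSpline(times, values)(grid)
        out = out - out.mean()
    return SignalTrace(out, sampling_rate=resample_rate, units=units, start_time=grid[0], label=label)


def breath_parameter_series(
    series: BreathSeries, parameter: str = "vt", resample_rate: float = 4.0
) -> SignalTrace:
    """Mean-removed per-breath parameter (vt or interval) on a uniform grid."""
    if parameter == "vt":
        values, units = series.vt, "dimensionless"
    elif parameter == "interval":
        values, units = series.intervals_ms, "ms"
    else:
        raise ValueError("parameter must be 'vt' or 'interval'")
    return _interp_series(series.onsets, values, resample_rate, units, f"breath_{parameter}")


def beat_parameter_series(
    beats: BeatSeries, parameter: str = "sbp", resample_rate: float = 4.0
) -> SignalTrace:
    """Mean-removed per-beat parameter (sbp) on a uniform grid."""
    if parameter != "sbp":
        raise ValueError("parameter must be 'sbp'")
    return _interp_series(beats.beat_times[1:], beats.sbp, resample_rate, "dimensionless", "beat_sbp")


def coherence_vt_sbp(
    vt_series: SignalTrace,
    sbp_series: SignalTrace,
    record_s: float = 600.0,
    segment_s: float = 120.0,
    overlap: float = 0.5,
    half_band: float = 0.05,
    alpha: float = 0.05,
) -> CouplingResult:
    """Welch magnitude-squared coherence over ``peak_freq`` +/- ``half_band``.

    Both series must share a uniform rate; the default 120-s Hann
    segments with 50 % overlap give >= 9 segments in a 10-min record.
    """
    if abs(vt_series.sampling_rate - sbp_series.sampling_rate) > 1e-9:
        raise ValueError("mismatched sampling rates")
    fs = vt_series.sampling_rate
    # align on the common overlap
    t0 = max(vt_series.start_time, sbp_series.start_time)
    n_rec = int(round(record_s * fs))
    x = vt_series.samples[int(round((t0 - vt_series.start_time) * fs)) :]
    y = sbp_series.samples[int(round((t0 - sbp_series.start_time) * fs)) :]
    n = min(x.size, y.size)
    if n < n_rec:
        raise ValueError(f"record too short: need {record_s} s at {fs} Hz")
    x, y = x[:n_rec], y[:n_rec]

    nperseg = int(round(segment_s * fs))
    noverlap = int(round(nperseg * overlap))
    step = nperseg - noverlap
    n_segments = (n_rec - nperseg) // step + 1
    if n_segments < 2:
        raise ValueError("need at least 2 Welch segments for a meaningful coherence")

    freqs, pxx = scipy.signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    _, coh = scipy.signal.coherence(x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)

    search = (freqs >= LF_DOMAIN[0]) & (freqs <= LF_DOMAIN[1])
    if not np.any(search):
        raise ValueError("no frequency bins in the low-frequency search domain")
    peak_freq = float(freqs[search][np.argmax(pxx[search])])
    band = (peak_freq - half_band, peak_freq + half_band)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    mean_coh = float(np.mean(coh[in_band]))
    significance = 1.0 - alpha ** (1.0 / (n_segments - 1))
    return CouplingResult(
        peak_freq=peak_freq,
        band=band,
        mean_coherence=mean_coh,
        significance_level=significance,
        n_segments=n_segments,
        freqs=freqs,
        coherence=coh,
    )
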