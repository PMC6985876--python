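"""RR tachogram construction and autoregressive HRV spectra.

Rat-specific bands: LF 0.04-0.6 Hz, HF 0.6-2.4 Hz. The analysis window
is split into Hann-tapered subwindows with 50 % overlap; each subwindow
is fit with a Burg autoregressive model (default order 16) and the
per-subwindow spectra are averaged — a Welch-style segmentation with AR
estimation per segment. A single-window AR fit is obtained by setting
``subwindow_s`` equal to ``window_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg

from cardioresp.core_io import SignalTrace
from cardioresp.hemo import BeatSeries

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "PSDEstimate",
    "SpectralSummary",
    "build_tachogram",
    "psd_ar",
    "band_powers",
    "time_varying_hrv",
]

LF_BAND = (0.04, 0.6)
HF_BAND = (0.6, 2.4)


@dataclass(frozen=True)
class PSDEstimate:
    freqs: np.ndarray        # Hz, increasing from 0
    power: np.ndarray        # ms^2/Hz, one-sided
    ar_order: int
    window: str
    n_segments: int
    segment_s: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValueError("freqs must increase from 0")

    @property
    def total_power(self) -> float:
        """ms^2, trapezoidal integral over all frequencies."""
        return float(np.trapezoid(self.power, self.freqs))


@dataclass(frozen=True)
class SpectralSummary:
    lf_power: float    # ms^2
    hf_power: float    # ms^2
    lf_nu: float       # normalized units, 100 * lf / (lf + hf)
    hf_nu: float
    lf_hf: float
    lf_band: tuple[float, float] = LF_BAND
    hf_band: tuple[float, float] = HF_BAND


def build_tachogram(beats: BeatSeries, resample_rate: float = 10.0, demean: bool = False) -> SignalTrace:
    """Cubic interpolation of the RR series onto a uniform grid.

    Each RR value is anchored at the time of the beat that closes its
    cycle. 10 Hz leaves ample margin above twice the 2.4-Hz band edge.
    """
    if len(beats) < 30:
        raise ValueError("need at least 30 beats to build a tachogram")
    t = beats.beat_times[1:]
    rr = beats.rr
    if np.ptp(rr) < 1e-12:
        # interpolation of a constant is the constant; avoids spline pathologies
        grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
        values = np.full(grid.size, rr[0])
    else:
        spline = CubicSpline(t, rr)
        grid = np.arange(t[0], t[-1], 1.0 / resample_rate)
        values = spline(grid)
    if demean:
        values = values - values.mean()
    return SignalTrace(values, sampling_rate=resample_rate, units="ms", start_time=grid[0], label="rr")


def _burg_psd(x: np.ndarray, fs: float, order: int, freqs: np.ndarray) -> np.ndarray:
    rho, sigma2 = burg(x, order=order, demean=True)
    # one-sided AR spectrum: sigma2 / (fs |1 - sum rho_k z^-k|^2), doubled
    z = np.exp(-2j * math.pi * np.outer(freqs, np.arange(1, order + 1)) / fs)
    denom = np.abs(1.0 - z @ rho) ** 2
    return 2.0 * sigma2 / (fs * denom)


def psd_ar(
    tacho: SignalTrace,
    window_s: float = 600.0,
    subwindow_s: float = 60.0,
    ar_order: int = 16,
    n_freqs: int = 8192,
) -> PSDEstimate:
    """Averaged Burg AR spectrum over Hann-tapered, 50 %-overlapping subwindows.

    Each subwindow is mean-removed and tapered with a power-normalized
    Hann window, so the spectral integral tracks the tapered-series
    variance.
    """
    fs = tacho.sampling_rate
    n = tacho.samples.size
    n_win = int(round(window_s * fs))
    if n_win > n:
        raise ValueError("window exceeds tachogram span")
    n_sub = int(round(subwindow_s * fs))
    if ar_order >= n_sub:
        raise ValueError("AR order must be below the subwindow sample count")
    step = max(n_sub // 2, 1)
    x = tacho.samples[:n_win]
    if np.ptp(x) < 1e-12:
        freqs = np.linspace(0.0, fs / 2.0, n_freqs)
        return PSDEstimate(freqs, np.zeros(n_freqs), ar_order, "hann", 0, subwindow_s)

    taper = np.hanning(n_sub)
    taper = taper / math.sqrt(np.mean(taper**2))  # preserve power
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    spectra = []
    for start in range(0, n_win - n_sub + 1, step):
        seg = x[start : start + n_sub]
        seg = (seg - seg.mean()) * taper
        spectra.append(_burg_psd(seg, fs, ar_order, freqs))
    return PSDEstimate(freqs, np.mean(spectra, axis=0), ar_order, "hann", len(spectra), subwindow_s)


def band_powers(
    psd: PSDEstimate,
    lf: tuple[float, float] = LF_BAND,
    hf: tuple[float, float] = HF_BAND,
) -> SpectralSummary:
    """Band powers by trapezoidal integration over half-open bands [lo, hi)."""
    if psd.freqs[-1] < hf[1]:
        raise ValueError("PSD does not cover the HF band")

    def _band(band: tuple[float, float]) -> float:
        mask = (psd.freqs >= band[0]) & (psd.freqs < band[1])
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd.power[mask], psd.freqs[mask]))

    lf_p, hf_p = _band(lf), _band(hf)
    total = lf_p + hf_p
    if hf_p <= 0:
        raise ValueError("HF band power is zero; LF/HF undefined")
    return SpectralSummary(
        lf_power=lf_p,
        hf_power=hf_p,
        lf_nu=100.0 * lf_p / total,
        hf_nu=100.0 * hf_p / total,
        lf_hf=lf_p / hf_p,
        lf_band=lf,
        hf_band=hf,
    )


def time_varying_hrv(
    tacho: SignalTrace,
    step_s: float,
    window_s: float = 600.0,
    subwindow_s: float = 60.0,
    ar_order: int = 16,
) -> list[tuple[float, SpectralSummary]]:
    """Sliding-window spectral summaries at ``step_s`` spacing.

    Row ``k`` is (window start time, summary); the number of rows is
    ``floor((span - window)/step) + 1``.
    """
    if step_s <= 0:
        raise ValueError("step must be > 0")
    fs = tacho.sampling_rate
    span = tacho.samples.size / fs
    if span < window_s:
        raise ValueError("tachogram shorter than one window")
    out = []
    n_rows = int(math.floor((span - window_s) / step_s)) + 1
    for k in range(n_rows):
        t0 = k * step_s
        i0 = int(round(t0 * fs))
        sub = SignalTrace(
            tacho.samples[i0 : i0 + int(round(window_s * fs))],
            sampling_rate=fs,
            units=tacho.units,
            start_time=tacho.start_time + t0,
        )
        psd = psd_ar(sub, window_s=window_s, subwindow_s=subwindow_s, ar_order=ar_order)
        out.append((tacho.start_time + t0, band_powers(psd)))
    return out
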