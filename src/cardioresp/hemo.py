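"""Arterial-pressure beat detection, heart-rate smoothing, and Teichholz volumes.

Beats are located at maxima of dP/dt (central differences after a 20-Hz
low-pass) rather than at pressure peaks; per-cycle systolic, diastolic,
mean and pulse pressures are then read off the raw waveform between
successive beat times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from cardioresp.core_io import SignalTrace

__all__ = ["BeatSeries", "EchoSummary", "detect_beats", "smooth_hr", "teichholz"]


@dataclass(frozen=True)
class BeatSeries:
    """Beat times plus per-cycle pressures.

    ``beat_times`` has length n; the per-cycle arrays (``rr`` in ms,
    pressures in mmHg) have length n - 1, cycle k spanning
    ``[beat_times[k], beat_times[k+1])``.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    pp: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_times", "rr", "sbp", "dbp", "map", "pp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.rr.size != self.beat_times.size - 1:
            raise ValueError("rr must have one entry per cycle (n_beats - 1)")
        if np.any(self.rr <= 0):
            raise ValueError("rr must be > 0")

    def __len__(self) -> int:
        return self.beat_times.size

    @classmethod
    def from_times(cls, beat_times: np.ndarray, sbp: float = 120.0, dbp: float = 80.0) -> "BeatSeries":
        """Build a series from beat times alone (constant nominal pressures)."""
        beat_times = np.asarray(beat_times, dtype=float)
        n = beat_times.size - 1
        rr = np.diff(beat_times) * 1000.0
        const = np.full(n, float(sbp)), np.full(n, float(dbp))
        return cls(beat_times, rr, const[0], const[1], (const[0] + 2 * const[1]) / 3.0, const[0] - const[1])

    @property
    def mean_hr(self) -> float:
        """beats/min from the mean RR."""
        return 60000.0 / float(np.mean(self.rr))


@dataclass(frozen=True)
class EchoSummary:
    lvedv: float   # uL
    lvesv: float   # uL
    sv: float      # uL
    ef: float      # %
    fs: float      # %
    meets_hf_criteria: bool | None = None


def _running_percentile(x: np.ndarray, fs: float, q: float = 95.0, block_s: float = 10.0) -> np.ndarray:
    """Piecewise-constant running percentile over consecutive blocks."""
    n = x.size
    block = max(int(block_s * fs), 1)
    nblocks = max(n // block, 1)
    out = np.empty(n)
    for b in range(nblocks):
        lo = b * block
        hi = n if b == nblocks - 1 else lo + block
        out[lo:hi] = np.percentile(x[lo:hi], q)
    return out


def detect_beats(
    pressure: SignalTrace,
    lowpass_hz: float = 20.0,
    threshold_frac: float = 0.3,
    refractory_s: float = 0.08,
    map_rule: str = "waveform",
) -> BeatSeries:
    """Detect beats at dP/dt maxima and extract per-cycle pressures.

    dP/dt maxima must exceed ``threshold_frac`` of the running 95th
    percentile of positive dP/dt and respect an 80-ms refractory period.
    MAP is the per-cycle waveform time-average, or DBP + PP/3 with
    ``map_rule="third"``.
    """
    fs = pressure.sampling_rate
    if fs < 100:
        raise ValueError("pressure sampling rate must be >= 100 Hz")
    sos = scipy.signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    p = scipy.signal.sosfiltfilt(sos, pressure.samples)
    dpdt = np.gradient(p) * fs
    height = threshold_frac * _running_percentile(np.clip(dpdt, 0, None), fs)
    peaks, _ = scipy.signal.find_peaks(dpdt, height=height, distance=max(int(refractory_s * fs), 1))
    if peaks.size < 2:
        raise ValueError("no beats found")

    raw = pressure.samples
    n_cycles = peaks.size - 1
    sbp = np.empty(n_cycles)
    dbp = np.empty(n_cycles)
    mbp = np.empty(n_cycles)
    for k in range(n_cycles):
        seg = raw[peaks[k] : peaks[k + 1]]
        sbp[k] = seg.max()
        dbp[k] = seg.min()
        mbp[k] = seg.mean()
    if map_rule == "third":
        mbp = dbp + (sbp - dbp) / 3.0
    elif map_rule != "waveform":
        raise ValueError("map_rule must be 'waveform' or 'third'")
    beat_times = pressure.start_time + peaks / fs
    rr = np.diff(beat_times) * 1000.0
    return BeatSeries(beat_times=beat_times, rr=rr, sbp=sbp, dbp=dbp, map=mbp, pp=sbp - dbp)


def smooth_hr(
    beats: BeatSeries,
    level_variance: float | None = None,
    observation_variance: float | None = None,
) -> BeatSeries:
    """Kalman (fixed-interval) smoothing of the RR series.

    The RR tachogram is modelled as a local level (random walk) observed
    in Gaussian noise; both variances are estimated by maximum likelihood
    unless supplied. Beat count is preserved.
    """
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    rr = beats.rr
    if rr.size < 9:
        raise ValueError("need at least 10 beats to smooth")
    if not np.all(np.isfinite(rr)):
        raise ValueError("non-finite RR values")
    if np.ptp(rr) < 1e-9:
        return beats  # constant input is a fixed point
    model = UnobservedComponents(rr, level="llevel")
    if level_variance is not None and observation_variance is not None:
        res = model.smooth([observation_variance, level_variance])
    else:
        res = model.fit(disp=False)
    smoothed = np.asarray(res.smoothed_state[0])
    smoothed = np.maximum(smoothed, 1e-6)
    return replace(beats, rr=smoothed)


def teichholz(
    lvedd: float,
    lvesd: float,
    reference: EchoSummary | None = None,
    ef_cutoff: float = 50.0,
    fold_change: float = 1.5,
) -> EchoSummary:
    """Left-ventricular volumes from M-mode diameters, V(D) = 7 D^3/(2.4 + D).

    Diameters in cm; volumes reported in uL. When a ``reference`` summary
    is given, a volume-overload predicate is evaluated: EF >= 50 % and
    both end-diastolic and stroke volume >= 1.5x the reference.
    """
    if lvedd <= 0 or lvesd <= 0:
        raise ValueError("diameters must be > 0")
    if lvesd > lvedd:
        raise ValueError("require lvesd <= lvedd")

    def vol_ul(d: float) -> float:
        return 7.0 / (2.4 + d) * d**3 * 1000.0

    lvedv = vol_ul(lvedd)
    lvesv = vol_ul(lvesd)
    sv = lvedv - lvesv
    ef = 100.0 * sv / lvedv
    fs = 100.0 * (lvedd - lvesd) / lvedd
    meets = None
    if reference is not None:
        meets = ef >= ef_cutoff and lvedv >= fold_change * reference.lvedv and sv >= fold_change * reference.sv
    return EchoSummary(lvedv=lvedv, lvesv=lvesv, sv=sv, ef=ef, fs=fs, meets_hf_criteria=meets)
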