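"""Breath segmentation, ventilation summaries, event scoring and variability.

Inspiration is positive flow by convention. Breath onsets are upward
threshold crossings with hysteresis (the signal must cross below the
negative threshold before a new onset can fire), with the threshold set
to 5 % of the 95th percentile of ``|flow|``. Tidal volume is the
trapezoidal integral of inspiratory flow.

Scoring rules: an apnea is a cessation of airflow lasting at least three
local breathing cycles (cycle = mean of the 10 preceding normal
onset-to-onset intervals); a hypopnea is a breath whose tidal volume is
at most 50 % of the mean of the 3 most recent normal breaths; a sigh is
a breath at or above 150 % of that reference; an apnea beginning within
one cycle of a sigh offset is scored as a post-sigh apnea. "Normal"
excludes sighs, hypopneas and the two breaths flanking an apnea.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from cardioresp.core_io import AnnotationTable, SignalTrace

__all__ = [
    "Breath",
    "BreathSeries",
    "VentilationSummary",
    "EventSummary",
    "VariabilityStats",
    "segment_breaths",
    "ventilation_summary",
    "detect_events",
    "event_summary",
    "poincare_stats",
]


@dataclass(frozen=True)
class Breath:
    """One segmented breath; ``interval`` is onset-to-onset (s)."""

    t_insp_onset: float
    t_exp_onset: float
    t_end: float
    vt: float
    ti: float
    te: float
    interval: float


@dataclass(frozen=True)
class BreathSeries:
    """Column-oriented ordered breaths plus the subject's body mass (g)."""

    onsets: np.ndarray
    exp_onsets: np.ndarray
    ends: np.ndarray
    vt: np.ndarray
    interval: np.ndarray
    body_mass: float

    def __post_init__(self) -> None:
        for name in ("onsets", "exp_onsets", "ends", "vt", "interval"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.body_mass > 0):
            raise ValueError("body_mass must be > 0")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("breaths must be strictly time-ordered")

    def __len__(self) -> int:
        return self.onsets.size

    def __getitem__(self, i: int) -> Breath:
        return Breath(
            t_insp_onset=float(self.onsets[i]),
            t_exp_onset=float(self.exp_onsets[i]),
            t_end=float(self.ends[i]),
            vt=float(self.vt[i]),
            ti=float(self.exp_onsets[i] - self.onsets[i]),
            te=float(self.ends[i] - self.exp_onsets[i]),
            interval=float(self.interval[i]),
        )

    @property
    def intervals_ms(self) -> np.ndarray:
        return self.interval * 1000.0

    @property
    def span(self) -> tuple[float, float]:
        return float(self.onsets[0]), float(self.ends[-1])


@dataclass(frozen=True)
class VentilationSummary:
    vt_per100g: float     # mL / 100 g
    rf: float             # breaths/min
    ve: float             # mL . 100 g^-1 . min^-1, == vt_per100g * rf
    window: tuple[float, float]
    n_valid_cycles: int
    valid: bool = True


@dataclass(frozen=True)
class EventSummary:
    apnea_rate: float
    hypopnea_rate: float
    ahi: float
    sigh_rate: float
    post_sigh_apnea_rate: float
    mean_durations: dict = field(default_factory=dict)   # kind -> s (absent kind omitted)


@dataclass(frozen=True)
class VariabilityStats:
    sd1: float      # ms
    sd2: float      # ms
    cv_vt: float    # %
    n_breaths: int


# ---------------------------------------------------------------------------


def segment_breaths(
    flow: SignalTrace,
    body_mass: float,
    hysteresis_frac: float = 0.05,
    min_breath_s: float = 0.1,
    min_vt_frac: float = 0.1,
    min_gap_s: float = 0.25,
) -> BreathSeries:
    """Segment a calibrated flow trace (mL/s) into breaths.

    Candidate breaths shorter than ``min_breath_s`` or with tidal volume
    below ``min_vt_frac`` of the running median are suppressed rather
    than emitted. The trailing incomplete breath is dropped so that every
    emitted breath has a defined onset-to-onset interval. Sub-threshold
    airflow before the next onset counts as a silent gap (breath end <
    next onset) only when it lasts at least ``min_gap_s``; shorter tails
    are tapering expiration and stay inside the breath.
    """
    x = flow.samples
    fs = flow.sampling_rate
    theta = hysteresis_frac * np.percentile(np.abs(x), 95)
    if theta <= 0:
        raise ValueError("no breaths: flat signal")

    above = x >= theta
    below = x <= -theta
    up = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    dn = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if above[0]:
        up = np.concatenate(([0], up))
    events = np.concatenate((up, dn))
    kinds = np.concatenate((np.ones(up.size, dtype=np.int8), np.zeros(dn.size, dtype=np.int8)))
    order = np.argsort(events, kind="stable")
    events, kinds = events[order], kinds[order]

    onsets_idx = []
    armed = True
    for idx, k in zip(events, kinds):
        if k == 1 and armed:
            onsets_idx.append(idx)
            armed = False
        elif k == 0 and not armed:
            armed = True
    if len(onsets_idx) < 2:
        raise ValueError("no breaths: fewer than two onsets detected")
    onsets_idx = np.asarray(onsets_idx)

    # refine each onset from the threshold crossing back to the start of its
    # positive run (the true zero crossing), which de-biases Ti/Te splits
    pos_start = np.flatnonzero((x[1:] > 0) & (x[:-1] <= 0)) + 1
    if pos_start.size:
        j = np.searchsorted(pos_start, onsets_idx, side="right") - 1
        refined = np.where(j >= 0, pos_start[np.clip(j, 0, None)], onsets_idx)
        onsets_idx = np.minimum(onsets_idx, np.maximum(refined, 0))
        onsets_idx = onsets_idx[np.concatenate(([True], np.diff(onsets_idx) > 0))]

    # first negative sample after each onset marks expiration onset
    neg_start = np.flatnonzero((x[1:] < 0) & (x[:-1] >= 0)) + 1
    # samples where airflow is active (used for expiratory offsets)
    active = np.flatnonzero(np.abs(x) >= theta)

    breaths = []
    median_hist: deque[float] = deque(maxlen=21)
    for i in range(onsets_idx.size - 1):
        i0, i_next = onsets_idx[i], onsets_idx[i + 1]
        j = np.searchsorted(neg_start, i0, side="right")
        if j >= neg_start.size or neg_start[j] >= i_next:
            continue  # no expiratory phase before next onset: merge into next
        i_exp = neg_start[j]
        k = np.searchsorted(active, i_next, side="left") - 1
        i_end = min(active[k] + 1, i_next) if k >= 0 else i_next
        if i_end <= i_exp or (i_next - i_end) / fs < min_gap_s:
            i_end = i_next
        vt = float(np.trapezoid(x[i0 : i_exp + 1])) / fs
        if (i_end - i0) / fs < min_breath_s:
            continue
        if median_hist and vt < min_vt_frac * float(np.median(median_hist)):
            continue
        median_hist.append(vt)
        breaths.append((i0, i_exp, i_end, vt, i_next))

    if len(breaths) < 2:
        raise ValueError("no breaths: signal too short or degenerate")

    i0s = np.array([b[0] for b in breaths], dtype=float)
    exps = np.array([b[1] for b in breaths], dtype=float)
    ends = np.array([b[2] for b in breaths], dtype=float)
    vts = np.array([b[3] for b in breaths], dtype=float)
    # onset-to-onset interval to the next *emitted* breath; the last breath
    # keeps its raw next-candidate interval
    nexts = np.concatenate((i0s[1:], [breaths[-1][4]]))
    t0 = flow.start_time
    return BreathSeries(
        onsets=t0 + i0s / fs,
        exp_onsets=t0 + exps / fs,
        ends=t0 + ends / fs,
        vt=vts,
        interval=(nexts - i0s) / fs,
        body_mass=body_mass,
    )


def ventilation_summary(
    series: BreathSeries,
    window: tuple[float, float],
    ten_second_convention: bool = False,
) -> VentilationSummary:
    """Mean VT (per 100 g), rate, and minute ventilation over ``[t0, t1)``.

    With ``ten_second_convention`` the window is flagged invalid unless it
    holds 10 +/- 2 complete cycles.
    """
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("empty window")
    mask = (series.onsets >= t0) & (series.onsets < t1)
    n = int(mask.sum())
    if n < 1:
        raise ValueError("window contains no complete breath")
    vt100 = float(series.vt[mask].mean()) * 100.0 / series.body_mass
    rf = 60.0 * n / (t1 - t0)
    valid = (abs(n - 10) <= 2) if ten_second_convention else True
    return VentilationSummary(
        vt_per100g=vt100, rf=rf, ve=vt100 * rf, window=(t0, t1), n_valid_cycles=n, valid=valid
    )


def detect_events(
    series: BreathSeries,
    flow: SignalTrace | None = None,
    n_baseline: int = 10,
    apnea_cycles: float = 3.0,
    hypopnea_frac: float = 0.5,
    sigh_frac: float = 1.5,
) -> AnnotationTable:
    """Score apneas, hypopneas, sighs and post-sigh apneas on a breath series.

    Apnea duration is measured from the last expiratory offset of the
    preceding breath to the next inspiratory onset.
    """
    nb = len(series)
    if nb < n_baseline:
        raise ValueError(f"need at least {n_baseline} breaths for baseline estimation")

    onsets, ends, vts = series.onsets, series.ends, series.vt
    cycle_hist: deque[float] = deque(
        (onsets[1 : n_baseline] - onsets[: n_baseline - 1]).tolist(), maxlen=n_baseline
    )
    ref_hist: deque[float] = deque([float(np.median(vts[:n_baseline]))] * 3, maxlen=3)

    table = AnnotationTable()
    last_sigh_end = -math.inf
    prev_gap_was_apnea = False
    for i in range(nb):
        cycle = float(np.mean(cycle_hist))
        ref = float(np.mean(ref_hist))
        kind = None
        if vts[i] <= hypopnea_frac * ref:
            kind = "hypopnea"
        elif vts[i] >= sigh_frac * ref:
            kind = "sigh"
        if kind is not None:
            table.add(kind, onsets[i], ends[i] - onsets[i])
            if kind == "sigh":
                last_sigh_end = ends[i]

        gap = (onsets[i + 1] - ends[i]) if i + 1 < nb else 0.0
        gap_is_apnea = gap >= apnea_cycles * cycle
        if gap_is_apnea:
            akind = "post_sigh_apnea" if (ends[i] - last_sigh_end) <= cycle else "apnea"
            table.add(akind, ends[i], gap)

        if kind is None and not gap_is_apnea and not prev_gap_was_apnea:
            ref_hist.append(float(vts[i]))
            if i + 1 < nb:
                cycle_hist.append(float(onsets[i + 1] - onsets[i]))
        prev_gap_was_apnea = gap_is_apnea
    return table


def event_summary(events: AnnotationTable, duration: float) -> EventSummary:
    """Hourly event rates plus per-kind mean durations; AHI = apnea + hypopnea."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    factor = 3600.0 / duration
    rates = {}
    durations = {}
    for kind in ("apnea", "hypopnea", "sigh", "post_sigh_apnea"):
        evs = events.of_kind(kind)
        rates[kind] = len(evs) * factor
        if evs:
            durations[kind] = float(np.mean([e.duration for e in evs]))
    return EventSummary(
        apnea_rate=rates["apnea"],
        hypopnea_rate=rates["hypopnea"],
        ahi=rates["apnea"] + rates["hypopnea"],
        sigh_rate=rates["sigh"],
        post_sigh_apnea_rate=rates["post_sigh_apnea"],
        mean_durations=durations,
    )


def poincare_stats(series: BreathSeries, n: int = 300) -> VariabilityStats:
    """Poincare SD1/SD2 (ms) of the first ``n`` intervals plus the VT CV (%).

    Population (1/n) variances:
        SD1^2 = Var(x[i+1] - x[i]) / 2
        SD2^2 = 2 Var(x) - SD1^2
    """
    if len(series) < n:
        raise ValueError(f"need at least {n} consecutive breaths, have {len(series)}")
    x = series.intervals_ms[:n]
    d = np.diff(x)
    var_d = float(np.var(d))     # population variance
    var_x = float(np.var(x))
    sd1_sq = var_d / 2.0
    sd2_sq = max(2.0 * var_x - sd1_sq, 0.0)
    vt = series.vt[:n]
    cv = 100.0 * float(np.std(vt)) / float(np.mean(vt))
    return VariabilityStats(sd1=math.sqrt(sd1_sq), sd2=math.sqrt(sd2_sq), cv_vt=cv, n_breaths=n)
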