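"""Active-expiration quantification via the E2/E1 expiratory area ratio.

Each expiratory phase is split at half of its duration: E1 is the area
under ``|flow|`` over the first half, E2 over the second half; a rising
E2/E1 indicates recruitment of active (late) expiration. Cycles are
sampled from randomly chosen event-free ("at rest") runs, mirroring
blind segment selection, with the choice reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardioresp.breath import BreathSeries, detect_events
from cardioresp.core_io import AnnotationTable, SignalTrace

__all__ = ["ExpirationStats", "active_expiration"]


@dataclass(frozen=True)
class ExpirationStats:
    e1: float                      # mL, mean early-expiratory area
    e2: float                      # mL, mean late-expiratory area
    ratio: float                   # e2 / e1
    te: float                      # s, mean expiratory time
    n_cycles: int
    segment_starts: tuple[float, ...]


def _zero_crossing(flow: np.ndarray, idx: int, before: bool) -> float:
    """Fractional sample position where ``flow`` crosses zero at a run edge.

    ``idx`` is the first (``before=True``) or last (``before=False``)
    negative sample of an expiratory run; the crossing into the adjacent
    non-negative sample is linearly interpolated.
    """
    p = idx - 1 if before else idx
    q = p + 1
    if p < 0 or q >= flow.size:
        return float(idx)
    f_p, f_q = float(flow[p]), float(flow[q])
    if before:
        if f_p < 0 or f_q >= 0:
            return float(idx)
    else:
        if f_p >= 0 or f_q < 0:
            return float(idx)
    if f_p == f_q:
        return float(idx)
    return p + f_p / (f_p - f_q)


def _trapz_frac(y: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of piecewise-linear ``y`` over fractional [a, b]."""

    def val(p: float) -> float:
        i = int(p)
        f = p - i
        if i + 1 >= y.size:
            return float(y[-1])
        return float(y[i] * (1 - f) + y[i + 1] * f)

    ia, ib = int(np.ceil(a)), int(np.floor(b))
    if ia > ib:
        return 0.5 * (val(a) + val(b)) * (b - a)
    total = float(np.trapezoid(y[ia : ib + 1]))
    total += 0.5 * (val(a) + y[ia]) * (ia - a)
    total += 0.5 * (y[ib] + val(b)) * (b - ib)
    return total


def _eupneic_mask(series: BreathSeries, events: AnnotationTable) -> np.ndarray:
    """True for breaths not inside (or adjacent to) any scored event."""
    ok = np.ones(len(series), dtype=bool)
    for ev in events:
        lo, hi = ev.onset - 1e-9, ev.onset + ev.duration + 1e-9
        ok &= ~((series.ends > lo) & (series.onsets < hi))
    return ok


def active_expiration(
    series: BreathSeries,
    flow: SignalTrace,
    n_segments: int = 3,
    cycles_per_segment: int = 20,
    seed: int | None = 0,
    events: AnnotationTable | None = None,
) -> ExpirationStats:
    """E2/E1 stats over ``n_segments`` random event-free runs of consecutive cycles.

    ``events`` defaults to :func:`detect_events` on the series; pass an
    empty table to skip the eupnea restriction.
    """
    if events is None:
        events = detect_events(series)
    ok = _eupneic_mask(series, events)

    # candidate starts of runs with cycles_per_segment consecutive eupneic breaths
    n_runs = len(series) - cycles_per_segment + 1
    if n_runs <= 0:
        raise ValueError(
            f"insufficient eupneic cycles: need {n_segments} non-overlapping runs "
            f"of {cycles_per_segment} breaths"
        )
    run_ok = np.ones(n_runs, dtype=bool)
    for off in range(cycles_per_segment):
        run_ok &= ok[off : off + run_ok.size]
    candidates = np.flatnonzero(run_ok)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for i in rng.permutation(candidates.size):
        c = candidates[i]
        if all(abs(c - d) >= cycles_per_segment for d in chosen):
            chosen.append(int(c))
            if len(chosen) == n_segments:
                break
    if len(chosen) < n_segments:
        # random placement can wedge even when a packing exists; fall back to
        # a sorted earliest-fit scan, which packs the maximum number of runs
        chosen = []
        for c in candidates:
            if all(abs(int(c) - d) >= cycles_per_segment for d in chosen):
                chosen.append(int(c))
                if len(chosen) == n_segments:
                    break
    if len(chosen) < n_segments:
        raise ValueError(
            f"insufficient eupneic cycles: need {n_segments} non-overlapping runs "
            f"of {cycles_per_segment} breaths"
        )
    chosen.sort()

    fs = flow.sampling_rate
    # expiratory flow is negative by convention; clip so stray inspiratory
    # samples at the window edges contribute nothing
    y = np.maximum(-flow.samples, 0.0)
    neg = flow.samples < 0
    e1s, e2s, tes = [], [], []
    for c in chosen:
        for b in range(c, c + cycles_per_segment):
            t_exp = series.exp_onsets[b]
            t_end = series.ends[b]
            if t_end <= t_exp:
                continue
            i0 = int(round((t_exp - flow.start_time) * fs))
            i1 = int(round((t_end - flow.start_time) * fs))
            if i1 - i0 < 4:
                continue
            # trim to the actual negative-flow run to de-bias the te/2 split
            run = np.flatnonzero(neg[i0:i1])
            if run.size < 4:
                continue
            a = _zero_crossing(flow.samples, i0 + int(run[0]), before=True)
            bnd = _zero_crossing(flow.samples, i0 + int(run[-1]), before=False)
            mid = 0.5 * (a + bnd)
            e1s.append(_trapz_frac(y, a, mid) / fs)
            e2s.append(_trapz_frac(y, mid, bnd) / fs)
            tes.append((bnd - a) / fs)
    e1 = float(np.mean(e1s))
    e2 = float(np.mean(e2s))
    return ExpirationStats(
        e1=e1,
        e2=e2,
        ratio=e2 / e1 if e1 > 0 else np.nan,
        te=float(np.mean(tes)),
        n_cycles=len(e1s),
        segment_starts=tuple(float(series.onsets[c]) for c in chosen),
    )
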