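"""Synthetic coupled respiratory-flow / arterial-pressure recordings.

Every recording carries exact ground-truth annotations so that each
downstream analysis (event scoring, variability, expiration shape, HRV
spectra, coherence, chemoreflex gains) can be validated by parameter
recovery.

Breath model
------------
Inspiration is a half-sine of duration ``ti`` (positive flow by
convention); expiration is an exponential decay whose time constant is
chosen per cycle so that the noise-free late/early expiratory area ratio
equals ``e2e1_target`` exactly:

    E2/E1 = exp(-te / (2 tau))  =>  tau = -te / (2 ln r)

Breath onset-to-onset intervals are ``60/rf`` plus AR(1) Gaussian jitter
whose *stationary* standard deviation is ``interval_jitter_sd`` (ms); the
AR coefficient maps to Poincare asymmetry via SD1 = sd*sqrt(1-phi),
SD2 = sd*sqrt(1+phi). Per-breath tidal volume is lognormal with
coefficient of variation ``vt_cv_pct``.

Apneas, hypopneas and sighs are inserted as a homogeneous Poisson process
(counts ~ Poisson(rate * duration/3600)) at well-separated breath slots;
each inserted event appears in the returned truth table with its exact
onset and duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from cardioresp.core_io import (
    AnnotationTable,
    GasProtocol,
    RecordingBundle,
    SignalTrace,
)

__all__ = [
    "SynthConfig",
    "generate_breathing",
    "generate_pressure",
    "generate_beat_times",
    "generate_chemo_session",
    "jitter_sd_for_sd2",
    "vt_cv_to_sigma",
]


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of a synthetic recording (deterministic given seed)."""

    duration: float = 600.0          # s
    seed: int = 0

    # breathing
    rf: float = 85.0                 # breaths/min
    vt: float = 0.32                 # mL per 100 g
    body_mass: float = 300.0         # g
    flow_rate: float = 200.0         # Hz, flow channel sampling
    ti_fraction: float = 0.4         # inspiratory fraction of the nominal cycle
    interval_jitter_sd: float = 35.0  # ms, stationary SD of AR(1) interval jitter
    interval_ar1: float = 0.4        # AR(1) coefficient in [0, 1)
    vt_cv_pct: float = 8.0           # % lognormal CV of per-breath VT
    vt_mod_freq: float = 0.1         # Hz, slow sinusoidal VT modulation
    vt_mod_depth: float = 0.0        # fractional depth of VT modulation
    e2e1_target: float = 0.89        # late/early expiratory area ratio
    noise_sd_flow: float = 0.03      # mL/s additive white noise

    # disordered-breathing events
    apnea_rate: float = 5.4          # events/h
    hypopnea_rate: float = 3.7       # events/h
    sigh_rate: float = 14.0          # events/h
    post_sigh_apnea_prob: float = 0.5
    hypopnea_depth: float = 0.4      # VT scale of an inserted hypopnea
    sigh_height: float = 2.0         # VT scale of an inserted sigh (scoring threshold is 1.5x)
    apnea_cycles: tuple[float, float] = (3.3, 4.5)  # uniform gap length, cycles

    # cardiovascular
    hr: float = 300.0                # beats/min
    sbp: float = 120.0               # mmHg
    dbp: float = 80.0                # mmHg
    pressure_rate: float = 500.0     # Hz
    lf_mod_freq: float = 0.3         # Hz, within 0.04-0.6
    lf_mod_depth: float = 4.0        # ms RR modulation amplitude
    hf_mod_depth: float = 4.0        # ms, frequency locked to rf/60 Hz
    rr_noise_ms: float = 1.0         # ms white RR jitter
    coupling_gain: float = 0.0       # mmHg per mL of VT deviation
    noise_sd_pressure: float = 0.5   # mmHg additive white noise

    # chemoreflex
    hcvr_gain: float = 4.0           # delta VE per % FICO2
    hvr_gain: float = 0.5            # delta VE per % FIO2 decrease
    resp_tau: float = 30.0           # s, first-order ventilatory time constant

    def __post_init__(self) -> None:
        if self.rf <= 0 or self.hr <= 0:
            raise ValueError("rf and hr must be > 0")
        for name in ("apnea_rate", "hypopnea_rate", "sigh_rate", "interval_jitter_sd", "vt_cv_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.interval_ar1 < 1):
            raise ValueError("interval_ar1 must be in [0, 1)")
        if not (0 <= self.post_sigh_apnea_prob <= 1):
            raise ValueError("post_sigh_apnea_prob must be in [0, 1]")
        if self.e2e1_target <= 0:
            raise ValueError("e2e1_target must be > 0")
        if not (0.04 <= self.lf_mod_freq <= 0.6):
            raise ValueError("lf_mod_freq must lie within the 0.04-0.6 Hz LF band")
        if self.sbp <= self.dbp:
            raise ValueError("require sbp > dbp")
        if not (0 < self.ti_fraction < 1):
            raise ValueError("ti_fraction must be in (0, 1)")

    @property
    def vt_ml(self) -> float:
        """Absolute tidal volume in mL."""
        return self.vt * self.body_mass / 100.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["apnea_cycles"] = list(d["apnea_cycles"])
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "SynthConfig":
        payload = dict(payload)
        if "apnea_cycles" in payload:
            payload["apnea_cycles"] = tuple(payload["apnea_cycles"])
        return cls(**payload)


def jitter_sd_for_sd2(sd2_ms: float, ar1: float) -> float:
    """Stationary jitter SD (ms) that yields a target Poincare SD2 under AR(1).

    For AR(1) with stationary variance s^2 and coefficient phi the lag-1
    autocorrelation is phi, hence SD2^2 = s^2 (1 + phi).
    """
    return sd2_ms / math.sqrt(1.0 + ar1)


def vt_cv_to_sigma(cv_pct: float) -> float:
    """Lognormal sigma giving a target coefficient of variation (percent)."""
    cv = cv_pct / 100.0
    return math.sqrt(math.log(1.0 + cv * cv))


# ---------------------------------------------------------------------------
# breath planning


@dataclass
class _Breath:
    onset: float
    interval: float
    ti: float
    vt: float
    gap_after: float = 0.0
    kind: str = "normal"   # normal | hypopnea | sigh
    gap_kind: str = ""     # apnea | post_sigh_apnea


def _plan_breaths(cfg: SynthConfig, rng: np.random.Generator, scale_fn=None) -> list[_Breath]:
    """Sequentially draw breath intervals and volumes (no events yet)."""
    mean_int = 60.0 / cfg.rf
    sd = cfg.interval_jitter_sd / 1000.0
    phi = cfg.interval_ar1
    sigma_vt = vt_cv_to_sigma(cfg.vt_cv_pct)
    # lognormal with unit mean: mu = -sigma^2/2
    mu_vt = -0.5 * sigma_vt * sigma_vt

    # plan past `duration` so that inserted gaps cannot leave a tail of silence
    gap_rate = cfg.apnea_rate + cfg.sigh_rate * cfg.post_sigh_apnea_prob
    expected_gap = gap_rate * cfg.duration / 3600.0 * np.mean(cfg.apnea_cycles) * mean_int
    plan_until = cfg.duration + 2.0 * expected_gap + 5.0 * mean_int

    jit = rng.normal(0.0, sd) if sd > 0 else 0.0
    breaths: list[_Breath] = []
    t = 0.0
    while t < plan_until:
        s = 1.0 if scale_fn is None else scale_fn(t)
        nominal = mean_int / s
        interval = max(nominal + jit, 0.3 * nominal)
        vt = cfg.vt_ml * s * math.exp(mu_vt + sigma_vt * rng.standard_normal()) if sigma_vt > 0 else cfg.vt_ml * s
        if cfg.vt_mod_depth > 0:
            vt *= 1.0 + cfg.vt_mod_depth * math.sin(2.0 * math.pi * cfg.vt_mod_freq * t)
        breaths.append(_Breath(onset=t, interval=interval, ti=cfg.ti_fraction * nominal, vt=vt))
        t += interval
        if sd > 0:
            jit = phi * jit + rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi))
    if len(breaths) < 4:
        raise ValueError("duration too short to plan breaths")
    return breaths


def _insert_events(cfg: SynthConfig, breaths: list[_Breath], rng: np.random.Generator) -> None:
    """Assign Poisson-drawn events to well-separated breath slots, in place."""
    mean_int = 60.0 / cfg.rf
    hours = cfg.duration / 3600.0
    event_time = (
        (cfg.apnea_rate + cfg.sigh_rate * cfg.post_sigh_apnea_prob) * np.mean(cfg.apnea_cycles) * mean_int
        + (cfg.hypopnea_rate + cfg.sigh_rate) * mean_int
    ) / 3600.0
    if event_time > 0.5:
        raise ValueError("event rates too high: > 50% of time would fall inside events")

    n_apnea = rng.poisson(cfg.apnea_rate * hours)
    n_hypo = rng.poisson(cfg.hypopnea_rate * hours)
    n_sigh = rng.poisson(cfg.sigh_rate * hours)

    # only anchor events on breaths that fully precede `duration`
    eligible = [i for i, b in enumerate(breaths[:-2]) if b.onset + b.interval < cfg.duration]
    margin, min_sep = 12, 10
    eligible = [i for i in eligible if i >= margin]
    order = rng.permutation(len(eligible))
    taken: list[int] = []

    def _next_slot() -> int:
        for pos in order[len(_next_slot.used):]:  # type: ignore[attr-defined]
            _next_slot.used.append(pos)
            i = eligible[pos]
            if all(abs(i - j) >= min_sep for j in taken):
                taken.append(i)
                return i
        raise ValueError("event rates too high to place without overlap")

    _next_slot.used = []  # type: ignore[attr-defined]

    for _ in range(n_apnea):
        i = _next_slot()
        breaths[i].gap_after = rng.uniform(*cfg.apnea_cycles) * mean_int
        breaths[i].gap_kind = "apnea"
    for _ in range(n_hypo):
        i = _next_slot()
        breaths[i].kind = "hypopnea"
        breaths[i].vt *= cfg.hypopnea_depth
    for _ in range(n_sigh):
        i = _next_slot()
        breaths[i].kind = "sigh"
        breaths[i].vt *= cfg.sigh_height
        if rng.random() < cfg.post_sigh_apnea_prob:
            breaths[i].gap_after = rng.uniform(*cfg.apnea_cycles) * mean_int
            breaths[i].gap_kind = "post_sigh_apnea"


def _apply_gaps(breaths: list[_Breath]) -> None:
    """Recompute onsets so that each gap shifts every later breath."""
    t = breaths[0].onset
    for b in breaths:
        b.onset = t
        t += b.interval + b.gap_after


def _truth_table(cfg: SynthConfig, breaths: list[_Breath]) -> AnnotationTable:
    truth = AnnotationTable()
    for b in breaths:
        end = b.onset + b.interval
        if end > cfg.duration:
            continue
        if b.kind == "hypopnea":
            truth.add("hypopnea", b.onset, b.interval)
        elif b.kind == "sigh":
            truth.add("sigh", b.onset, b.interval)
        if b.gap_kind and end + b.gap_after <= cfg.duration:
            truth.add(b.gap_kind, end, b.gap_after)
    return truth


def _render_flow(cfg: SynthConfig, breaths: list[_Breath], rng: np.random.Generator) -> SignalTrace:
    fs = cfg.flow_rate
    n = int(round(cfg.duration * fs))
    flow = np.zeros(n)
    log_r = math.log(cfg.e2e1_target)
    for b in breaths:
        i0 = int(round(b.onset * fs))
        if i0 >= n:
            break
        ti = b.ti
        te = b.interval - ti
        if te <= 0:
            continue
        # inspiratory half-sine: integral A * 2 ti / pi = vt
        ni = max(int(round(ti * fs)), 2)
        amp_i = math.pi * b.vt / (2.0 * ti)
        tt = np.arange(ni) / fs
        seg = amp_i * np.sin(math.pi * tt / ti)
        j1 = min(i0 + ni, n)
        flow[i0:j1] += seg[: j1 - i0]
        # expiratory exponential: tau from E2/E1 target, area matches vt
        tau = -te / (2.0 * log_r)
        amp_e = b.vt / (tau * (1.0 - math.exp(-te / tau)))
        ne = int(round(te * fs))
        if ne > 0:
            tt = np.arange(ne) / fs
            seg = -amp_e * np.exp(-tt / tau)
            j0 = i0 + ni
            j1 = min(j0 + ne, n)
            if j0 < n:
                flow[j0:j1] += seg[: j1 - j0]
    if cfg.noise_sd_flow > 0:
        flow += rng.normal(0.0, cfg.noise_sd_flow, size=n)
    return SignalTrace(flow, sampling_rate=fs, units="mL/s", label="flow")


def generate_breathing(config: SynthConfig) -> tuple[SignalTrace, AnnotationTable]:
    """Synthesize a flow trace plus exact truth annotations.

    Deterministic given ``config`` (including its seed); independent RNG
    substreams drive the breath plan, event placement and channel noise,
    so changing e.g. the noise level leaves the event schedule untouched.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_breath, rng_event, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    breaths = _plan_breaths(config, rng_breath)
    _insert_events(config, breaths, rng_event)
    _apply_gaps(breaths)
    truth = _truth_table(config, breaths)
    flow = _render_flow(config, breaths, rng_noise)
    return flow, truth


# ---------------------------------------------------------------------------
# arterial pressure


def generate_beat_times(
    config: SynthConfig, duration: float | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Beat times (s) with LF sinusoidal and respiration-locked HF RR modulation."""
    cfg = config
    if duration is None:
        duration = cfg.duration
    if rng is None:
        ss = np.random.SeedSequence(cfg.seed)
        rng = np.random.default_rng(ss.spawn(4)[3])
    rr0 = 60.0 / cfg.hr
    f_hf = cfg.rf / 60.0
    times = []
    t = 0.0
    while t < duration:
        times.append(t)
        rr = rr0 + (
            cfg.lf_mod_depth * math.sin(2.0 * math.pi * cfg.lf_mod_freq * t)
            + cfg.hf_mod_depth * math.sin(2.0 * math.pi * f_hf * t)
            + (cfg.rr_noise_ms * rng.standard_normal() if cfg.rr_noise_ms > 0 else 0.0)
        ) / 1000.0
        t += max(rr, 0.3 * rr0)
    return np.asarray(times)


def _pulse_shape(phase: np.ndarray, rise: float = 0.25, decay_k: float = 3.0) -> np.ndarray:
    """Normalized pulse in [0, 1]: quarter-sine upstroke then exponential run-off.

    Equals 1 at ``phase == rise`` and exactly 0 at phase 0 and 1, so the
    per-cycle max/min recover systolic/diastolic levels exactly.
    """
    shape = np.empty_like(phase)
    up = phase < rise
    shape[up] = np.sin(0.5 * math.pi * phase[up] / rise)
    ph = phase[~up]
    e_end = math.exp(-decay_k * (1.0 - rise))
    shape[~up] = (np.exp(-decay_k * (ph - rise)) - e_end) / (1.0 - e_end)
    return shape


def generate_pressure(config: SynthConfig, breathing=None) -> SignalTrace:
    """500-Hz arterial pressure with per-beat SBP coupled to VT deviations.

    ``breathing`` may be a ``BreathSeries`` (from breath segmentation), a
    ``(times, vt)`` array pair, or ``None`` (required only when
    ``coupling_gain`` is zero).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    beat_times = generate_beat_times(cfg, rng=rng)
    n_beats = beat_times.size
    sbp_per_beat = np.full(n_beats, cfg.sbp)

    if cfg.coupling_gain != 0.0:
        if breathing is None:
            raise ValueError("coupling_gain > 0 requires a breathing signal")
        if hasattr(breathing, "onsets") and hasattr(breathing, "vt"):
            bt, bv = np.asarray(breathing.onsets), np.asarray(breathing.vt)
        else:
            bt, bv = (np.asarray(a, dtype=float) for a in breathing)
        dev = bv - bv.mean()
        sbp_per_beat = cfg.sbp + cfg.coupling_gain * np.interp(beat_times, bt, dev)

    fs = cfg.pressure_rate
    n = int(round(cfg.duration * fs))
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(beat_times, t, side="right") - 1, 0, n_beats - 1)
    nxt = np.where(idx + 1 < n_beats, idx + 1, idx)
    span = np.where(nxt > idx, beat_times[nxt] - beat_times[idx], 60.0 / cfg.hr)
    phase = np.clip((t - beat_times[idx]) / span, 0.0, 1.0)
    pp = sbp_per_beat[idx] - cfg.dbp
    pressure = cfg.dbp + pp * _pulse_shape(phase)
    if cfg.noise_sd_pressure > 0:
        pressure = pressure + rng.normal(0.0, cfg.noise_sd_pressure, size=n)
    return SignalTrace(pressure, sampling_rate=fs, units="mmHg", label="pressure")


# ---------------------------------------------------------------------------
# gas-challenge sessions


def generate_chemo_session(
    config: SynthConfig, protocol: GasProtocol
) -> tuple[RecordingBundle, AnnotationTable]:
    """Recording whose minute ventilation follows a first-order response.

    The ventilatory target is ``ve0 + hcvr_gain * FICO2 + hvr_gain *
    max(0, 21 - FIO2)`` with time constant ``resp_tau``; the response is
    realized by scaling tidal volume and respiratory rate equally (each by
    the square root of the ventilation ratio).
    """
    cfg = config
    if not protocol.segments:
        raise ValueError("protocol is empty")
    span = protocol.end - protocol.start
    if abs(span - cfg.duration) > 1e-9:
        cfg = SynthConfig(**{**cfg.to_dict(), "duration": span, "apnea_cycles": cfg.apnea_cycles})

    ve0 = cfg.vt_ml * cfg.rf  # mL/min at baseline
    state = {"t": 0.0, "ve": ve0}

    def target(t: float) -> float:
        # gains are per 100 g (paper units); convert to absolute mL/min
        seg = protocol.at(protocol.start + min(t, span - 1e-9))
        drive = cfg.hcvr_gain * seg.fico2 + cfg.hvr_gain * max(0.0, 21.0 - seg.fio2)
        return ve0 + drive * cfg.body_mass / 100.0

    def scale_fn(t: float) -> float:
        # exact piecewise-exponential relaxation toward the current target
        tgt = target(t)
        dt = t - state["t"]
        if cfg.resp_tau <= 0:
            state["ve"] = tgt
        else:
            state["ve"] = tgt + (state["ve"] - tgt) * math.exp(-dt / cfg.resp_tau)
        state["t"] = t
        return math.sqrt(max(state["ve"], 1e-9) / ve0)

    ss = np.random.SeedSequence(cfg.seed)
    rng_breath, rng_event, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    breaths = _plan_breaths(cfg, rng_breath, scale_fn=scale_fn)
    _insert_events(cfg, breaths, rng_event)
    _apply_gaps(breaths)
    truth = _truth_table(cfg, breaths)
    flow = _render_flow(cfg, breaths, rng_noise)
    flow = SignalTrace(
        flow.samples, flow.sampling_rate, flow.units, start_time=protocol.start, label=flow.label
    )
    bundle = RecordingBundle(flow=flow, body_mass=cfg.body_mass, protocol=protocol, subject_id="synthetic")
    return bundle, truth
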