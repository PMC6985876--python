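"""Chemoreflex gains (HVR, HCVR), the episodic-stimulation schedule, and
post-stimulation ventilatory-plasticity deltas.

HCVR is the slope of minute ventilation between inspired CO2 fractions
of 0.03 % and 7 %; HVR the slope between inspired O2 of 21 % and 10 %,
reported per % FIO2 *decrease* so that a normal response is positive
(the raw signed slope is kept alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

from cardioresp.breath import VentilationSummary
from cardioresp.core_io import GasProtocol, GasSegment

__all__ = ["ChemoreflexGain", "PlasticityResult", "ehs_schedule", "chemoreflex_gain", "post_ehs_deltas"]

HCVR_LEVELS = (0.03, 7.0)   # % FICO2
HVR_LEVELS = (21.0, 10.0)   # % FIO2


@dataclass(frozen=True)
class ChemoreflexGain:
    gain: float                     # delta VE per % (per % FIO2 decrease for hvr)
    raw_slope: float                # signed slope d(VE)/d(level)
    mode: str                       # "hvr" | "hcvr"
    levels: tuple[float, float]
    ve: tuple[float, float]         # VE at each level, mL . 100 g^-1 . min^-1


@dataclass(frozen=True)
class PlasticityResult:
    minutes: float                  # time post-stimulation
    delta_vt: float                 # mL / 100 g, post - pre
    delta_rf: float                 # breaths/min
    delta_ve: float                 # mL . 100 g^-1 . min^-1


def ehs_schedule(
    n_cycles: int = 10,
    stim_s: float = 300.0,
    rest_s: float = 300.0,
    fico2: float = 7.0,
    fio2: float = 21.0,
    rest_fico2: float = 0.03,
    start: float = 0.0,
) -> GasProtocol:
    """Alternating hypercapnic/normocapnic segments, beginning with stimulation.

    Defaults reproduce 10 cycles of 5-min 7 % CO2 spaced by 5-min
    normoxic rests (20 segments, 6000 s).
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if stim_s <= 0 or rest_s <= 0:
        raise ValueError("durations must be positive")
    segments = []
    t = start
    for _ in range(n_cycles):
        segments.append(GasSegment(start=t, end=t + stim_s, fio2=fio2, fico2=fico2))
        t += stim_s
        segments.append(GasSegment(start=t, end=t + rest_s, fio2=fio2, fico2=rest_fico2))
        t += rest_s
    return GasProtocol(tuple(segments))


def chemoreflex_gain(ve_by_level: dict[float, VentilationSummary], mode: str) -> ChemoreflexGain:
    """Two-point ventilatory-response slope for ``mode`` in {"hvr", "hcvr"}.

    ``ve_by_level`` maps the inspired-gas percentage to the ventilation
    summary measured at that level; exactly the canonical level pair is
    required ((21, 10) for hvr, (0.03, 7) for hcvr).
    """
    if mode == "hcvr":
        levels = HCVR_LEVELS
    elif mode == "hvr":
        levels = HVR_LEVELS
    else:
        raise ValueError("mode must be 'hvr' or 'hcvr'")
    try:
        summaries = [ve_by_level[level] for level in levels]
    except KeyError as exc:
        raise ValueError(f"missing ventilation summary for level {exc.args[0]}% (mode={mode})") from exc
    ve = tuple(s.ve for s in summaries)
    raw_slope = (ve[1] - ve[0]) / (levels[1] - levels[0])
    # hvr reported per % FIO2 decrease => flip the sign of the raw slope
    gain = raw_slope if mode == "hcvr" else -raw_slope
    return ChemoreflexGain(gain=gain, raw_slope=raw_slope, mode=mode, levels=levels, ve=ve)


def post_ehs_deltas(
    pre: VentilationSummary,
    post_series: list[tuple[float, VentilationSummary]],
) -> list[PlasticityResult]:
    """Per-timepoint post-minus-pre ventilation deltas (depression => negative)."""
    if pre is None:
        raise ValueError("missing baseline summary")
    out = []
    for minutes, post in post_series:
        out.append(
            PlasticityResult(
                minutes=float(minutes),
                delta_vt=post.vt_per100g - pre.vt_per100g,
                delta_rf=post.rf - pre.rf,
                delta_ve=post.ve - pre.ve,
            )
        )
    return out
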