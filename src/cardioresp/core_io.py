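"""Domain types and CSV/YAML readers and writers.

Conventions: time is in seconds from recording start, rates in Hz,
sample indexing is 0-based and windows are half-open ``[t0, t1)``.
CSV is the canonical interchange format for both signals and
annotations; gas protocols are YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

VALID_UNITS = ("mL/s", "mmHg", "ms", "dimensionless")
EVENT_KINDS = ("apnea", "hypopnea", "sigh", "post_sigh_apnea")

#: maximum tolerated relative jitter of a time column before the file is
#: rejected as non-uniformly sampled
UNIFORMITY_TOL = 0.01

_FLOAT_FMT = "%.17g"  # exact float round-trip, still deterministic text


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled physiological time series."""

    samples: np.ndarray
    sampling_rate: float
    units: str = "dimensionless"
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("non-finite samples in signal")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class Annotation:
    kind: str
    onset: float
    duration: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


class AnnotationTable:
    """Ordered, typed respiratory events (apnea/hypopnea/sigh/post-sigh apnea)."""

    def __init__(self, events: list[Annotation] | None = None):
        events = sorted(events or [], key=lambda e: e.onset)
        self.events: list[Annotation] = events

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.events == other.events

    def add(self, kind: str, onset: float, duration: float, **attributes) -> None:
        self.events.append(Annotation(kind, float(onset), float(duration), attributes))
        self.events.sort(key=lambda e: e.onset)

    def of_kind(self, kind: str) -> list[Annotation]:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        return [e for e in self.events if e.kind == kind]

    def onsets(self, kind: str | None = None) -> np.ndarray:
        events = self.events if kind is None else self.of_kind(kind)
        return np.array([e.onset for e in events], dtype=float)


@dataclass(frozen=True)
class GasSegment:
    start: float
    end: float
    fio2: float
    fico2: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("segment must satisfy start < end")
        if not (0 < self.fio2 <= 100):
            raise ValueError("fio2 must be in (0, 100]")
        if not (0 <= self.fico2 <= 100):
            raise ValueError("fico2 must be in [0, 100]")


@dataclass(frozen=True)
class GasProtocol:
    """Contiguous, non-overlapping FIO2/FICO2 schedule."""

    segments: tuple[GasSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("protocol must contain at least one segment")
        for a, b in zip(segs, segs[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("protocol segments must be contiguous and non-overlapping")
        object.__setattr__(self, "segments", segs)

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def at(self, t: float) -> GasSegment:
        """Segment active at time ``t`` (half-open segments; last end inclusive)."""
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg
        if np.isclose(t, self.end):
            return self.segments[-1]
        raise ValueError(f"time {t} outside protocol span [{self.start}, {self.end}]")


@dataclass(frozen=True)
class RecordingBundle:
    flow: SignalTrace
    body_mass: float
    subject_id: str = ""
    pressure: SignalTrace | None = None
    protocol: GasProtocol | None = None

    def __post_init__(self) -> None:
        if not (self.body_mass > 0):
            raise ValueError("body_mass must be > 0")
        if self.pressure is not None:
            if self.pressure.start_time >= self.flow.end_time or self.flow.start_time >= self.pressure.end_time:
                raise ValueError("flow and pressure time ranges do not overlap")


# ---------------------------------------------------------------------------
# signal I/O


def write_signal(trace: SignalTrace, path: str | Path) -> Path:
    """Write a trace as headered CSV.

    The header comments carry label, units, sampling rate and start time so
    that :func:`read_signal` can rebuild the trace exactly. Fixed ``%.9g``
    float formatting makes the file bit-stable.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {trace.label}\n")
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# sampling_rate: {_FLOAT_FMT % trace.sampling_rate}\n")
        fh.write(f"# start_time: {_FLOAT_FMT % trace.start_time}\n")
        fh.write("value\n")
        fh.writelines(_FLOAT_FMT % v + "\n" for v in trace.samples)
    return path


def read_signal(
    path: str | Path,
    value_column: str | int = "value",
    time_column: str | int | None = None,
    sampling_rate: float | None = None,
    units: str | None = None,
) -> SignalTrace:
    """Read a delimited-text signal.

    Files written by :func:`write_signal` need no extra arguments. For
    foreign CSV, pass a ``value_column`` plus either ``sampling_rate`` or a
    ``time_column`` with uniform spacing (rejected above 1 % jitter).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    import pandas as pd

    frame = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    values = np.asarray(_column(frame, value_column), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in signal file")

    if sampling_rate is None and "sampling_rate" in meta:
        sampling_rate = float(meta["sampling_rate"])
    start_time = float(meta.get("start_time", 0.0))
    if time_column is not None:
        t = np.asarray(_column(frame, time_column), dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("time column must be strictly increasing")
        if (dt.max() - dt.min()) / dt.mean() > UNIFORMITY_TOL:
            raise ValueError("non-uniform sampling (> 1% jitter)")
        sampling_rate = 1.0 / dt.mean()
        start_time = t[0]
    if sampling_rate is None:
        raise ValueError("sampling_rate not given and no time column or header present")
    return SignalTrace(
        samples=values,
        sampling_rate=float(sampling_rate),
        units=units or meta.get("units", "dimensionless"),
        start_time=start_time,
        label=meta.get("label", ""),
    )


def _column(frame, spec):
    if isinstance(spec, int):
        return frame.iloc[:, spec]
    return frame[spec]


# ---------------------------------------------------------------------------
# annotation I/O


def write_annotations(table: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("kind,onset,duration,attributes\n")
        for ev in table:
            attrs = json.dumps(ev.attributes, sort_keys=True).replace('"', '""')
            fh.write(f'{ev.kind},{_FLOAT_FMT % ev.onset},{_FLOAT_FMT % ev.duration},"{attrs}"\n')
    return path


def read_annotations(path: str | Path) -> AnnotationTable:
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    events = []
    for row in frame.itertuples(index=False):
        attrs = json.loads(row.attributes) if isinstance(row.attributes, str) else {}
        events.append(Annotation(str(row.kind), float(row.onset), float(row.duration), attrs))
    return AnnotationTable(events)


# ---------------------------------------------------------------------------
# protocol I/O


def write_protocol(protocol: GasProtocol, path: str | Path) -> Path:
    payload = {
        "segments": [
            {"start": float(s.start), "end": float(s.end), "fio2": float(s.fio2), "fico2": float(s.fico2)}
            for s in protocol.segments
        ]
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def read_protocol(path: str | Path) -> GasProtocol:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return GasProtocol(tuple(GasSegment(**seg) for seg in payload["segments"]))


# ---------------------------------------------------------------------------


def slice_trace(trace: SignalTrace, t0: float, t1: float) -> SignalTrace:
    """Sub-trace over the half-open window ``[t0, t1)`` (absolute seconds)."""
    if not (t0 < t1):
        raise ValueError("require t0 < t1")
    if t0 < trace.start_time - 0.5 / trace.sampling_rate or t1 > trace.end_time + 0.5 / trace.sampling_rate:
        raise ValueError("window outside trace span")
    i0 = int(round((t0 - trace.start_time) * trace.sampling_rate))
    i1 = int(round((t1 - trace.start_time) * trace.sampling_rate))
    i0 = max(i0, 0)
    i1 = min(i1, len(trace))
    if i1 - i0 < 2:
        raise ValueError("window too short")
    return replace(trace, samples=trace.samples[i0:i1], start_time=trace.start_time + i0 / trace.sampling_rate)
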