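"""Force–velocity analysis of stall-containing trap traces.

Full-rate (5 kHz) traces are median filtered (200-point window), maximal
contiguous passages through 1-pN-wide force bins centered on 2, 3, 4 and
5 pN are extracted, and the average velocity of each passage is estimated
as the force change across the passage divided by the trap spring constant
and the passage duration:

    v = delta_F / (k * delta_t)     [nm/s]

Passages with negative average velocity (detachment events, motor not
engaged) are excluded from the curve.  The curve reports mean +/- SEM and
event counts per bin, pooled across traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import TrapTrace


class ForceVelocityError(ValueError):
    pass


@dataclass(frozen=True)
class FVParams:
    median_window: int = 200               # samples; odd-adjusted internally
    bin_centers: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    bin_width: float = 1.0
    spring_constant: float = 0.06          # pN/nm
    min_event_samples: int = 25            # 5 ms at 5 kHz

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ForceVelocityError("bin_width must be > 0")
        if self.spring_constant <= 0:
            raise ForceVelocityError("spring_constant must be > 0")
        centers = sorted(self.bin_centers)
        for a, b in zip(centers, centers[1:]):
            if b - a < self.bin_width:
                raise ForceVelocityError("overlapping force bins")


@dataclass
class BinEvent:
    trace_id: str
    bin_center: float
    t_enter: float
    t_exit: float
    delta_force: float
    duration: float

    @property
    def velocity(self) -> float:
        raise AttributeError("use event_velocity(event, spring_constant)")


@dataclass
class FVCurve:
    bin_centers: np.ndarray
    mean_velocity: np.ndarray   # nm/s; NaN where n_events == 0
    sem: np.ndarray
    n_events: np.ndarray


def median_filter(trace: TrapTrace, window: int = 200) -> TrapTrace:
    """Running median; even windows are widened to the next odd size and
    edge windows are truncated, so output length equals input length."""
    if window < 3:
        raise ForceVelocityError("median window must be >= 3")
    if window > len(trace):
        raise ForceVelocityError("median window exceeds trace length")
    if window % 2 == 0:
        window += 1
    filt = pd.Series(trace.force).rolling(
        window, center=True, min_periods=1).median().to_numpy()
    return TrapTrace(times=trace.times, force=filt,
                     spring_constant=trace.spring_constant,
                     sample_rate=trace.sample_rate, label=trace.label,
                     ground_truth=trace.ground_truth)


def extract_bin_events(trace: TrapTrace, params: FVParams) -> list[BinEvent]:
    """Maximal contiguous runs with force in ``[c - w/2, c + w/2)``.

    Runs shorter than ``min_event_samples`` are dropped.  ``delta_force``
    is force at exit minus force at entry.
    """
    params.validate()
    f = trace.force
    t = trace.times
    events: list[BinEvent] = []
    half = params.bin_width / 2.0
    for c in params.bin_centers:
        mask = (f >= c - half) & (f < c + half)
        idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        for a, b in zip(idx[::2], idx[1::2]):   # [a, b) is a run
            if b - a < max(2, params.min_event_samples):
                continue
            events.append(BinEvent(
                trace_id=trace.label, bin_center=c,
                t_enter=float(t[a]), t_exit=float(t[b - 1]),
                delta_force=float(f[b - 1] - f[a]),
                duration=float(t[b - 1] - t[a])))
    events.sort(key=lambda e: (e.bin_center, e.t_enter))
    return events


def event_velocity(event: BinEvent, spring_constant: float) -> float:
    """Average velocity of one bin passage: ``delta_F / (k * delta_t)``."""
    if event.duration <= 0:
        raise ForceVelocityError("zero-duration event")
    return event.delta_force / (spring_constant * event.duration)


def force_velocity_curve(traces: list[TrapTrace], params: FVParams,
                         prefiltered: bool = False) -> FVCurve:
    """Median-filter each trace, extract bin passages, and average the
    non-negative passage velocities per bin (pooled across traces).

    Traces are processed individually and pooled afterwards, so passages
    never span trace boundaries.
    """
    if not traces:
        raise ForceVelocityError("no traces supplied")
    params.validate()
    velocities: dict[float, list[float]] = {c: [] for c in params.bin_centers}
    for trace in traces:
        filt = trace if prefiltered else median_filter(trace, params.median_window)
        for ev in extract_bin_events(filt, params):
            v = event_velocity(ev, params.spring_constant)
            if v >= 0:
                velocities[ev.bin_center].append(v)

    centers = np.array(sorted(params.bin_centers))
    mean = np.full(centers.size, np.nan)
    sem = np.full(centers.size, np.nan)
    n = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        vs = np.array(velocities[c])
        n[i] = vs.size
        if vs.size:
            mean[i] = vs.mean()
            sem[i] = vs.std(ddof=1) / math.sqrt(vs.size) if vs.size > 1 else 0.0
    return FVCurve(bin_centers=centers, mean_velocity=mean, sem=sem, n_events=n)
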