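"""Stall detection in downsampled optical-trap traces.

A stall is a stationary period of the bead above a force threshold that is
terminated by the bead snapping back to the trap center (detachment) or by
resumed motion.  Definitions follow the fixed-trap convention:

* traces are block-mean downsampled to the analysis rate (250 Hz default);
* "stationary" means the centered rolling standard deviation of the force
  stays below a bound;
* stall force = mean force over the last 20% of the event samples;
* stall time = duration of the contiguous run of samples at >= 80% of the
  stall force ending at the event end (total supra-threshold time is
  available as an option).

Wild-type and mutant analysis presets encode the published thresholds
(> 2.5 pN for > 100 ms, and > 1 pN for > 150 ms, respectively).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .synthetic_data import TrapTrace


class StallAnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class StallCriteria:
    """Detection thresholds.  Forces pN, durations/windows ms, rate Hz."""

    min_force: float = 2.5
    min_duration: float = 100.0
    stationarity_sd_max: float = 0.35
    stationarity_window: float = 40.0
    snap_drop_fraction: float = 0.5
    snap_max_time: float = 20.0
    analysis_rate: float = 250.0

    def validate(self) -> None:
        if self.min_force <= 0:
            raise StallAnalysisError("min_force must be > 0")
        if self.min_duration <= 0:
            raise StallAnalysisError("min_duration must be > 0")
        if not 0 < self.snap_drop_fraction <= 1:
            raise StallAnalysisError("snap_drop_fraction must be in (0, 1]")
        if self.stationarity_window > self.min_duration:
            raise StallAnalysisError(
                "stationarity_window must not exceed min_duration")

    @classmethod
    def wt_preset(cls, **overrides) -> "StallCriteria":
        """Stationary periods at forces > 2.5 pN lasting > 100 ms."""
        return replace(cls(), **overrides)

    @classmethod
    def mutant_preset(cls, **overrides) -> "StallCriteria":
        """Stationary periods at forces > 1 pN lasting > 150 ms."""
        return replace(cls(min_force=1.0, min_duration=150.0), **overrides)


@dataclass
class StallEvent:
    trace_id: str
    start_time: float
    end_time: float
    stall_force: float
    stall_time: float
    outcome: Literal["detach", "resume", "censored"]


def downsample(trace: TrapTrace, target_rate: float) -> TrapTrace:
    """Non-overlapping block-mean downsampling (preserves the trace mean)."""
    ratio = trace.sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise StallAnalysisError(
            f"target rate {target_rate} Hz does not divide "
            f"sample rate {trace.sample_rate} Hz")
    m = int(round(ratio))
    if m == 1:
        return trace
    n_blocks = len(trace) // m
    force = trace.force[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    times = trace.times[: n_blocks * m : m]
    return TrapTrace(times=times, force=force,
                     spring_constant=trace.spring_constant,
                     sample_rate=target_rate, label=trace.label,
                     ground_truth=trace.ground_truth)


def _rolling_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling SD; edges (incomplete windows) return +inf."""
    out = np.full(x.size, np.inf)
    if window > x.size:
        return out
    sw = np.lib.stride_tricks.sliding_window_view(x, window)
    sd = sw.std(axis=1, ddof=0)
    lo = (window - 1) // 2
    out[lo: lo + sd.size] = sd
    return out


def stall_force(samples: np.ndarray) -> float:
    """Mean force over the last 20% (ceil rule) of the event samples."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 5:
        raise StallAnalysisError(f"stall event has only {n} samples (< 5)")
    k = math.ceil(0.2 * n)
    return float(samples[-k:].mean())


def stall_time(samples: np.ndarray, stall_force_pn: float, sample_rate: float,
               mode: Literal["contiguous", "total"] = "contiguous") -> float:
    """Time spent at >= 80% of the stall force.

    ``contiguous`` (default): the run of supra-threshold samples ending at
    the event end — the dwell terminated by detachment.  ``total``: all
    supra-threshold samples in the event.
    """
    samples = np.asarray(samples, dtype=float)
    above = samples >= 0.8 * stall_force_pn
    dt = 1.0 / sample_rate
    if mode == "total":
        return float(above.sum() * dt)
    n = 0
    for a in above[::-1]:
        if not a:
            break
        n += 1
    return n * dt


def detect_stalls(trace: TrapTrace, criteria: StallCriteria,
                  stall_time_mode: Literal["contiguous", "total"] = "contiguous",
                  ) -> list[StallEvent]:
    """Find maximal stationary supra-threshold intervals and score them.

    The trace must already be at ``criteria.analysis_rate`` (use
    :func:`downsample` first).  Events shorter than ``min_duration`` are
    dropped; the outcome is ``detach`` if the force falls by at least
    ``snap_drop_fraction * stall_force`` within ``snap_max_time`` after the
    event, ``censored`` if the trace ends first, else ``resume``.
    """
    criteria.validate()
    if len(trace) == 0:
        raise StallAnalysisError("empty trace")
    if abs(trace.sample_rate - criteria.analysis_rate) > 1e-6:
        raise StallAnalysisError(
            f"trace at {trace.sample_rate} Hz; downsample to "
            f"{criteria.analysis_rate} Hz first")

    rate = criteria.analysis_rate
    f = trace.force
    window = max(2, int(round(criteria.stationarity_window * 1e-3 * rate)))
    sd = _rolling_sd(f, window)
    mask = (sd <= criteria.stationarity_sd_max) & (f > criteria.min_force)

    min_samples = int(round(criteria.min_duration * 1e-3 * rate))
    snap_samples = max(1, int(round(criteria.snap_max_time * 1e-3 * rate)))

    events: list[StallEvent] = []
    n = f.size
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        # [i, j) is a maximal stationary supra-threshold run
        if (j - i) > min_samples and (j - i) >= 5:
            f_stall = stall_force(f[i:j])
            # the centered stationarity window ends the run up to half a
            # window before the actual snap; include that margin in the
            # lookahead
            look = snap_samples + window
            if j + look > n:
                outcome = "censored"
                end = j
            else:
                after = f[j: j + look]
                drop_level = f_stall - criteria.snap_drop_fraction * f_stall
                outcome = "detach" if after.min() <= drop_level else "resume"
                end = j
                if outcome == "detach":
                    # samples still at stall level up to the snap belong to
                    # the event (lost only to the rolling-window edge)
                    while end < j + look and f[end] >= 0.8 * f_stall:
                        end += 1
            seg = f[i:end]
            f_stall = stall_force(seg)
            t_stall = stall_time(seg, f_stall, rate, mode=stall_time_mode)
            events.append(StallEvent(
                trace_id=trace.label, start_time=float(trace.times[i]),
                end_time=float(trace.times[end - 1] + 1.0 / rate),
                stall_force=f_stall, stall_time=t_stall, outcome=outcome))
        i = j
    return events
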