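"""Classification and quantification of single-particle TIRF tracks.

Kymograph-derived (time, position) tracks are classified per the standard
single-molecule motility rules: binding events shorter than 1.5 s are not
counted; a counted track is *processive* if it contains a directed
displacement segment of at least 500 nm, *static* if its total positional
range stays within a localization-scale bound (250 nm default, ~2.4 pixels
at 105 nm/pixel), and *diffusive* otherwise.

Because complexes can change speed during a run, the mean velocity of a
processive track is the unweighted mean over piecewise-linear velocity
segments rather than net displacement over total time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class MotilityError(ValueError):
    pass


PIXEL_SIZE_NM = 105.0

CLASSES = ("processive", "static", "diffusive")


@dataclass
class Track:
    """Single-particle trajectory; positions in nm, minus-end-positive."""

    times: np.ndarray
    positions: np.ndarray
    pixel_size: float = PIXEL_SIZE_NM
    frame_interval: float = 0.5
    track_id: str = ""
    microtubule_id: str = ""
    ground_truth_mode: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.size < 2:
            raise MotilityError("track needs >= 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise MotilityError("track times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class MotilityParams:
    min_binding_duration: float = 1.5       # s
    min_processive_run: float = 500.0       # nm
    static_displacement_max: float = 250.0  # nm
    segment_tolerance: float = 50.0         # nm RMS
    directed_t_min: float = 6.0             # drift-vs-fluctuation t statistic
    directed_min_increments: int = 10        # noisy windows need >= this many

    def validate(self) -> None:
        for name in ("min_binding_duration", "min_processive_run",
                     "static_displacement_max", "segment_tolerance"):
            if getattr(self, name) <= 0:
                raise MotilityError(f"{name} must be > 0")


def _has_directed_run(pos: np.ndarray, min_run: float, t_min: float,
                      min_increments: int) -> bool:
    """True if some window has |net displacement| >= min_run with the mean
    frame increment dominating its standard error (t >= t_min).

    The t statistic ``mean(d) / (sd(d) / sqrt(m))`` over the window's frame
    increments separates drift from Brownian wander: noise-free directed
    motion has sd 0 (always qualifies), while a random walk achieving a
    500-nm excursion almost never shows a significant increment mean.
    Noisy windows shorter than ``min_increments`` increments are not
    considered — the t statistic has too heavy a tail there.
    """
    n = pos.size
    inc = np.diff(pos)
    for i in range(n - 1):
        for j in range(i + 1, n):
            disp = pos[j] - pos[i]
            if abs(disp) < min_run:
                continue
            seg = inc[i:j]
            sd = seg.std(ddof=1) if seg.size > 1 else 0.0
            if sd == 0.0:
                return True
            if seg.size < min_increments:
                continue
            t = abs(seg.mean()) / (sd / math.sqrt(seg.size))
            if t >= t_min:
                return True
    return False


def classify_track(track: Track, params: MotilityParams = MotilityParams()
                   ) -> str:
    """Classify one track as excluded / processive / static / diffusive."""
    params.validate()
    if track.duration < params.min_binding_duration:
        return "excluded"
    pos = track.positions
    if _has_directed_run(pos, params.min_processive_run,
                         params.directed_t_min,
                         params.directed_min_increments):
        return "processive"
    if np.ptp(pos) <= params.static_displacement_max:
        return "static"
    return "diffusive"


@dataclass
class VelocitySegment:
    t_start: float
    t_end: float
    velocity: float   # nm/s


def _segment_rms(t: np.ndarray, x: np.ndarray) -> float:
    """RMS residual of the least-squares line through (t, x)."""
    if t.size < 3:
        return 0.0
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(np.sqrt(np.mean((x - A @ coef) ** 2)))


def segment_velocities(track: Track,
                       params: MotilityParams = MotilityParams()
                       ) -> list[VelocitySegment]:
    """Piecewise-linear segmentation by bottom-up merging.

    Adjacent segments are merged greedily (smallest merged residual first)
    while the merged segment's RMS deviation from its least-squares line
    stays within ``segment_tolerance``.  Each segment's velocity is its
    least-squares slope.
    """
    t, x = track.times, track.positions
    if t.size < 3:
        raise MotilityError("track shorter than 3 points")
    # start from minimal 2-point segments: boundaries are index ranges
    bounds = list(range(0, t.size, 2))
    if bounds[-1] != t.size - 1:
        bounds.append(t.size - 1)
    # bounds[i]..bounds[i+1] inclusive is a segment
    while len(bounds) > 2:
        costs = []
        for i in range(len(bounds) - 2):
            a, b = bounds[i], bounds[i + 2]
            costs.append(_segment_rms(t[a:b + 1], x[a:b + 1]))
        best = int(np.argmin(costs))
        if costs[best] > params.segment_tolerance:
            break
        del bounds[best + 1]

    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        tt, xx = t[a:b + 1], x[a:b + 1]
        slope = np.polyfit(tt, xx, 1)[0]
        segments.append(VelocitySegment(t_start=float(tt[0]),
                                        t_end=float(tt[-1]),
                                        velocity=float(slope)))
    return segments


def mean_segment_velocity(track: Track,
                          params: MotilityParams = MotilityParams()) -> float:
    """Unweighted mean of per-segment velocities of a processive track."""
    segs = segment_velocities(track, params)
    return float(np.mean([s.velocity for s in segs]))


def run_length(track: Track, total_path: bool = False) -> float:
    """Net minus-end-directed displacement from first to last point.

    With ``total_path=True`` the summed absolute path length is returned
    instead.
    """
    if total_path:
        return float(np.abs(np.diff(track.positions)).sum())
    return float(track.positions[-1] - track.positions[0])


@dataclass
class MotilitySummary:
    microtubule_id: str
    fraction_processive: float
    fraction_static: float
    fraction_diffusive: float
    mean_velocity: float      # nm/s over processive tracks (NaN if none)
    mean_run_length: float    # nm over processive tracks (NaN if none)
    n_tracks: int             # counted (non-excluded) tracks


def summarize_motility(tracks: list[Track],
                       params: MotilityParams = MotilityParams()
                       ) -> list[MotilitySummary]:
    """Per-microtubule class fractions, velocities and run lengths.

    Fractions are computed over counted (non-excluded) tracks and sum to 1.
    """
    by_mt: dict[str, list[Track]] = {}
    for tr in tracks:
        by_mt.setdefault(tr.microtubule_id, []).append(tr)

    summaries = []
    any_counted = False
    for mt_id, group in sorted(by_mt.items()):
        labels = [classify_track(tr, params) for tr in group]
        counted = [(tr, lab) for tr, lab in zip(group, labels)
                   if lab != "excluded"]
        if not counted:
            continue
        any_counted = True
        n = len(counted)
        frac = {c: sum(1 for _, lab in counted if lab == c) / n
                for c in CLASSES}
        proc = [tr for tr, lab in counted if lab == "processive"]
        vel = float(np.mean([mean_segment_velocity(tr, params)
                             for tr in proc])) if proc else float("nan")
        rl = float(np.mean([run_length(tr) for tr in proc])) \
            if proc else float("nan")
        summaries.append(MotilitySummary(
            microtubule_id=mt_id, fraction_processive=frac["processive"],
            fraction_static=frac["static"],
            fraction_diffusive=frac["diffusive"],
            mean_velocity=vel, mean_run_length=rl, n_tracks=n))
    if not any_counted:
        raise MotilityError("all tracks excluded (< minimum binding duration)")
    return summaries
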