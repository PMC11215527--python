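"""Population statistics over trap traces and stall events.

* Pooled, normalized force-probability histograms across traces.
* Deterministic three-Gaussian least-squares fit of the histogram; the
  component nearest 0 pN is the "unbound" peak (bead not tethered to the
  microtubule) and can be subtracted bin-wise from the histogram.
* Double-exponential survival (1-CDF) fits of stall times.
* Per-construct stall summaries (mean +/- SEM of stall force, stall time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax

from .stall_analysis import StallEvent
from .synthetic_data import TrapTrace


class ForceStatsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Force histograms and Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class ForceHistogram:
    bin_edges: np.ndarray    # pN, length n_bins + 1
    probability: np.ndarray  # normalized frequency per bin, length n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class GaussianMixtureFit:
    components: list[tuple[float, float, float]]  # (weight, mean pN, sd pN)
    residual_rms: float
    unbound_component_index: int

    def component_probability(self, index: int, hist: ForceHistogram
                              ) -> np.ndarray:
        """Predicted per-bin probability of one component."""
        w, mu, sd = self.components[index]
        x = hist.bin_centers
        pdf = np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        return w * pdf * hist.bin_width


def force_histogram(traces: list[TrapTrace], bin_width: float = 0.2
                    ) -> ForceHistogram:
    """Pool force samples across traces into a unit-probability histogram."""
    if not traces:
        raise ForceStatsError("no traces supplied")
    pooled = np.concatenate([t.force for t in traces])
    lo = math.floor(pooled.min() / bin_width) * bin_width
    hi = math.ceil(pooled.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    return ForceHistogram(bin_edges=edges,
                          probability=counts / counts.sum())


def _mixture_model(x, pars, n, bin_width):
    out = np.zeros_like(x)
    for i in range(n):
        w = pars[f"w{i}"]
        mu = pars[f"mu{i}"]
        sd = pars[f"sd{i}"]
        out += w * np.exp(-0.5 * ((x - mu) / sd) ** 2) \
            / (sd * math.sqrt(2 * math.pi))
    return out * bin_width


def fit_gaussian_mixture(hist: ForceHistogram, n_components: int = 3
                         ) -> GaussianMixtureFit:
    """Nonlinear least squares of a sum of Gaussians to the histogram.

    Initialization is deterministic: component means start at the
    ``n_components`` largest local maxima of the smoothed histogram
    (falling back to probability-quantile spacing), SDs at 0.5 pN, equal
    weights.  This is a curve fit to (bin center, probability) pairs, not
    an EM fit to samples.
    """
    x = hist.bin_centers
    y = hist.probability
    if np.count_nonzero(y) < 3 * n_components:
        raise ForceStatsError(
            f"need >= {3 * n_components} non-empty bins for "
            f"{n_components} components")

    smooth = gaussian_filter1d(y, sigma=2.0)
    peaks = argrelmax(smooth, order=2)[0]
    peaks = peaks[np.argsort(smooth[peaks])[::-1]]
    means0 = list(x[peaks[:n_components]])
    while len(means0) < n_components:
        # quantile fallback for missing modes
        q = (len(means0) + 0.5) / n_components
        cdf = np.cumsum(y)
        means0.append(float(x[np.searchsorted(cdf, q * cdf[-1])]))
    means0.sort()

    pars = Parameters()
    for i in range(n_components):
        pars.add(f"w{i}", value=1.0 / n_components, min=1e-6, max=1.0)
        pars.add(f"mu{i}", value=means0[i],
                 min=x[0] - hist.bin_width, max=x[-1] + hist.bin_width)
        pars.add(f"sd{i}", value=0.5, min=hist.bin_width / 4.0,
                 max=(x[-1] - x[0]) if x.size > 1 else 1.0)

    def resid(p):
        return _mixture_model(x, p, n_components, hist.bin_width) - y

    out = minimize(resid, pars, method="leastsq")
    rms = float(np.sqrt(np.mean(out.residual ** 2)))
    if not out.success:
        raise ForceStatsError(
            f"mixture fit did not converge (rms residual {rms:.3g})")
    comps = [
        (float(out.params[f"w{i}"].value), float(out.params[f"mu{i}"].value),
         float(out.params[f"sd{i}"].value))
        for i in range(n_components)
    ]
    comps.sort(key=lambda c: c[1])
    unbound = int(np.argmin([abs(c[1]) for c in comps]))
    return GaussianMixtureFit(components=comps, residual_rms=rms,
                              unbound_component_index=unbound)


def subtract_unbound_peak(hist: ForceHistogram, fit: GaussianMixtureFit,
                          renormalize: bool = False) -> ForceHistogram:
    """Remove the predicted unbound (near-0 pN) component bin-wise.

    The result is floored at zero and, by default, *not* renormalized.
    """
    pred = fit.component_probability(fit.unbound_component_index, hist)
    resid = np.clip(hist.probability - pred, 0.0, None)
    if renormalize and resid.sum() > 0:
        resid = resid / resid.sum()
    return ForceHistogram(bin_edges=hist.bin_edges.copy(), probability=resid)


# ---------------------------------------------------------------------------
# Stall-time survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    amplitude_fast: float
    tau_fast: float
    tau_slow: float
    amplitude_sem: float
    tau_fast_sem: float
    tau_slow_sem: float
    n_events: int


def stall_time_survival(stall_times: np.ndarray) -> SurvivalFit:
    """Fit the empirical survival function (1-CDF) of stall times to
    ``A exp(-t/tau_fast) + (1 - A) exp(-t/tau_slow)``.

    The 1-CDF is evaluated at the event times themselves (no binning),
    with uniform weights, and SEMs come from the fit covariance.  A second
    exponential is notoriously ill-conditioned on single-exponential data:
    if a single exponential already fits to within the binomial sampling
    noise of the empirical survival (rms <= 1.6 * sqrt(1/(6n))), the
    collapsed solution is returned (both time constants equal, amplitude 1).
    """
    t = np.sort(np.asarray(stall_times, dtype=float))
    n = t.size
    if n < 20:
        raise ForceStatsError(f"need >= 20 events, got {n}")
    if np.ptp(t) <= 0:
        raise ForceStatsError("degenerate input: all stall times identical")
    surv = 1.0 - np.arange(1, n + 1) / n + 0.5 / n  # midpoint convention

    mean = t.mean()

    # single-exponential baseline
    pars1 = Parameters()
    pars1.add("tau", value=mean, min=1e-6)
    out1 = minimize(lambda p: np.exp(-t / p["tau"]) - surv, pars1,
                    method="leastsq")
    rms1 = float(np.sqrt(np.mean(out1.residual ** 2)))

    pars = Parameters()
    pars.add("amp", value=0.5, min=0.0, max=1.0)
    pars.add("tau_fast", value=mean / 3.0, min=1e-6)
    pars.add("delta", value=mean * 3.0 - mean / 3.0, min=0.0)
    pars.add("tau_slow", expr="tau_fast + delta")

    def resid(p):
        a = p["amp"]
        model = a * np.exp(-t / p["tau_fast"]) \
            + (1 - a) * np.exp(-t / p["tau_slow"])
        return model - surv

    out = minimize(resid, pars, method="leastsq")
    if not out.success:
        raise ForceStatsError(f"survival fit failed: {out.message}")

    def sem_of(params, name):
        v = params[name].stderr
        return float(v) if v is not None else float("nan")

    # empirical-survival sampling noise: sqrt(mean(S(1-S))/n) ~ sqrt(1/(6n))
    noise_floor = math.sqrt(1.0 / (6.0 * n))
    if out1.success and rms1 <= 1.6 * noise_floor:
        tau = float(out1.params["tau"].value)
        tau_sem = sem_of(out1.params, "tau")
        return SurvivalFit(amplitude_fast=1.0, tau_fast=tau, tau_slow=tau,
                           amplitude_sem=0.0, tau_fast_sem=tau_sem,
                           tau_slow_sem=tau_sem, n_events=n)

    p = out.params
    return SurvivalFit(
        amplitude_fast=float(p["amp"].value),
        tau_fast=float(p["tau_fast"].value),
        tau_slow=float(p["tau_slow"].value),
        amplitude_sem=sem_of(p, "amp"), tau_fast_sem=sem_of(p, "tau_fast"),
        tau_slow_sem=sem_of(p, "tau_slow"), n_events=n)


# ---------------------------------------------------------------------------
# Stall summaries
# ---------------------------------------------------------------------------

@dataclass
class StallSummary:
    construct: str
    mean_stall_force: float
    sem: float
    n_stalls: int
    mean_stall_time: float
    single_event: bool = False


def summarize_stalls(events: list[StallEvent], construct: str = "",
                     outcomes: tuple[str, ...] = ("detach",)) -> StallSummary:
    """Mean +/- SEM of stall force over events with the given outcomes.

    Censored events are excluded by default; a single-event summary reports
    SEM 0 with a warning flag.
    """
    kept = [e for e in events if e.outcome in outcomes]
    if not kept:
        raise ForceStatsError("no events with accepted outcomes")
    forces = np.array([e.stall_force for e in kept])
    times = np.array([e.stall_time for e in kept])
    n = forces.size
    sem = float(forces.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return StallSummary(construct=construct,
                        mean_stall_force=float(forces.mean()), sem=sem,
                        n_stalls=n, mean_stall_time=float(times.mean()),
                        single_event=(n == 1))
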