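"""Trap-stiffness calibration from the thermal power spectrum of a bead.

A bead in a harmonic trap of stiffness ``k`` with drag ``gamma`` undergoes
Ornstein–Uhlenbeck motion whose one-sided position power spectral density is
the Lorentzian

    S(f) = D / (2 pi^2 (f_c^2 + f^2)),   f_c = k / (2 pi gamma),

with ``D = k_B T / gamma`` the diffusion coefficient (nm^2/s).  Fitting the
measured spectrum to this form yields the corner frequency and hence the
stiffness ``k = 2 pi gamma f_c``; equipartition (``k = k_B T / var(x)``)
provides an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import signal

from .synthetic_data import BOLTZMANN_PN_NM_298K, TrapTrace

DEFAULT_SEGMENT_LENGTH = 2 ** 13


class CalibrationError(RuntimeError):
    """Spectral fit failure (degenerate spectrum, corner outside band...)."""


@dataclass
class PowerSpectrum:
    """One-sided, segment-averaged position PSD (nm^2/Hz)."""

    frequency: np.ndarray
    density: np.ndarray
    n_segments_averaged: int

    def variance(self) -> float:
        """Integral of the density == variance of the position signal."""
        return float(np.trapezoid(self.density, self.frequency))


@dataclass
class CalibrationResult:
    corner_frequency: float        # Hz
    diffusion_coefficient: float   # nm^2/s
    stiffness: float               # pN/nm
    fit_residual: float            # rms residual in log-density space
    stiffness_equipartition: float = float("nan")


def power_spectrum(trace: TrapTrace,
                   segment_length: int = DEFAULT_SEGMENT_LENGTH
                   ) -> PowerSpectrum:
    """Welch-style segment-averaged periodogram of bead position.

    Position is derived from the recorded force via ``x = F / k``.
    Non-overlapping boxcar segments keep the estimate Parseval-consistent
    (the integral of the density matches the signal variance).
    """
    n = len(trace)
    if segment_length > n:
        raise CalibrationError(
            f"segment_length {segment_length} exceeds trace length {n}")
    x = trace.force / trace.spring_constant
    freq, dens = signal.welch(
        x, fs=trace.sample_rate, window="boxcar",
        nperseg=segment_length, noverlap=0, detrend="constant",
        scaling="density")
    # drop the DC bin: detrending zeroes it and it breaks log-space fits
    return PowerSpectrum(frequency=freq[1:], density=dens[1:],
                         n_segments_averaged=n // segment_length)


def lorentzian(f: np.ndarray, f_c: float, diffusion: float) -> np.ndarray:
    return diffusion / (2.0 * np.pi ** 2 * (f_c ** 2 + f ** 2))


def fit_lorentzian(psd: PowerSpectrum,
                   fit_band: tuple[float, float],
                   drag: float | None = None,
                   thermal_energy: float = BOLTZMANN_PN_NM_298K,
                   ) -> CalibrationResult:
    """Least-squares Lorentzian fit of the PSD in log-density space.

    The fit uses uniform weights on ``log S`` so high-frequency bins do not
    dominate.  If ``drag`` is supplied the stiffness is ``2 pi drag f_c``;
    the equipartition estimate ``k_B T / var(x)`` is always reported as a
    cross-check.
    """
    lo, hi = fit_band
    if lo >= hi:
        raise CalibrationError("empty fit band")
    if lo < psd.frequency[0] or hi > psd.frequency[-1]:
        raise CalibrationError("fit band outside spectrum range")
    sel = (psd.frequency >= lo) & (psd.frequency <= hi)
    f = psd.frequency[sel]
    s = psd.density[sel]
    if np.any(s <= 0) or np.ptp(np.log(s[s > 0])) < 1e-6:
        raise CalibrationError("degenerate spectrum (no corner frequency)")

    log_s = np.log(s)
    # initial corner: frequency where density falls to half its low-f level
    s0 = np.median(s[: max(3, s.size // 20)])
    below = np.flatnonzero(s <= 0.5 * s0)
    fc0 = f[below[0]] if below.size else math_sqrt_mid(lo, hi)
    d0 = s0 * 2.0 * np.pi ** 2 * fc0 ** 2

    pars = Parameters()
    pars.add("log_fc", value=np.log(fc0))
    pars.add("log_d", value=np.log(d0))

    def resid(p):
        return np.log(lorentzian(f, np.exp(p["log_fc"]),
                                 np.exp(p["log_d"]))) - log_s

    out = minimize(resid, pars, method="leastsq")
    if not out.success:
        raise CalibrationError(f"Lorentzian fit failed: {out.message}")
    f_c = float(np.exp(out.params["log_fc"].value))
    diff = float(np.exp(out.params["log_d"].value))
    if not lo <= f_c <= hi:
        raise CalibrationError(
            f"fitted corner frequency {f_c:.1f} Hz outside band {lo}-{hi} Hz")

    var_x = psd.variance()
    k_equi = thermal_energy / var_x if var_x > 0 else float("nan")
    k = 2.0 * np.pi * drag * f_c if drag is not None else k_equi
    rms = float(np.sqrt(np.mean(out.residual ** 2)))
    return CalibrationResult(corner_frequency=f_c, diffusion_coefficient=diff,
                             stiffness=k, fit_residual=rms,
                             stiffness_equipartition=k_equi)


def math_sqrt_mid(lo: float, hi: float) -> float:
    return float(np.sqrt(lo * hi))
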