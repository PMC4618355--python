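"""Enzyme progress-curve kinetics and growth-phenotype extraction.

Progress curves follow irreversible single-substrate Michaelis-Menten
depletion, dS/dt = -kcat*E0*S/(Km+S), whose closed-form solution is expressed
through the Wright omega function (omega(x) = W(e^x), principal Lambert
branch), which is numerically safe for large S0/Km.  Growth curves are fit
with the modified Gompertz model on log OD, with a log-linear fallback over a
detected exponential window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.special import wrightomega

__all__ = [
    "ProgressCurve",
    "KineticFit",
    "GrowthCurveFit",
    "progress_closed_form",
    "simulate_progress_curve",
    "fit_michaelis_menten",
    "gompertz_od",
    "fit_growth_curve",
    "generations",
    "promoter_activity",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Substrate depletion trace: time (s) vs substrate (uM) at known E0 (nM), S0 (uM)."""

    time: np.ndarray
    substrate: np.ndarray
    e0_nm: float
    s0_um: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.substrate, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and substrate must be 1-D and equal length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "substrate", s)


@dataclass(frozen=True)
class KineticFit:
    kcat: float  # s^-1
    km: float  # uM
    kcat_over_km: float  # uM^-1 s^-1
    residual_norm: float
    km_identifiable: bool = True


@dataclass(frozen=True)
class GrowthCurveFit:
    times: np.ndarray
    od: np.ndarray
    model: str  # "gompertz" | "loglinear" | "none"
    growth_rate: float  # h^-1 (maximal specific growth rate)
    lag: float  # h
    asymptote: float  # OD600
    no_growth: bool = False
    fitted: np.ndarray = field(default_factory=lambda: np.array([]))


def progress_closed_form(
    t: np.ndarray, e0_nm: float, s0_um: float, kcat: float, km: float
) -> np.ndarray:
    """Noiseless S(t) = Km * omega(ln(S0/Km) + (S0 - kcat*E0*t)/Km).

    E0 enters in uM (e0_nm / 1000) so that kcat*E0 has units uM/s.
    """
    if e0_nm <= 0 or s0_um <= 0 or kcat <= 0 or km <= 0:
        raise ValueError("all rates and concentrations must be positive")
    t = np.asarray(t, dtype=float)
    vmax = kcat * e0_nm * 1e-3  # uM/s
    x = np.log(s0_um / km) + (s0_um - vmax * t) / km
    return km * np.real(wrightomega(x))


def simulate_progress_curve(
    e0_nm: float,
    s0_um: float,
    kcat: float,
    km: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ProgressCurve:
    """Simulate a progress curve, optionally with additive Gaussian noise."""
    s = progress_closed_form(t_grid, e0_nm, s0_um, kcat, km)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sd, size=s.shape)
    return ProgressCurve(time=np.asarray(t_grid, float), substrate=s, e0_nm=e0_nm, s0_um=s0_um)


def fit_michaelis_menten(curves: list[ProgressCurve]) -> KineticFit:
    """Joint least-squares fit of the closed-form progress model to one or more curves.

    Parameters are fit in log space (positivity).  The Km-identifiability flag
    is cleared when every curve starts far below the fitted Km (first-order
    regime), where only kcat/Km is constrained.
    """
    if not curves:
        raise ValueError("need at least one progress curve")

    def residuals(logp: np.ndarray) -> np.ndarray:
        kcat, km = np.exp(logp)
        out = []
        for c in curves:
            out.append(progress_closed_form(c.time, c.e0_nm, c.s0_um, kcat, km) - c.substrate)
        return np.concatenate(out)

    km0 = float(np.median([c.s0_um for c in curves])) / 2.0
    # crude initial-rate estimate for kcat: fastest observed early depletion
    rates = []
    for c in curves:
        if c.time.size >= 2 and c.time[1] > c.time[0]:
            rates.append(max((c.substrate[0] - c.substrate[1]) / (c.time[1] - c.time[0]), 1e-9))
    v0 = max(rates) if rates else 1e-3
    kcat0 = v0 * (km0 + curves[0].s0_um) / curves[0].s0_um / (curves[0].e0_nm * 1e-3)
    sol = least_squares(
        residuals,
        x0=np.log([max(kcat0, 1e-9), max(km0, 1e-9)]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"progress-curve fit did not converge: {sol.message}")
    kcat, km = np.exp(sol.x)
    identifiable = any(c.s0_um >= 0.1 * km for c in curves)
    if not identifiable:
        warnings.warn(
            "all curves are in the first-order regime (S0 << Km); "
            "only kcat/Km is well determined",
            RuntimeWarning,
            stacklevel=2,
        )
    return KineticFit(
        kcat=float(kcat),
        km=float(km),
        kcat_over_km=float(kcat / km),
        residual_norm=float(np.linalg.norm(sol.fun)),
        km_identifiable=identifiable,
    )


def gompertz_od(
    t: np.ndarray, od0: float, rate: float, lag: float, amplitude: float
) -> np.ndarray:
    """Modified Gompertz growth trajectory in OD units.

    ln(OD/OD0) = A * exp(-exp(mu*e/A * (lag - t) + 1)) with mu the maximal
    specific growth rate (h^-1), lag in h and A = ln(asymptote/OD0).
    """
    t = np.asarray(t, dtype=float)
    if amplitude <= 0:
        return np.full_like(t, od0)
    y = amplitude * np.exp(-np.exp(rate * np.e / amplitude * (lag - t) + 1.0))
    return od0 * np.exp(y)


def _exponential_window(times: np.ndarray, log_od: np.ndarray, tol: float) -> slice:
    """Longest contiguous window whose log-OD stays within ``tol`` of a line."""
    n = times.size
    best = slice(0, min(3, n))
    for i in range(n - 2):
        for j in range(n, i + 2, -1):
            if j - i <= best.stop - best.start:
                break
            tt, yy = times[i:j], log_od[i:j]
            coef = np.polyfit(tt, yy, 1)
            if np.max(np.abs(np.polyval(coef, tt) - yy)) <= tol:
                best = slice(i, j)
                break
    return best


def fit_growth_curve(
    times: np.ndarray,
    od: np.ndarray,
    exp_window_tol: float = 0.05,
) -> GrowthCurveFit:
    """Extract the maximal specific growth rate from an OD600 time series.

    Fits the modified Gompertz model on ln(OD/OD0); if that fails, falls back
    to log-linear regression over the longest detected exponential window.
    A series with no net OD increase returns rate 0 with ``no_growth`` set.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    if np.any(y <= 0):
        raise ValueError("OD values must be positive")
    od0 = float(y[0])
    logr = np.log(y / od0)
    if logr.max() < 0.05:  # < ~5% net increase: call it no growth
        return GrowthCurveFit(
            times=t, od=y, model="none", growth_rate=0.0, lag=0.0,
            asymptote=float(y.max()), no_growth=True, fitted=np.full_like(y, od0),
        )

    amp0 = max(float(logr.max()), 0.1)
    span = float(t[-1] - t[0])
    rate0 = amp0 / max(span / 2.0, 1e-6)
    try:
        # free intercept c: the generating trajectory need not pass through
        # the first observation exactly
        popt, _ = curve_fit(
            lambda tt, r, lag, a, c: c + a * np.exp(-np.exp(r * np.e / a * (lag - tt) + 1.0)),
            t,
            logr,
            p0=[rate0, span / 4.0, amp0, 0.0],
            maxfev=20000,
        )
        rate, lag, amp, c = popt
        if rate > 0 and amp > 0:
            base = od0 * np.exp(c)
            with np.errstate(over="ignore"):
                # an unbounded amplitude (no plateau observed) yields inf
                asymptote = float(base * np.exp(amp))
            return GrowthCurveFit(
                times=t, od=y, model="gompertz", growth_rate=float(rate),
                lag=float(max(lag, 0.0)), asymptote=asymptote,
                fitted=gompertz_od(t, base, rate, lag, amp),
            )
    except RuntimeError:
        pass
    win = _exponential_window(t, np.log(y), exp_window_tol)
    coef = np.polyfit(t[win], np.log(y[win]), 1)
    rate = float(max(coef[0], 0.0))
    return GrowthCurveFit(
        times=t, od=y, model="loglinear", growth_rate=rate, lag=float(t[win.start]),
        asymptote=float(y.max()), fitted=np.exp(np.polyval(coef, t)),
    )


def generations(passages: int, dilution_factor: float) -> float:
    """Doublings accumulated over serial passaging: passages * log2(dilution)."""
    if passages < 0:
        raise ValueError("passages must be non-negative")
    if dilution_factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return passages * float(np.log2(dilution_factor))


def promoter_activity(fluorescence: float, od: float) -> float:
    """Promoter activity as fluorescence per unit biomass (GFP / OD600)."""
    if od <= 0:
        raise ValueError("OD must be positive")
    return fluorescence / od
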