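"""Arrhenius and Q10 analysis of temperature-rate profiles.

Activation energies come from ordinary least squares of ln(rate) on 1/T(K):

    ln k = ln A - Ea / (R T)

so Ea = -slope * R.  Q10 — the factor by which a rate increases over a
10 degC rise — is evaluated over the study's 10-20 degC convention
(T1 = 283.15 K, T2 = 293.15 K) as

    Q10 = exp( (Ea / R) * dT / (T1 T2) ).

A two-regime fit searches a candidate-break grid exhaustively, fitting a
separate Arrhenius line on each side and minimizing the total squared
residual in ln space (ties resolved toward the lower break temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .rates import RateEstimate

__all__ = [
    "R_GAS",
    "ArrheniusFit",
    "Q10Result",
    "TwoRegimeFit",
    "fit_arrhenius",
    "two_regime_fit",
    "q10_from_ea",
    "ea_from_q10",
]

R_GAS = 8.314  # J K-1 mol-1
_T0_Q10 = (283.15, 293.15)  # K, the 10-20 degC convention


class FitError(ValueError):
    pass


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + 273.15


@dataclass(frozen=True)
class ArrheniusFit:
    ea: float  # kJ mol-1
    ln_a: float
    r_squared: float
    temp_range: tuple[float, float]  # degC
    n_points: int
    n_excluded: int = 0  # non-positive rates dropped before logging

    def predict_ln_rate(self, t_celsius):
        t_k = celsius_to_kelvin(t_celsius)
        return self.ln_a - (self.ea * 1000.0 / R_GAS) / t_k


@dataclass(frozen=True)
class Q10Result:
    q10: float
    ea: float  # kJ mol-1
    t1: float  # K
    t2: float  # K

    @property
    def delta_t(self) -> float:
        return self.t2 - self.t1


@dataclass(frozen=True)
class TwoRegimeFit:
    left: ArrheniusFit
    right: ArrheniusFit
    break_temp: float  # degC
    sse_total: float
    single_sse: float
    fallback: bool = False  # no feasible break; left == right == single fit

    @property
    def improvement(self) -> float:
        """Fraction of the single-regime SSE removed by the break.

        A numerically zero single-fit SSE (data already on one line) means
        there is nothing to improve; reported as 0.
        """
        if self.single_sse <= 1e-12:
            return 0.0
        return 1.0 - self.sse_total / self.single_sse


def _profile_arrays(profile: Iterable[RateEstimate]) -> tuple[np.ndarray, np.ndarray]:
    temps = np.array([r.temperature for r in profile], dtype=float)
    vals = np.array([r.rate for r in profile], dtype=float)
    return temps, vals


def _ols_ln_rate(t_c: np.ndarray, rate: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of ln(rate) on 1/T(K): (ea_kj, ln_a, r_squared, sse)."""
    x = 1.0 / celsius_to_kelvin(t_c)
    y = np.log(rate)
    res = stats.linregress(x, y)
    ea = -res.slope * R_GAS / 1000.0
    pred = res.intercept + res.slope * x
    sse = float(np.sum((y - pred) ** 2))
    return ea, float(res.intercept), float(res.rvalue**2), sse


def fit_arrhenius(
    profile: Sequence[RateEstimate] | None = None,
    temp_range: tuple[float, float] | None = None,
    temperatures=None,
    rates=None,
) -> ArrheniusFit:
    """Fit the Arrhenius law to per-temperature maximum rates.

    Accepts either a list of RateEstimate or explicit temperature/rate
    arrays.  Non-positive rates cannot be log-transformed; they are excluded
    and counted in ``n_excluded``.  At least three usable points are
    required.
    """
    if profile is not None:
        temps, vals = _profile_arrays(profile)
    else:
        temps = np.asarray(temperatures, dtype=float)
        vals = np.asarray(rates, dtype=float)
    if temp_range is not None:
        keep = (temps >= temp_range[0]) & (temps <= temp_range[1])
        temps, vals = temps[keep], vals[keep]
    pos = vals > 0
    n_excluded = int(np.sum(~pos))
    temps, vals = temps[pos], vals[pos]
    if len(temps) < 3:
        raise FitError(f"need >= 3 positive rates, got {len(temps)}")
    ea, ln_a, r2, _ = _ols_ln_rate(temps, vals)
    return ArrheniusFit(
        ea=ea,
        ln_a=ln_a,
        r_squared=r2,
        temp_range=(float(temps.min()), float(temps.max())),
        n_points=len(temps),
        n_excluded=n_excluded,
    )


def two_regime_fit(
    profile: Sequence[RateEstimate] | None = None,
    candidate_breaks: Sequence[float] = (),
    min_points: int = 3,
    temperatures=None,
    rates=None,
) -> TwoRegimeFit:
    """Exhaustive two-regime Arrhenius fit over a grid of candidate breaks.

    Points at or below a candidate break go to the left fit, points above to
    the right; both sides need ``min_points`` positive rates.  Returns the
    break minimizing total ln-space SSE (ties: lower temperature).  With no
    feasible candidate, falls back to the single-regime fit, flagged.
    """
    if profile is not None:
        temps, vals = _profile_arrays(profile)
    else:
        temps = np.asarray(temperatures, dtype=float)
        vals = np.asarray(rates, dtype=float)
    pos = vals > 0
    temps, vals = temps[pos], vals[pos]
    single = fit_arrhenius(temperatures=temps, rates=vals)
    _, _, _, single_sse = _ols_ln_rate(temps, vals)

    best: tuple[float, float, ArrheniusFit, ArrheniusFit] | None = None
    for brk in sorted(candidate_breaks):
        left = temps <= brk
        right = ~left
        if left.sum() < min_points or right.sum() < min_points:
            continue
        ea_l, ln_a_l, r2_l, sse_l = _ols_ln_rate(temps[left], vals[left])
        ea_r, ln_a_r, r2_r, sse_r = _ols_ln_rate(temps[right], vals[right])
        sse = sse_l + sse_r
        if best is None or sse < best[0] - 1e-15:
            fit_l = ArrheniusFit(ea_l, ln_a_l, r2_l,
                                 (float(temps[left].min()), float(temps[left].max())),
                                 int(left.sum()))
            fit_r = ArrheniusFit(ea_r, ln_a_r, r2_r,
                                 (float(temps[right].min()), float(temps[right].max())),
                                 int(right.sum()))
            best = (sse, float(brk), fit_l, fit_r)
    if best is None:
        return TwoRegimeFit(single, single, math.nan, single_sse, single_sse, fallback=True)
    sse, brk, fit_l, fit_r = best
    return TwoRegimeFit(fit_l, fit_r, brk, sse, single_sse)


def q10_from_ea(ea_kj: float, t1: float = _T0_Q10[0], t2: float = _T0_Q10[1]) -> Q10Result:
    """Q10 from an activation energy in kJ/mol over [t1, t2] in K."""
    if not math.isfinite(ea_kj):
        raise ValueError("ea must be finite")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    q10 = math.exp((ea_kj * 1000.0 / R_GAS) * (t2 - t1) / (t1 * t2))
    return Q10Result(q10=q10, ea=ea_kj, t1=t1, t2=t2)


def ea_from_q10(q10: float, t1: float = _T0_Q10[0], t2: float = _T0_Q10[1]) -> float:
    """Algebraic inverse of q10_from_ea; returns Ea in kJ/mol."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return R_GAS * math.log(q10) * (t1 * t2) / (t2 - t1) / 1000.0
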