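"""Substrate partitioning of sulphate reduction and critical-temperature
detection.

Sulphate reduction can run on acetate (1 acetate : 1 sulphate) or on H2
(4 H2 : 1 sulphate).  Comparing the sulphate removal rate with the total
acetate oxidation rate bounds the hydrogenotrophic share from below: the
acetate-fuelled part of sulphate reduction can be at most the measured
acetate oxidation, so

    fraction_h2_min = (SRR - min(SRR, acox_acetate)) / SRR,

where acox arrives in CO2 units and is halved back to acetate units.  The
"at least" phrasing is deliberate: other organic electron donors are folded
into the non-acetate bound.  A breakpoint detector makes the visually
identified critical temperature objective: exhaustive two-segment least
squares over a candidate grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .rates import RateEstimate, max_rate_profile

__all__ = [
    "PartitionResult",
    "PartitionProfile",
    "BreakpointResult",
    "h2_fraction_bound",
    "partition_profile",
    "detect_breakpoint",
]


@dataclass(frozen=True)
class PartitionResult:
    temperature: float
    time: float
    srr: float  # nmol cm-3 day-1, sulphate units
    acox_acetate_units: float
    fraction_h2_min: float  # in [0, 1]
    degenerate: bool = False  # srr == 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_h2_min <= 1.0):
            raise ValueError("fraction_h2_min must lie in [0, 1]")


@dataclass
class PartitionProfile:
    results: list[PartitionResult]
    threshold_temperature: float | None  # lowest T with fraction >= 0.5
    pairing: str


@dataclass(frozen=True)
class BreakpointResult:
    break_temp: float
    sse_total: float
    left_fit: tuple[float, float]  # (slope, intercept)
    right_fit: tuple[float, float]
    improvement: float  # 1 - SSE_two / SSE_one


def h2_fraction_bound(srr: RateEstimate, acox_co2: RateEstimate) -> PartitionResult:
    """Lower bound on the hydrogenotrophic fraction of sulphate reduction.

    ``srr`` is the sulphate removal rate, ``acox_co2`` the total acetate
    oxidation rate in CO2 units (two CO2 per acetate).
    """
    if srr.temperature != acox_co2.temperature:
        raise ValueError("rates must be at the same temperature")
    if srr.rate < 0 or acox_co2.rate < 0:
        raise ValueError("rates must be non-negative")
    acox_acetate = acox_co2.rate / 2.0
    if srr.rate == 0:
        return PartitionResult(srr.temperature, srr.time, 0.0, acox_acetate, 0.0, degenerate=True)
    acetate_capable = min(srr.rate, acox_acetate)  # 1:1 acetate:sulphate
    frac = (srr.rate - acetate_capable) / srr.rate
    return PartitionResult(srr.temperature, srr.time, srr.rate, acox_acetate, frac)


def partition_profile(
    rates: Iterable[RateEstimate],
    srr_process: str = "sulphate_removal",
    acox_process: str = "acetate_oxidation",
    pairing: str = "max",
    threshold: float = 0.5,
) -> PartitionProfile:
    """Per-temperature partition bounds and the 50%-hydrogenotrophic onset.

    ``pairing="max"`` compares per-temperature maximum rates over time (the
    default, matching maximum-activity profiles); ``pairing="timewise"``
    pairs estimates cell by cell at matching times.  Reports the lowest
    temperature with fraction_h2_min >= threshold (None if never reached).
    """
    rates = list(rates)
    srr_all = [r for r in rates if r.process == srr_process]
    acox_all = [r for r in rates if r.process == acox_process]
    if pairing == "max":
        srr_by_t = {r.temperature: r for r in max_rate_profile(srr_all)}
        acox_by_t = {r.temperature: r for r in max_rate_profile(acox_all)}
        pairs = [(srr_by_t[t], acox_by_t[t]) for t in sorted(srr_by_t) if t in acox_by_t]
        missing = sorted(set(srr_by_t) ^ set(acox_by_t))
    elif pairing == "timewise":
        # pair each SRR estimate with the acox estimate nearest in time at
        # the same temperature (sampling grids need not coincide exactly)
        acox_by_temp: dict[float, list[RateEstimate]] = {}
        for r in acox_all:
            acox_by_temp.setdefault(r.temperature, []).append(r)
        pairs = []
        missing = []
        for s in sorted(srr_all, key=lambda r: (r.temperature, r.time)):
            cands = acox_by_temp.get(s.temperature)
            if not cands:
                missing.append(s.temperature)
                continue
            pairs.append((s, min(cands, key=lambda a: abs(a.time - s.time))))
        missing = sorted(set(missing))
        if missing:
            raise ValueError(f"no {acox_process} estimates at temperatures {missing}")
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if not pairs:
        raise ValueError(f"no shared grid between {srr_process} and {acox_process}: {missing}")
    results = [h2_fraction_bound(s, a) for s, a in pairs]
    threshold_t: float | None = None
    for res in sorted(results, key=lambda r: (r.temperature, r.time)):
        if not res.degenerate and res.fraction_h2_min >= threshold:
            threshold_t = res.temperature
            break
    return PartitionProfile(results=results, threshold_temperature=threshold_t, pairing=pairing)


def _segment_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (x, y): (sse, slope, intercept)."""
    if len(x) == 0:
        return 0.0, 0.0, 0.0
    if len(set(x.tolist())) == 1:
        m = float(np.mean(y))
        return float(np.sum((y - m) ** 2)), 0.0, m
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(resid @ resid), float(slope), float(intercept)


def detect_breakpoint(
    temperatures: Sequence[float],
    response: Sequence[float],
    grid: Sequence[float],
    min_points: int = 3,
) -> BreakpointResult:
    """Two-segment least-squares breakpoint search over a candidate grid.

    Points at or below a candidate go left, above go right; both segments
    need ``min_points`` points.  The candidate minimizing the total SSE
    wins, ties resolved toward the lower temperature.
    """
    x = np.asarray(temperatures, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape:
        raise ValueError("temperatures and response must have equal length")
    sse_one, _, _ = _segment_sse(x, y)
    best: tuple[float, float, tuple, tuple] | None = None
    for brk in sorted(grid):
        left = x <= brk
        right = ~left
        if left.sum() < min_points or right.sum() < min_points:
            continue
        sse_l, sl_l, ic_l = _segment_sse(x[left], y[left])
        sse_r, sl_r, ic_r = _segment_sse(x[right], y[right])
        sse = sse_l + sse_r
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(brk), (sl_l, ic_l), (sl_r, ic_r))
    if best is None:
        raise ValueError("no feasible breakpoint candidate")
    sse, brk, fit_l, fit_r = best
    # a numerically zero single-line SSE leaves nothing to improve
    if sse_one <= 1e-12 * max(1.0, float(y @ y)):
        improvement = 0.0
    else:
        improvement = 1.0 - sse / sse_one
    return BreakpointResult(brk, sse, fit_l, fit_r, improvement)
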