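"""Process-rate estimation from radiotracer incubations and from sulphate
concentration time series.

Units convention: 1 cm3 of slurry is taken as 1 mL, so a pool in uM is
numerically a pool in nmol cm-3 and all rates come out in nmol cm-3 day-1.

The tracer turnover rate uses the first-order single-time-point form

    rate = (product activity / added activity) * pool / duration

without back-reaction or isotope-fractionation corrections.  Rates of
acetate oxidation to CO2 are multiplied by 2 to account for the two CO2
molecules produced per acetate.  Each assay is run at three increasing
durations in triplicate; the reported estimate is the unweighted mean of the
three time-point means (replicates averaged within each time point first).
Sulphate removal rates are concentration differences between consecutive
sampling points, assigned to the interval midpoint, with negative values
clamped to zero (the raw value is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TracerIncubation",
    "RateEstimate",
    "tracer_rate",
    "aggregate_rate",
    "sulphate_removal_rates",
    "max_rate_profile",
]


class InvalidIncubationError(ValueError):
    pass


@dataclass(frozen=True)
class TracerIncubation:
    """One radiotracer measurement (one vial, one duration)."""

    process: str
    temperature: float  # degC
    start_day: float
    duration: float  # days
    added_activity: float
    product_activity: float
    pool: float  # uM (== nmol cm-3) substrate pool at incubation start
    replicate: int = 1
    timepoint_index: int = 1  # 1..3
    zero_pool: bool = False  # warning flag set by the simulator

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidIncubationError("duration must be positive")
        if self.pool < 0:
            raise InvalidIncubationError("pool must be >= 0")
        if self.product_activity < 0 or self.product_activity > self.added_activity:
            raise InvalidIncubationError(
                "product activity must lie in [0, added activity] "
                f"(got {self.product_activity} of {self.added_activity})"
            )


@dataclass(frozen=True)
class RateEstimate:
    """A process rate at one (temperature, time), nmol cm-3 day-1."""

    process: str
    temperature: float
    time: float
    rate: float
    sd: float = 0.0
    n: int = 1
    raw_rate: float | None = None  # pre-clamp value where clamping applied
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rate < 0 and "raw" not in self.flags:
            raise ValueError("rate must be >= 0 unless flagged raw")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def tracer_rate(inc: TracerIncubation, co2_double: bool = False) -> RateEstimate:
    """Turnover rate of a single incubation, in substrate-pool units.

    With ``co2_double`` (acetate oxidation to CO2 only) the rate is doubled
    to express it in CO2 units.
    """
    if inc.added_activity <= 0:
        raise InvalidIncubationError("added_activity must be positive")
    fraction = inc.product_activity / inc.added_activity
    rate = fraction * inc.pool / inc.duration
    if co2_double:
        rate *= 2.0
    flags = ("zero_pool",) if inc.zero_pool else ()
    return RateEstimate(
        process=inc.process,
        temperature=inc.temperature,
        time=inc.start_day,
        rate=rate,
        sd=0.0,
        n=1,
        flags=flags,
    )


def aggregate_rate(
    incs: Sequence[TracerIncubation], co2_double: bool = False
) -> RateEstimate:
    """Average one process/temperature/start group of incubations.

    Replicates are averaged within each of the (up to three) time points,
    then the time-point means are averaged with equal weight regardless of
    replicate count.  The dispersion is the sample sd of the time-point
    means (0, flagged, when only one time point is present).
    """
    if not incs:
        raise InvalidIncubationError("empty incubation group")
    proc = incs[0].process
    temp = incs[0].temperature
    start = incs[0].start_day
    tp_means: dict[int, list[float]] = {}
    for inc in incs:
        if inc.process != proc or inc.temperature != temp:
            raise InvalidIncubationError("mixed process/temperature in aggregate group")
        tp_means.setdefault(inc.timepoint_index, []).append(
            tracer_rate(inc, co2_double=co2_double).rate
        )
    if len(tp_means) > 3:
        raise InvalidIncubationError("more than three time points in group")
    means = np.array([np.mean(v) for _, v in sorted(tp_means.items())])
    flags: tuple[str, ...] = ()
    if len(means) == 1:
        sd = 0.0
        flags = ("single_timepoint",)
    else:
        sd = float(np.std(means, ddof=1))
    return RateEstimate(
        process=proc,
        temperature=temp,
        time=start,
        rate=float(np.mean(means)),
        sd=sd,
        n=len(incs),
        flags=flags,
    )


def sulphate_removal_rates(
    series: pd.DataFrame, species: str = "sulphate", process: str = "sulphate_removal"
) -> list[RateEstimate]:
    """Sulphate removal rates from concentration differences.

    ``series`` is a long-format table with columns temperature, time,
    species, value (replicates, if present, are averaged per time point).
    For consecutive points (t1, c1), (t2, c2) the rate (c1 - c2)/(t2 - t1)
    is assigned to the interval midpoint; negative rates are reported as 0
    with the raw value retained.
    """
    sub = series[series["species"] == species]
    if sub.empty:
        raise ValueError(f"no rows for species {species!r}")
    out: list[RateEstimate] = []
    for temp, grp in sub.groupby("temperature"):
        prof = grp.groupby("time")["value"].mean().sort_index()
        if prof.index.duplicated().any():
            raise ValueError(f"duplicate time points at T={temp}")
        if len(prof) < 2:
            raise ValueError(f"need >= 2 time points at T={temp}")
        t = prof.index.to_numpy(dtype=float)
        c = prof.to_numpy(dtype=float)
        for i in range(len(t) - 1):
            raw = (c[i] - c[i + 1]) / (t[i + 1] - t[i])
            out.append(
                RateEstimate(
                    process=process,
                    temperature=float(temp),
                    time=float((t[i] + t[i + 1]) / 2.0),
                    rate=max(raw, 0.0),
                    raw_rate=float(raw),
                    n=int(len(grp[grp["time"].isin(t[i : i + 2])])),
                    flags=("clamped",) if raw < 0 else (),
                )
            )
    return out


def max_rate_profile(rates: Iterable[RateEstimate]) -> list[RateEstimate]:
    """Per (process, temperature) maximum rate over time (ties: earliest)."""
    best: dict[tuple[str, float], RateEstimate] = {}
    for r in rates:
        key = (r.process, r.temperature)
        cur = best.get(key)
        if cur is None or r.rate > cur.rate or (r.rate == cur.rate and r.time < cur.time):
            best[key] = r
    return [best[k] for k in sorted(best)]
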