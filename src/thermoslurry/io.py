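"""Readers, writers, configuration and the pipeline driver.

Tables are long ("tidy") CSV, UTF-8, "." decimal, temperatures in degC.
Every writer emits a header-comment block (version, config hash, schema
pointer) so outputs are self-describing; readers skip those comments.
Left-censored values may be written as "<LIMIT" (e.g. "<1") and are parsed
back as the limit with the below-detection flag set.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import DEFAULT_CO2_FACTORS, net_balance
from .catalogue import (
    COPIES_PER_CELL,
    TRACER_ASSAYS,
    default_design,
    default_processes,
    default_sources,
)
from .cells import summarize_cells
from .kinetics import q10_from_ea, two_regime_fit
from .observe import observe_concentrations, observe_qpcr, observe_tracers
from .partition import partition_profile
from .rates import RateEstimate, TracerIncubation, aggregate_rate, sulphate_removal_rates
from .simulate import simulate
from .thermo import ActivityModel, favourability_profile, load_reactions

log = logging.getLogger("thermoslurry")

TIMESERIES_COLUMNS = ["temperature", "time", "species", "replicate", "value"]
TRACER_COLUMNS = [
    "process", "temperature", "start_day", "duration", "added_activity",
    "product_activity", "pool", "replicate", "timepoint_index",
]
QPCR_COLUMNS = ["domain", "temperature", "time", "replicate", "copies_per_ml"]

_KNOWN_CONFIG_KEYS = {
    "out_dir", "seed", "stages", "design", "inputs", "kinetics", "gibbs",
    "balance", "partition", "cells", "tracer_schedule",
}
_STAGES = ("simulate", "rates", "kinetics", "gibbs", "balance", "partition", "cells")


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    design: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    gibbs: dict = field(default_factory=dict)
    balance: dict = field(default_factory=dict)
    partition: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    tracer_schedule: tuple = (0.005, 0.01, 0.02)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        for key, p in raw.get("inputs", {}).items():
            if not Path(p).exists():
                raise DataError(f"input file for {key!r} does not exist: {p}")
        stages = {s: True for s in _STAGES}
        stages.update(raw.get("stages", {}))
        bad = set(stages) - set(_STAGES)
        if bad:
            raise DataError(f"unknown stages: {sorted(bad)}")
        return cls(
            out_dir=Path(raw.get("out_dir", "out")),
            seed=int(raw.get("seed", 0)),
            stages=stages,
            design=raw.get("design", {}),
            inputs=raw.get("inputs", {}),
            kinetics=raw.get("kinetics", {}),
            gibbs=raw.get("gibbs", {}),
            balance=raw.get("balance", {}),
            partition=raw.get("partition", {}),
            cells=raw.get("cells", {}),
            tracer_schedule=tuple(raw.get("tracer_schedule", (0.005, 0.01, 0.02))),
        )

    def hash(self) -> str:
        payload = yaml.safe_dump(
            {
                "seed": self.seed,
                "stages": self.stages,
                "design": self.design,
                "inputs": {k: str(v) for k, v in self.inputs.items()},
                "kinetics": self.kinetics,
                "gibbs": self.gibbs,
                "balance": self.balance,
                "partition": self.partition,
                "cells": self.cells,
                "tracer_schedule": list(self.tracer_schedule),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    row_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "", schema: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# thermoslurry v{__version__}\n")
        fh.write(f"# config_hash: {config_hash}\n")
        fh.write(f"# schema: {schema or 'docs/schemas.md'}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, comment="#", sep=sep)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format concentration table.

    Values like "<1" are parsed as the detection limit with the
    below_detection flag set.  Duplicate (temperature, time, species,
    replicate) keys and non-numeric values are reported with row numbers.
    """
    df = _read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    below = pd.Series(False, index=df.index)
    vals = df["value"]
    if vals.dtype == object:
        s = vals.astype(str).str.strip()
        below = s.str.startswith("<")
        vals = s.str.lstrip("<")
    parsed = pd.to_numeric(vals, errors="coerce")
    bad = df.index[parsed.isna()]
    if len(bad):
        raise DataError(f"{path}: non-numeric value at rows {list(bad[:5])}")
    df = df.assign(value=parsed)
    if "below_detection" in df.columns:
        df["below_detection"] = df["below_detection"].astype(bool) | below
    else:
        df["below_detection"] = below
    for c in ("temperature", "time"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
        if df[c].isna().any():
            raise DataError(f"{path}: non-numeric {c}")
    key = ["temperature", "time", "species", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].to_dict()
        raise DataError(f"{path}: duplicate key {first}")
    return df


def read_tracers(path: str | Path) -> list[TracerIncubation]:
    df = _read_csv(path)
    missing = [c for c in TRACER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            TracerIncubation(
                process=str(r["process"]),
                temperature=float(r["temperature"]),
                start_day=float(r["start_day"]),
                duration=float(r["duration"]),
                added_activity=float(r["added_activity"]),
                product_activity=float(r["product_activity"]),
                pool=float(r["pool"]),
                replicate=int(r["replicate"]),
                timepoint_index=int(r["timepoint_index"]),
                zero_pool=bool(r.get("zero_pool", False)),
            )
        )
    return out


def tracers_to_frame(incs: Sequence[TracerIncubation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "process": i.process, "temperature": i.temperature, "start_day": i.start_day,
                "duration": i.duration, "added_activity": i.added_activity,
                "product_activity": i.product_activity, "pool": i.pool,
                "replicate": i.replicate, "timepoint_index": i.timepoint_index,
                "zero_pool": i.zero_pool,
            }
            for i in incs
        ]
    )


def rates_to_frame(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "process": r.process, "temperature": r.temperature, "time": r.time,
                "rate": r.rate, "sd": r.sd, "n": r.n,
                "raw_rate": r.raw_rate if r.raw_rate is not None else r.rate,
                "flags": "|".join(r.flags),
            }
            for r in rates
        ]
    )


def frame_to_rates(df: pd.DataFrame) -> list[RateEstimate]:
    out = []
    for _, r in df.iterrows():
        flags = tuple(str(r.get("flags", "")).split("|")) if r.get("flags") else ()
        out.append(
            RateEstimate(
                process=str(r["process"]), temperature=float(r["temperature"]),
                time=float(r["time"]), rate=float(r["rate"]),
                sd=float(r.get("sd", 0.0)), n=int(r.get("n", 1)),
                raw_rate=float(r["raw_rate"]) if "raw_rate" in r else None, flags=flags,
            )
        )
    return out


def aggregate_tracer_rates(incs: Sequence[TracerIncubation]) -> list[RateEstimate]:
    """Aggregate raw incubations per (assay, temperature, start day).

    The acetate-oxidation assay is doubled into CO2 units per its
    convention; other assays stay in substrate units.
    """
    double = {a.name: a.co2_double for a in TRACER_ASSAYS}
    groups: dict[tuple, list[TracerIncubation]] = {}
    for inc in incs:
        groups.setdefault((inc.process, inc.temperature, inc.start_day), []).append(inc)
    return [
        aggregate_rate(g, co2_double=double.get(key[0], False))
        for key, g in sorted(groups.items())
    ]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Outputs land in config.out_dir with the config hash embedded; a rerun
    with identical config and seed is byte-identical.  Any stage error
    aborts with the stage name, removing partial outputs of that stage.
    """
    h = config.hash()
    report = RunReport(config_hash=h, version=__version__)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        p = out / name
        write_table(df, p, config_hash=h)
        written.append(p)
        report.outputs.append(str(p))
        report.row_counts[name] = len(df)

    conc = trac = qpcr = None
    stage = "simulate"
    try:
        if config.stages.get("simulate"):
            design = default_design(seed=config.seed, **config.design)
            sim = simulate(design, default_processes(), default_sources())
            conc = observe_concentrations(sim, design)
            trac = observe_tracers(sim, design, schedule=config.tracer_schedule)
            qpcr = observe_qpcr(sim, design)
            emit(conc, "concentrations.csv")
            emit(tracers_to_frame(trac), "tracers.csv")
            emit(qpcr, "qpcr.csv")
            true_rows = []
            tidx = [int(np.argmin(np.abs(sim.times - t))) for t in design.time_points]
            for p, spec in enumerate(sim.processes):
                for ti, temp in enumerate(sim.temperatures):
                    for tp, ki in zip(design.time_points, tidx):
                        true_rows.append((spec.name, float(temp), float(tp),
                                          float(sim.rates[p, ti, ki])))
            emit(pd.DataFrame(true_rows, columns=["process", "temperature", "time", "rate"]),
                 "true_rates.csv")
        if conc is None and "concentrations" in config.inputs:
            conc = read_timeseries(config.inputs["concentrations"])
        if trac is None and "tracers" in config.inputs:
            trac = read_tracers(config.inputs["tracers"])
        if qpcr is None and "qpcr" in config.inputs:
            qpcr = _read_csv(config.inputs["qpcr"])

        all_rates: list[RateEstimate] = []
        stage = "rates"
        if config.stages.get("rates"):
            if trac is None or conc is None:
                raise DataError("rates stage needs tracer and concentration inputs")
            all_rates = aggregate_tracer_rates(trac)
            all_rates += sulphate_removal_rates(conc)
            n_zero = sum(1 for r in all_rates if r.rate == 0)
            report.exclusions["zero_rates"] = n_zero
            emit(rates_to_frame(all_rates), "rates.csv")

        stage = "kinetics"
        if config.stages.get("kinetics") and all_rates:
            rows = []
            grid_spec = config.kinetics.get("break_grid", [30, 60, 1])
            grid = np.arange(grid_spec[0], grid_spec[1] + 1e-9, grid_spec[2])
            for proc in sorted({r.process for r in all_rates}):
                from .rates import max_rate_profile

                prof = max_rate_profile([r for r in all_rates if r.process == proc])
                pos = [r for r in prof if r.rate > 0]
                if len(pos) < 3:
                    report.warnings.append(f"kinetics: {proc}: <3 positive rates, skipped")
                    continue
                try:
                    tr = two_regime_fit(prof, candidate_breaks=grid)
                except Exception as exc:  # refuse, keep going
                    report.warnings.append(f"kinetics: {proc}: {exc}")
                    continue
                for side, fit in (("left", tr.left), ("right", tr.right)):
                    rows.append(
                        {
                            "process": proc, "side": side, "ea_kj_mol": round(fit.ea, 1),
                            "ln_a": fit.ln_a, "r_squared": fit.r_squared,
                            "q10": round(q10_from_ea(fit.ea).q10, 1),
                            "break_temp": tr.break_temp, "improvement": tr.improvement,
                            "n_points": fit.n_points, "n_excluded": fit.n_excluded,
                            "fallback": tr.fallback,
                        }
                    )
            emit(pd.DataFrame(rows), "kinetics.csv")

        stage = "gibbs"
        if config.stages.get("gibbs") and conc is not None:
            model = ActivityModel(ph=float(config.gibbs.get("ph", 7.5)))
            threshold = float(config.gibbs.get("threshold", -10.0))
            frames = []
            for name, rx in load_reactions(config.gibbs.get("reactions")).items():
                prof = favourability_profile(rx, conc, model, threshold)
                prof.insert(0, "reaction", name)
                frames.append(prof)
            emit(pd.concat(frames, ignore_index=True), "gibbs.csv")

        stage = "balance"
        if config.stages.get("balance") and all_rates:
            factors = dict(DEFAULT_CO2_FACTORS)
            factors.update(config.balance.get("factors", {}))
            split = float(config.balance.get("split_temp", 43.0))
            bal = net_balance(all_rates, factors, split_temp=split)
            emit(bal.table, "balance.csv")
            emit(
                pd.DataFrame(
                    [{
                        "split_temp": split, "mean_below": bal.mean_below,
                        "mean_above": bal.mean_above,
                        "ratio_below_over_above": bal.ratio_below_over_above,
                    }]
                ),
                "balance_summary.csv",
            )

        stage = "partition"
        if config.stages.get("partition") and all_rates:
            prof = partition_profile(all_rates, pairing=config.partition.get("pairing", "max"))
            emit(
                pd.DataFrame(
                    [
                        {
                            "temperature": r.temperature, "time": r.time, "srr": r.srr,
                            "acox_acetate_units": r.acox_acetate_units,
                            "fraction_h2_min": r.fraction_h2_min, "degenerate": r.degenerate,
                        }
                        for r in prof.results
                    ]
                ),
                "partition.csv",
            )
            report.row_counts["partition_threshold_temperature"] = prof.threshold_temperature

        stage = "cells"
        if config.stages.get("cells") and qpcr is not None:
            divisors = dict(COPIES_PER_CELL)
            divisors.update(config.cells.get("divisors", {}))
            emit(summarize_cells(qpcr, divisors), "cells.csv")
    except Exception:
        for p in written[-1:]:
            p.unlink(missing_ok=True)
        log.error("pipeline failed in stage %r", stage)
        raise

    report_df = pd.DataFrame(
        [{"key": k, "value": v} for k, v in {
            "config_hash": h, "version": __version__, **report.row_counts,
            "warnings": "; ".join(report.warnings),
        }.items()]
    )
    write_table(report_df, out / "run_report.csv", config_hash=h)
    return report
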