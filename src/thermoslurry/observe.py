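"""Synthetic measurements of a simulated experiment.

Turns ground-truth trajectories into the three observation tables the
analysis stages consume: pore-water/headspace concentrations (with
multiplicative lognormal noise and left-censoring at detection limits),
triplicate three-time-point radiotracer incubations, and qPCR 16S rRNA gene
copy tables.  All randomness is driven by the design seed; identical seeds
give identical tables.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import COPIES_PER_CELL, TRACER_ASSAYS, TracerAssay
from .rates import TracerIncubation
from .simulate import ExperimentDesign, SimulationResult

__all__ = [
    "observe_concentrations",
    "observe_tracers",
    "observe_qpcr",
    "assay_true_rate",
    "true_sulphate_reduction",
    "true_cells",
]

#: nominal added radioactivity per vial (arbitrary activity units)
ADDED_ACTIVITY = 1.0e5


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def observe_concentrations(
    sim: SimulationResult, design: ExperimentDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Long-format concentration table.

    Columns: temperature, time, species, replicate, value, below_detection.
    Values under the species detection limit are reported at the limit with
    the below_detection flag set.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    time_idx = [int(np.argmin(np.abs(sim.times - t))) for t in design.time_points]
    for ti, temp in enumerate(sim.temperatures):
        for tp, ki in zip(design.time_points, time_idx):
            truth = sim.state[ti, ki, :]
            noise = _lognormal_factors(rng, design.noise_cv, (design.replicates, len(sim.species)))
            for rep in range(design.replicates):
                for si, sp in enumerate(sim.species):
                    val = truth[si] * noise[rep, si]
                    limit = design.detection_limits.get(sp, 0.0)
                    below = val < limit
                    rows.append(
                        (float(temp), float(tp), sp, rep + 1, float(limit if below else val), bool(below))
                    )
    return pd.DataFrame(
        rows, columns=["temperature", "time", "species", "replicate", "value", "below_detection"]
    )


def assay_true_rate(sim: SimulationResult, assay: TracerAssay) -> np.ndarray:
    """True instantaneous assay rate in substrate units, shape (n_T, n_t)."""
    total = np.zeros_like(sim.rates[0])
    for pname in assay.processes:
        p = sim.process_index(pname)
        conv = abs(sim.processes[p].species_per_rate_unit(assay.substrate))
        total += sim.rates[p] * conv
    return total


def observe_tracers(
    sim: SimulationResult,
    design: ExperimentDesign,
    schedule: Sequence[float] = (0.005, 0.01, 0.02),
    assays: Sequence[TracerAssay] = TRACER_ASSAYS,
    rng: np.random.Generator | None = None,
) -> list[TracerIncubation]:
    """Synthesize triplicate incubations at three durations per assay.

    The product activity fraction is (true rate x duration) / pool with the
    substrate pool taken from the trajectory at incubation start.  Zero
    pools yield zero fractions with a warning flag.  Durations are short
    (default 7-30 min) so that label turnover stays in the linear regime
    even for rapidly cycling pools.
    """
    if len(schedule) != 3 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be three strictly increasing durations")
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    out: list[TracerIncubation] = []
    time_idx = [int(np.argmin(np.abs(sim.times - t))) for t in design.time_points]
    for assay in assays:
        truth = assay_true_rate(sim, assay)
        si = sim.species_index(assay.substrate)
        for ti, temp in enumerate(sim.temperatures):
            for tp, ki in zip(design.time_points, time_idx):
                pool = float(sim.state[ti, ki, si])
                rate = float(truth[ti, ki])
                for j, dur in enumerate(schedule, start=1):
                    if pool > 0:
                        frac = rate * dur / pool
                    else:
                        frac = 0.0
                    noise = _lognormal_factors(rng, design.noise_cv, design.replicates)
                    for rep in range(design.replicates):
                        prod = min(frac * noise[rep] * ADDED_ACTIVITY, ADDED_ACTIVITY)
                        out.append(
                            TracerIncubation(
                                process=assay.name,
                                temperature=float(temp),
                                start_day=float(tp),
                                duration=float(dur),
                                added_activity=ADDED_ACTIVITY,
                                product_activity=prod,
                                pool=pool,
                                replicate=rep + 1,
                                timepoint_index=j,
                                zero_pool=(pool == 0.0),
                            )
                        )
    return out


# --- qPCR abundance model ---------------------------------------------------
# Cell densities respond to cumulative substrate turnover: bacterial cells
# track the chemoorganotrophic/SR processes, archaeal cells the methanogens.
# A thermal mortality term thins both domains at high temperature.

_BACTERIAL = (
    "acetoclastic_metal_reduction",
    "acetoclastic_sulphate_reduction",
    "hydrogenotrophic_sulphate_reduction",
    "hydrogenotrophic_acetogenesis",
)
_ARCHAEAL = (
    "methylotrophic_methanogenesis",
    "acetoclastic_methanogenesis",
    "hydrogenotrophic_methanogenesis",
)

_BASE_CELLS = {"Bacteria": 5.0e6, "Archaea": 1.0e6}  # cells per mL at day 0
_YIELD = {"Bacteria": 60.0, "Archaea": 120.0}  # cells per nmol substrate turned over
_DEATH_RATE = 0.04  # day-1 at full thermal stress
_DEATH_MID = 60.0  # degC
_DEATH_WIDTH = 5.0


def true_cells(sim: SimulationResult, domain: str) -> np.ndarray:
    """Ground-truth cell density (cells per mL), shape (n_T, n_t)."""
    names = _BACTERIAL if domain == "Bacteria" else _ARCHAEAL
    dt = float(sim.times[1] - sim.times[0]) if len(sim.times) > 1 else 0.0
    cum = np.zeros_like(sim.rates[0])
    for pname in names:
        try:
            p = sim.process_index(pname)
        except KeyError:
            continue
        cum += np.cumsum(sim.rates[p], axis=1) * dt
    death = _DEATH_RATE / (1.0 + np.exp(-(sim.temperatures - _DEATH_MID) / _DEATH_WIDTH))
    surv = np.exp(-np.outer(death, sim.times))
    return (_BASE_CELLS[domain] + _YIELD[domain] * cum) * surv


def observe_qpcr(
    sim: SimulationResult,
    design: ExperimentDesign,
    copies_per_cell: Mapping[str, float] = COPIES_PER_CELL,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Triplicate 16S rRNA gene copy counts per (domain, temperature, time).

    Columns: domain, temperature, time, replicate, copies_per_ml.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    rows = []
    time_idx = [int(np.argmin(np.abs(sim.times - t))) for t in design.time_points]
    for domain, divisor in copies_per_cell.items():
        cells = true_cells(sim, domain)
        for ti, temp in enumerate(sim.temperatures):
            for tp, ki in zip(design.time_points, time_idx):
                copies = cells[ti, ki] * divisor
                noise = _lognormal_factors(rng, design.noise_cv, design.replicates)
                for rep in range(design.replicates):
                    rows.append((domain, float(temp), float(tp), rep + 1, float(copies * noise[rep])))
    return pd.DataFrame(
        rows, columns=["domain", "temperature", "time", "replicate", "copies_per_ml"]
    )


def true_sulphate_reduction(sim: SimulationResult) -> pd.DataFrame:
    """True sulphate consumption split by substrate (sulphate units).

    Columns: temperature, time, hydrogenotrophic, acetoclastic — the
    simulator's ground truth for validating the partition lower bound.
    """
    rows = []
    h2 = np.zeros_like(sim.rates[0])
    ac = np.zeros_like(sim.rates[0])
    for p, spec in enumerate(sim.processes):
        nu_so4 = spec.species_per_rate_unit("sulphate")
        if nu_so4 >= 0:
            continue
        consumption = sim.rates[p] * abs(nu_so4)
        if "hydrogen" in spec.substrates:
            h2 += consumption
        else:
            ac += consumption
    for ti, temp in enumerate(sim.temperatures):
        for ki, t in enumerate(sim.times):
            rows.append((float(temp), float(t), float(h2[ti, ki]), float(ac[ti, ki])))
    return pd.DataFrame(rows, columns=["temperature", "time", "hydrogenotrophic", "acetoclastic"])
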