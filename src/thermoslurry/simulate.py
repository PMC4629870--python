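"""Forward simulation of thermal-gradient anaerobic slurry incubations.

The model tracks a small set of chemical pools (sulphate, H2, CH4, acetate,
methylamine, ammonium, DIC, metal oxide; all in uM, with 1 cm3 slurry taken
as 1 mL so uM == nmol cm-3) in sealed vials incubated at fixed temperatures
between 0 and 80 degC for up to 100 days.  Each anaerobic process is active
inside one or more Gaussian "temperature windows of opportunity"; its
instantaneous rate is

    r = r_max * window(T) * prod_substrates c/(c+K) * [t >= onset]

in units of its ``rate_species``.  Pools are advanced by explicit Euler with
a per-step limiting-substrate clamp so that no step consumes more of any
substrate than is present (stoichiometry stays exact at depletion).
Temperature-dependent source terms emulate the activation of sedimentary
organic matter, releasing H2, acetate and methylamine into the slurry; the
organic carbon they add is recorded in a cumulative carbon ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChemSpecies",
    "ThermalWindow",
    "ProcessSpec",
    "SourceTerm",
    "ExperimentDesign",
    "SimulationResult",
    "window_response",
    "step_state",
    "simulate",
]


class ConfigurationError(ValueError):
    """Raised for invalid model configuration (empty windows, bad design)."""


class IntegrationError(RuntimeError):
    """Raised when the forward integration produces a non-finite state."""


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical pool tracked by the simulator.

    Dissolved species are in uM; headspace gases are carried as uM
    gas-equivalent referenced to slurry volume, so all pools share one unit.
    """

    name: str
    phase: str = "dissolved"  # "dissolved" | "gas"
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.phase not in ("dissolved", "gas"):
            raise ConfigurationError(f"unknown phase {self.phase!r} for {self.name}")


@dataclass(frozen=True)
class ThermalWindow:
    """Asymmetric Gaussian temperature window.

    Response is ``weight * exp(-(T - t_opt)^2 / (2 sigma^2))`` with
    ``sigma_left`` below the optimum and ``sigma_right`` above it.
    """

    t_opt: float
    sigma_left: float
    sigma_right: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise ConfigurationError("window sigmas must be positive")
        if not (0.0 < self.weight <= 1.0):
            raise ConfigurationError("window weight must be in (0, 1]")


def window_response(t_celsius, windows: Sequence[ThermalWindow]):
    """Temperature response in [0, 1]: max over the process's windows.

    Accepts a scalar or array of temperatures (degC).
    """
    if not windows:
        raise ConfigurationError("process has no thermal windows")
    t = np.asarray(t_celsius, dtype=float)
    resp = np.zeros_like(t)
    for w in windows:
        sigma = np.where(t < w.t_opt, w.sigma_left, w.sigma_right)
        resp = np.maximum(resp, w.weight * np.exp(-((t - w.t_opt) ** 2) / (2.0 * sigma**2)))
    return float(resp) if np.isscalar(t_celsius) else resp


@dataclass(frozen=True)
class ProcessSpec:
    """One anaerobic process: stoichiometry, temperature windows, kinetics.

    ``stoichiometry`` maps species name to a signed coefficient per mol of
    reaction advance; the reported rate is in units of ``rate_species``.
    ``co2_factor`` is the signed mol CO2 per mol of the reported rate unit
    used by the carbon-balance stage.  ``tracer_substrate`` names the
    radiolabelled pool a tracer assay of this process would monitor (None if
    the process is not tracer-measurable).  ``ea`` is the ground-truth
    activation energy (kJ/mol) on the rising limb, used only for validation.
    """

    name: str
    stoichiometry: Mapping[str, float]
    rate_species: str
    r_max: float
    windows: tuple[ThermalWindow, ...]
    half_saturation: Mapping[str, float] = field(default_factory=dict)
    onset_day: float = 0.0
    ea: float = 60.0
    co2_factor: float = 0.0
    tracer_substrate: str | None = None

    def __post_init__(self) -> None:
        if self.r_max < 0:
            raise ConfigurationError(f"{self.name}: r_max must be >= 0")
        if not self.windows:
            raise ConfigurationError(f"{self.name}: windows must be non-empty")
        if self.rate_species not in self.stoichiometry:
            raise ConfigurationError(f"{self.name}: rate_species not in stoichiometry")
        for sp in self.half_saturation:
            if self.stoichiometry.get(sp, 0.0) >= 0:
                raise ConfigurationError(
                    f"{self.name}: half-saturation species {sp} must be a consumed substrate"
                )

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(s for s, nu in self.stoichiometry.items() if nu < 0)

    def species_per_rate_unit(self, species: str) -> float:
        """Signed mol of *species* per unit advance of the reported rate."""
        return self.stoichiometry.get(species, 0.0) / abs(self.stoichiometry[self.rate_species])


@dataclass(frozen=True)
class SourceTerm:
    """Temperature-dependent release of a species from sedimentary organic
    matter (thermal activation / fermentative supply).

    ``mode`` is "logistic" (amplitude / (1 + exp(-(T - t_mid)/width)),
    increasing with temperature) or "window" (Gaussian, via ``window``).
    ``carbon`` is mol organic carbon added per mol species (acetate 2,
    methylamine 1, H2 0) and feeds the carbon ledger.
    """

    species: str
    amplitude: float  # nmol cm-3 day-1 at full activation
    mode: str = "logistic"
    t_mid: float = 45.0
    width: float = 3.0
    window: ThermalWindow | None = None
    carbon: float = 0.0

    def rate(self, t_celsius):
        t = np.asarray(t_celsius, dtype=float)
        if self.mode == "logistic":
            r = self.amplitude / (1.0 + np.exp(-(t - self.t_mid) / self.width))
        elif self.mode == "window":
            if self.window is None:
                raise ConfigurationError("window source term requires a window")
            r = self.amplitude * window_response(t, [self.window])
        else:
            raise ConfigurationError(f"unknown source mode {self.mode!r}")
        return float(r) if np.isscalar(t_celsius) else r


@dataclass
class ExperimentDesign:
    """Design of a thermal-gradient incubation experiment."""

    temperatures: Sequence[float]
    time_points: Sequence[float]
    replicates: int = 3
    scenario: str = "unamended"
    initial_state: Mapping[str, float] = field(default_factory=dict)
    noise_cv: float = 0.05
    detection_limits: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    dt: float = 0.1

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size == 0 or temps.min() < 0 or temps.max() > 80:
            raise ConfigurationError("temperatures must lie within [0, 80] degC")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0) or tp.max() > 100:
            raise ConfigurationError("time_points must be strictly increasing with max <= 100 days")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.scenario not in ("unamended", "amended"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")


@dataclass
class SimulationResult:
    """Ground-truth trajectories of one simulated experiment.

    ``state`` has shape (n_temperatures, n_steps, n_species) and
    ``rates`` (n_processes, n_temperatures, n_steps) in each process's
    rate_species units.  ``carbon_ledger`` (n_temperatures, n_steps) is the
    cumulative organic carbon added by the source terms (nmol C cm-3).
    """

    temperatures: np.ndarray
    times: np.ndarray
    species: tuple[str, ...]
    processes: tuple[ProcessSpec, ...]
    state: np.ndarray
    rates: np.ndarray
    carbon_ledger: np.ndarray

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def process_index(self, name: str) -> int:
        for i, p in enumerate(self.processes):
            if p.name == name:
                return i
        raise KeyError(name)

    def at(self, temperature: float, time: float, species: str) -> float:
        """Pool value nearest to (temperature, time)."""
        ti = int(np.argmin(np.abs(self.temperatures - temperature)))
        ki = int(np.argmin(np.abs(self.times - time)))
        return float(self.state[ti, ki, self.species_index(species)])


def _rates_array(
    state: np.ndarray,
    temps: np.ndarray,
    specs: Sequence[ProcessSpec],
    species: Sequence[str],
    t_day: float,
) -> np.ndarray:
    """Instantaneous rates, shape (n_processes, n_temperatures)."""
    idx = {s: i for i, s in enumerate(species)}
    rates = np.zeros((len(specs), len(temps)))
    for p, spec in enumerate(specs):
        if t_day < spec.onset_day or spec.r_max == 0.0:
            continue
        r = spec.r_max * window_response(temps, spec.windows)
        for sp, k in spec.half_saturation.items():
            c = state[:, idx[sp]]
            r = r * (c / (c + k))
        rates[p] = r
    return rates


def _step_arrays(
    state: np.ndarray,
    temps: np.ndarray,
    specs: Sequence[ProcessSpec],
    species: Sequence[str],
    dt: float,
    t_day: float,
    sources: Sequence[SourceTerm] = (),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One explicit-Euler step over all temperatures at once.

    Returns (new_state, applied_rates, carbon_added).  The limiting-substrate
    clamp scales each process so that gross consumption of every substrate
    stays within the available pool.
    """
    if np.any(state < 0):
        raise IntegrationError("negative pool on entry to step")
    idx = {s: i for i, s in enumerate(species)}
    rates = _rates_array(state, temps, specs, species, t_day)

    # Per-species gross consumption (nmol cm-3 day-1), ignoring concurrent
    # production within the step (conservative clamp).
    demand = np.zeros_like(state)
    for p, spec in enumerate(specs):
        for sp in spec.substrates:
            demand[:, idx[sp]] += rates[p] * abs(spec.species_per_rate_unit(sp))
    with np.errstate(divide="ignore", invalid="ignore"):
        avail_scale = np.where(demand * dt > state, state / np.maximum(demand * dt, 1e-300), 1.0)
    avail_scale = np.clip(avail_scale, 0.0, 1.0)

    scaled = rates.copy()
    for p, spec in enumerate(specs):
        s = np.ones(len(temps))
        for sp in spec.substrates:
            s = np.minimum(s, avail_scale[:, idx[sp]])
        scaled[p] *= s

    delta = np.zeros_like(state)
    for p, spec in enumerate(specs):
        for sp, nu in spec.stoichiometry.items():
            delta[:, idx[sp]] += scaled[p] * (nu / abs(spec.stoichiometry[spec.rate_species]))

    carbon = np.zeros(len(temps))
    for src in sources:
        r = src.rate(temps)
        delta[:, idx[src.species]] += r
        carbon += r * src.carbon * dt

    new_state = state + delta * dt
    # Guard floating-point dust at depletion; the clamp keeps real mass exact.
    new_state[(new_state < 0) & (new_state > -1e-9)] = 0.0
    if np.any(new_state < 0):
        bad = np.argwhere(new_state < 0)[0]
        raise IntegrationError(
            f"pool went negative at T={temps[bad[0]]:.1f}C species={species[bad[1]]}"
        )
    if not np.all(np.isfinite(new_state)):
        bad = np.argwhere(~np.isfinite(new_state))[0]
        raise IntegrationError(
            f"non-finite state at T={temps[bad[0]]:.1f}C t={t_day:.2f}d species={species[bad[1]]}"
        )
    return new_state, scaled, carbon


def step_state(
    state: Mapping[str, float],
    specs: Sequence[ProcessSpec],
    t_celsius: float,
    dt: float,
    t_day: float = 0.0,
    sources: Sequence[SourceTerm] = (),
) -> tuple[dict[str, float], dict[str, float]]:
    """Advance a single pool map one Euler step; returns (pools, rates)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    species = list(state)
    for spec in specs:
        for sp in spec.stoichiometry:
            if sp not in state:
                raise ConfigurationError(f"{spec.name}: species {sp} missing from state")
    arr = np.array([[state[s] for s in species]], dtype=float)
    if np.any(arr < 0):
        raise IntegrationError("negative pool on entry")
    new, rates, _ = _step_arrays(arr, np.array([t_celsius]), specs, species, dt, t_day, sources)
    return (
        {s: float(new[0, i]) for i, s in enumerate(species)},
        {spec.name: float(rates[p, 0]) for p, spec in enumerate(specs)},
    )


def simulate(
    design: ExperimentDesign,
    specs: Sequence[ProcessSpec],
    sources: Sequence[SourceTerm] = (),
) -> SimulationResult:
    """Integrate the slurry model over the full design.

    The dynamics are deterministic; measurement noise enters only in the
    ``observe_*`` functions.
    """
    species = tuple(design.initial_state)
    for spec in specs:
        for sp in spec.stoichiometry:
            if sp not in species:
                raise ConfigurationError(f"{spec.name}: species {sp} missing from initial_state")
    for src in sources:
        if src.species not in species:
            raise ConfigurationError(f"source species {src.species} missing from initial_state")

    temps = np.asarray(design.temperatures, dtype=float)
    t_end = float(max(design.time_points))
    n_steps = int(math.ceil(t_end / design.dt)) + 1
    times = np.arange(n_steps) * design.dt

    state = np.zeros((len(temps), n_steps, len(species)))
    rates = np.zeros((len(specs), len(temps), n_steps))
    ledger = np.zeros((len(temps), n_steps))

    cur = np.tile(
        np.array([design.initial_state[s] for s in species], dtype=float), (len(temps), 1)
    )
    state[:, 0, :] = cur
    for k in range(1, n_steps):
        cur, applied, carbon = _step_arrays(
            cur, temps, specs, species, design.dt, times[k - 1], sources
        )
        state[:, k, :] = cur
        rates[:, :, k - 1] = applied  # rate applied over [t_{k-1}, t_k]
        ledger[:, k] = ledger[:, k - 1] + carbon
    rates[:, :, -1] = _rates_array(cur, temps, specs, species, times[-1])

    return SimulationResult(
        temperatures=temps,
        times=times,
        species=species,
        processes=tuple(specs),
        state=state,
        rates=rates,
        carbon_ledger=ledger,
    )
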