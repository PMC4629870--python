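"""In-situ Gibbs free energies of the slurry's catabolic reactions.

The standard-state energy is corrected to temperature with the integrated
Gibbs-Helmholtz relation at constant reaction enthalpy,

    dG0(T) = dG0(T0) * (T/T0) + dH0 * (1 - T/T0),      T0 = 298.15 K,

and to in-situ conditions through the reaction quotient,

    dG'r = dG0(T) + R T ln Q,

with dissolved activities in mol/L, gas activities in bar, water activity 1
and H+ referenced to pH 7 (the bundled dG0 values use the primed
convention).  Activity coefficients are taken as 1: the calculation is a
concentration-quotient screen, not a full speciation model.  A reaction is
flagged "open" (a thermodynamic window of opportunity) when dG'r falls
below a threshold, by default -10 kJ per mol reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kinetics import R_GAS

__all__ = [
    "ReactionSpec",
    "GibbsResult",
    "ActivityModel",
    "load_reactions",
    "load_species_table",
    "load_henry_table",
    "henry_constant",
    "element_imbalance",
    "check_element_balance",
    "dg0_at_temperature",
    "delta_g_prime",
    "favourability_profile",
]

T_REF = 298.15  # K
DEFAULT_OPEN_THRESHOLD = -10.0  # kJ per mol reaction


@dataclass(frozen=True)
class ReactionSpec:
    """A catabolic reaction with standard-state (pH-7) energetics."""

    name: str
    stoichiometry: Mapping[str, float]
    dg0: float  # kJ per mol reaction at 298.15 K
    dh0: float  # kJ per mol reaction, assumed temperature-independent


@dataclass(frozen=True)
class GibbsResult:
    reaction: str
    temperature: float  # K
    dg_prime: float  # kJ per mol reaction; -inf sentinel for zero substrate
    reaction_quotient_ln: float
    zero_substrate: bool = False


def _data_text(name: str) -> str:
    return resources.files("thermoslurry.data").joinpath(name).read_text()


def load_species_table() -> dict:
    """Element/charge composition of the thermodynamic species."""
    return yaml.safe_load(_data_text("reactions.yaml"))["species"]


def load_reactions(path: str | None = None) -> dict[str, ReactionSpec]:
    """The bundled (or a user-supplied) reaction table, element-checked."""
    if path is None:
        raw = yaml.safe_load(_data_text("reactions.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = raw.get("species", load_species_table())
    out = {}
    for name, spec in raw["reactions"].items():
        rx = ReactionSpec(name, dict(spec["stoichiometry"]), float(spec["dg0"]), float(spec["dh0"]))
        check_element_balance(rx, table)
        out[name] = rx
    return out


def load_henry_table() -> dict[str, dict[float, float]]:
    raw = yaml.safe_load(_data_text("henry.yaml"))
    return {g: {float(t): float(k) for t, k in tab.items()} for g, tab in raw.items()}


def henry_constant(gas: str, t_celsius: float, table=None) -> float:
    """K_H (mol L-1 bar-1) at temperature, linearly interpolated."""
    if table is None:
        table = load_henry_table()
    tab = table[gas]
    ts = np.array(sorted(tab))
    ks = np.array([tab[t] for t in ts])
    return float(np.interp(t_celsius, ts, ks))


def element_imbalance(rx: ReactionSpec, species_table: Mapping | None = None) -> dict[str, float]:
    """Net element (C,H,O,S,N) and charge imbalance; all-zero if balanced."""
    if species_table is None:
        species_table = load_species_table()
    totals: dict[str, float] = {e: 0.0 for e in ("C", "H", "O", "S", "N", "charge")}
    for sp, nu in rx.stoichiometry.items():
        if sp not in species_table:
            raise KeyError(f"{rx.name}: species {sp!r} not in element table")
        entry = species_table[sp]
        for e, n in entry.get("elements", {}).items():
            totals[e] += nu * n
        totals["charge"] += nu * entry.get("charge", 0)
    return {e: v for e, v in totals.items() if abs(v) > 1e-9}


def check_element_balance(rx: ReactionSpec, species_table: Mapping | None = None) -> None:
    bad = element_imbalance(rx, species_table)
    if bad:
        raise ValueError(f"{rx.name} is not element-balanced: {bad}")


def dg0_at_temperature(rx: ReactionSpec, t_kelvin: float) -> float:
    """Standard-state energy at temperature (kJ per mol reaction)."""
    if not (250.0 <= t_kelvin <= 400.0):
        raise ValueError(f"temperature {t_kelvin} K outside [250, 400]")
    ratio = t_kelvin / T_REF
    return rx.dg0 * ratio + rx.dh0 * (1.0 - ratio)


def _activity(sp: str, state: Mapping[str, float], ph: float | None, species_table) -> float:
    phase = species_table[sp]["phase"]
    if phase == "water":
        return 1.0
    if phase == "proton":
        if ph is not None:
            return 10.0 ** (-(ph - 7.0))
        return float(state.get("H+", 1.0))
    if sp not in state:
        raise KeyError(f"species {sp!r} missing from state")
    return float(state[sp])


def delta_g_prime(
    rx: ReactionSpec,
    state: Mapping[str, float],
    t_kelvin: float,
    ph: float | None = None,
) -> GibbsResult:
    """dG'r under in-situ conditions.

    ``state`` maps species to activity (mol/L dissolved, bar gas).  A zero
    activity on a consumed species makes the reaction formally infinitely
    favourable; a -inf sentinel is returned with the zero_substrate flag so
    the caller can treat it as non-physical.
    """
    table = load_species_table()
    ln_q = 0.0
    zero_substrate = False
    for sp, nu in rx.stoichiometry.items():
        a = _activity(sp, state, ph, table)
        if a < 0:
            raise ValueError(f"negative activity for {sp}")
        if a == 0.0:
            if nu < 0:
                zero_substrate = True
            else:
                return GibbsResult(rx.name, t_kelvin, math.inf, math.inf)
        else:
            ln_q += nu * math.log(a)
    if zero_substrate:
        return GibbsResult(rx.name, t_kelvin, -math.inf, -math.inf, zero_substrate=True)
    dg = dg0_at_temperature(rx, t_kelvin) + (R_GAS / 1000.0) * t_kelvin * ln_q
    return GibbsResult(rx.name, t_kelvin, dg, ln_q)


@dataclass
class ActivityModel:
    """Maps measured pools (uM, gas-equivalent for headspace species) to the
    activities the energy calculation needs.

    Gases are converted from dissolved-equivalent concentration to partial
    pressure through Henry's law; DIC enters as CO2 using a fixed CO2
    fraction (no carbonate speciation).  Pools the time series does not
    carry fall back to ``defaults`` (mol/L).
    """

    ph: float = 7.5
    co2_fraction_of_dic: float = 0.05
    defaults: dict[str, float] = field(default_factory=lambda: {"sulphide": 1.0e-3})
    #: measured species name -> (thermo species, kind)
    mapping: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "acetate": ("acetate", "dissolved"),
            "sulphate": ("sulphate", "dissolved"),
            "ammonium": ("ammonium", "dissolved"),
            "methylamine": ("methylammonium", "dissolved"),
            "hydrogen": ("H2", "gas"),
            "methane": ("CH4", "gas"),
            "dic": ("CO2", "dic"),
        }
    )

    def state_from_pools(self, pools: Mapping[str, float], t_celsius: float,
                         henry_table=None) -> dict[str, float]:
        if henry_table is None:
            henry_table = load_henry_table()
        state = dict(self.defaults)
        for meas, (sp, kind) in self.mapping.items():
            if meas not in pools:
                continue
            molar = float(pools[meas]) * 1e-6  # uM -> mol/L
            if kind == "dissolved":
                state[sp] = molar
            elif kind == "gas":
                state[sp] = molar / henry_constant(sp, t_celsius, henry_table)
            elif kind == "dic":
                state[sp] = molar * self.co2_fraction_of_dic / henry_constant(
                    "CO2", t_celsius, henry_table
                )
        return state


def favourability_profile(
    rx: ReactionSpec,
    series: pd.DataFrame,
    model: ActivityModel | None = None,
    threshold: float = DEFAULT_OPEN_THRESHOLD,
) -> pd.DataFrame:
    """dG'r per (temperature, time) from a long-format concentration table.

    Returns columns temperature, time, dg_prime, open (dG'r < threshold).
    Cells missing a required species are skipped and counted in the
    DataFrame's ``attrs['skipped']``.
    """
    if model is None:
        model = ActivityModel()
    henry = load_henry_table()
    rows = []
    skipped = 0
    pools = (
        series.groupby(["temperature", "time", "species"])["value"].mean().unstack("species")
    )
    for (temp, t), row in pools.iterrows():
        state = model.state_from_pools(row.dropna().to_dict(), float(temp), henry)
        try:
            res = delta_g_prime(rx, state, float(temp) + 273.15, ph=model.ph)
        except KeyError:
            skipped += 1
            continue
        rows.append((float(temp), float(t), res.dg_prime, bool(res.dg_prime < threshold)))
    out = pd.DataFrame(rows, columns=["temperature", "time", "dg_prime", "open"])
    out.attrs["skipped"] = skipped
    return out
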