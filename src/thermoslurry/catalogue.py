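"""Default model configuration: species, process catalogue, organic-matter
source terms and experiment designs.

The catalogue encodes the activity zones observed on the thermal gradient:
acetoclastic metal reduction (up to ~34 degC, optimum 25), acetoclastic
sulphate reduction (optimum 29, up to ~43), hydrogenotrophic sulphate
reduction (optimum 61-69, active ~43-73), methylotrophic methanogenesis
(~12-43), acetoclastic methanogenesis (30-43 and 50-65), hydrogenotrophic
methanogenesis (up to ~20 and 45-80) and hydrogenotrophic acetogenesis
(43-80), with thermal activation of sedimentary organic matter supplying H2,
acetate and methylamine increasingly above ~40 degC.  Window positions come
from the observed zones; rate amplitudes are calibration choices anchored to
the printed maximum rates (acetate oxidation ~1644, sulphate reduction ~602
nmol cm-3 day-1) and are fully config-overridable.

All pools are uM (== nmol cm-3 under the 1 cm3 == 1 mL slurry convention).
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import ChemSpecies, ExperimentDesign, ProcessSpec, SourceTerm, ThermalWindow

__all__ = [
    "SPECIES",
    "default_processes",
    "optional_processes",
    "default_sources",
    "default_design",
    "TRACER_ASSAYS",
    "COPIES_PER_CELL",
    "SPECIES_CARBON",
]

SPECIES = (
    ChemSpecies("sulphate"),
    ChemSpecies("hydrogen", phase="gas"),
    ChemSpecies("methane", phase="gas"),
    ChemSpecies("acetate"),
    ChemSpecies("methylamine"),
    ChemSpecies("ammonium"),
    ChemSpecies("dic", phase="gas"),
    ChemSpecies("metal_oxide"),
)

#: mol organic carbon per mol species, for the carbon ledger and mass checks
SPECIES_CARBON = {"acetate": 2.0, "methylamine": 1.0, "hydrogen": 0.0}

#: 16S rRNA gene copies per cell (rrnDB averages)
COPIES_PER_CELL = {"Bacteria": 4.19, "Archaea": 1.71}


def default_processes() -> list[ProcessSpec]:
    """The shipped process catalogue (fresh instances, safe to modify)."""
    return [
        ProcessSpec(
            name="acetoclastic_metal_reduction",
            # CH3COO- + 8 Fe(III) -> 2 CO2 + 8 Fe(II); rate in acetate units
            stoichiometry={"acetate": -1, "metal_oxide": -8, "dic": +2},
            rate_species="acetate",
            r_max=850.0,
            windows=(ThermalWindow(25.0, 9.0, 4.5),),
            half_saturation={"acetate": 10.0, "metal_oxide": 1000.0},
            onset_day=2.0,
            ea=50.0,
            co2_factor=+2.0,
            tracer_substrate="acetate",
        ),
        ProcessSpec(
            name="acetoclastic_sulphate_reduction",
            # CH3COO- + SO4-- -> 2 CO2 + HS-; rate in acetate units
            stoichiometry={"acetate": -1, "sulphate": -1, "dic": +2},
            rate_species="acetate",
            r_max=100.0,
            windows=(ThermalWindow(29.0, 8.0, 5.0),),
            half_saturation={"acetate": 10.0, "sulphate": 200.0},
            onset_day=2.0,
            ea=56.8,
            co2_factor=+2.0,
            tracer_substrate="acetate",
        ),
        ProcessSpec(
            name="hydrogenotrophic_sulphate_reduction",
            # 4 H2 + SO4-- -> HS- + 4 H2O; rate in sulphate units
            stoichiometry={"hydrogen": -4, "sulphate": -1},
            rate_species="sulphate",
            r_max=650.0,
            windows=(ThermalWindow(65.0, 8.0, 2.8),),
            half_saturation={"hydrogen": 2.0, "sulphate": 200.0},
            onset_day=3.0,
            ea=8.9,
            co2_factor=0.0,
        ),
        ProcessSpec(
            name="methylotrophic_methanogenesis",
            # 4 CH3NH2 + 2 H2O -> 3 CH4 + CO2 + 4 NH3; rate in methylamine units
            stoichiometry={"methylamine": -4, "methane": +3, "dic": +1, "ammonium": +4},
            rate_species="methylamine",
            r_max=40.0,
            windows=(ThermalWindow(30.0, 9.0, 4.0),),
            half_saturation={"methylamine": 20.0},
            onset_day=2.0,
            ea=100.0,
            co2_factor=+0.25,
            tracer_substrate="methylamine",
        ),
        ProcessSpec(
            name="acetoclastic_methanogenesis",
            # CH3COO- + H+ -> CH4 + CO2; rate in acetate units
            stoichiometry={"acetate": -1, "methane": +1, "dic": +1},
            rate_species="acetate",
            r_max=6.0,
            windows=(ThermalWindow(36.0, 3.0, 2.5, weight=0.25), ThermalWindow(55.0, 2.5, 4.0)),
            half_saturation={"acetate": 50.0},
            onset_day=10.0,
            ea=75.0,
            co2_factor=+1.0,
            tracer_substrate="acetate",
        ),
        ProcessSpec(
            name="hydrogenotrophic_methanogenesis",
            # 4 H2 + CO2 -> CH4 + 2 H2O; rate in CH4 (== CO2 consumed) units
            stoichiometry={"hydrogen": -4, "dic": -1, "methane": +1},
            rate_species="methane",
            r_max=25.0,
            windows=(ThermalWindow(12.0, 6.0, 4.0, weight=0.4), ThermalWindow(70.0, 9.0, 7.0)),
            half_saturation={"hydrogen": 1.0, "dic": 500.0},
            onset_day=40.0,
            ea=30.0,
            co2_factor=-1.0,
            tracer_substrate="dic",
        ),
        ProcessSpec(
            name="hydrogenotrophic_acetogenesis",
            # 4 H2 + 2 CO2 -> CH3COO- + H+ + 2 H2O; rate in acetate units
            stoichiometry={"hydrogen": -4, "dic": -2, "acetate": +1},
            rate_species="acetate",
            r_max=18.0,
            windows=(ThermalWindow(70.0, 12.0, 8.0),),
            half_saturation={"hydrogen": 5.0, "dic": 500.0},
            onset_day=5.0,
            ea=120.0,
            co2_factor=-2.0,
            tracer_substrate="dic",
        ),
    ]


def optional_processes() -> list[ProcessSpec]:
    """Off-by-default processes the study infers only indirectly."""
    return [
        ProcessSpec(
            name="anaerobic_oxidation_of_methane",
            # CH4 + SO4-- -> HCO3- + HS- + H2O; rate in methane units
            stoichiometry={"methane": -1, "sulphate": -1, "dic": +1},
            rate_species="methane",
            r_max=2.0,
            windows=(ThermalWindow(35.0, 15.0, 10.0),),
            half_saturation={"methane": 50.0, "sulphate": 500.0},
            onset_day=10.0,
            ea=60.0,
            co2_factor=+1.0,
        ),
        ProcessSpec(
            name="anaerobic_ammonium_oxidation",
            stoichiometry={"ammonium": -1},
            rate_species="ammonium",
            r_max=5.0,
            windows=(ThermalWindow(24.0, 6.0, 6.0),),
            half_saturation={"ammonium": 200.0},
            onset_day=15.0,
            ea=60.0,
            co2_factor=0.0,
        ),
    ]


def default_sources() -> list[SourceTerm]:
    """Organic-matter supply of H2, acetate and methylamine.

    A mesophilic fermentative window feeds acetate and methylamine around
    ambient temperatures; logistic thermal-activation terms switch on above
    ~40 degC, supplying the H2 that drives thermophilic sulphate reduction
    and the acetate that accumulates at high temperature.
    """
    return [
        SourceTerm("acetate", 800.0, mode="window",
                   window=ThermalWindow(25.0, 12.0, 5.0), carbon=2.0),
        SourceTerm("acetate", 25.0, mode="logistic", t_mid=48.0, width=3.0, carbon=2.0),
        SourceTerm("methylamine", 3.0, mode="window",
                   window=ThermalWindow(25.0, 12.0, 8.0), carbon=1.0),
        SourceTerm("methylamine", 0.5, mode="logistic", t_mid=48.0, width=3.0, carbon=1.0),
        SourceTerm("hydrogen", 3.0, mode="window",
                   window=ThermalWindow(20.0, 15.0, 8.0), carbon=0.0),
        SourceTerm("hydrogen", 600.0, mode="logistic", t_mid=50.0, width=3.0, carbon=0.0),
    ]


#: initial pools, uM (sulphate after the pre-incubation to steady state)
_INITIAL_UNAMENDED = {
    "sulphate": 12000.0,
    "hydrogen": 45.0,
    "methane": 1.0,
    "acetate": 10.0,
    "methylamine": 50.0,
    "ammonium": 500.0,
    "dic": 30000.0,
    "metal_oxide": 500000.0,
}

#: amendment: 2 mM acetate, 2 mM methylamine, H2:CO2 headspace (~36 mM gas-eq.)
_AMENDED_OVERRIDES = {"acetate": 2000.0, "methylamine": 2000.0, "hydrogen": 36000.0}

#: left-censoring limits, uM (organic acids <1 uM; methylamine ~120 uM)
_DETECTION_LIMITS = {"acetate": 1.0, "methylamine": 120.0}


def default_design(
    scenario: str = "unamended",
    temperatures=None,
    time_points=(15.0, 40.0, 62.0, 80.0, 100.0),
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    dt: float = 0.1,
) -> ExperimentDesign:
    """The shipped experiment design: 0-80 degC grid, five sampling series."""
    if temperatures is None:
        temperatures = list(range(0, 81, 1))
    initial = dict(_INITIAL_UNAMENDED)
    if scenario == "amended":
        initial.update(_AMENDED_OVERRIDES)
    return ExperimentDesign(
        temperatures=temperatures,
        time_points=time_points,
        replicates=replicates,
        scenario=scenario,
        initial_state=initial,
        noise_cv=noise_cv,
        detection_limits=dict(_DETECTION_LIMITS),
        seed=seed,
        dt=dt,
    )


@dataclass(frozen=True)
class TracerAssay:
    """One radiotracer assay: labelled substrate pool and the processes whose
    turnover it integrates (with conversion from each process's rate unit to
    substrate units)."""

    name: str
    substrate: str
    processes: tuple[str, ...]
    co2_double: bool = False  # acetate -> 2 CO2 bookkeeping convention


#: the five 14C assays; acetate oxidation integrates both electron acceptors
TRACER_ASSAYS = (
    TracerAssay(
        "acetate_oxidation",
        "acetate",
        ("acetoclastic_metal_reduction", "acetoclastic_sulphate_reduction"),
        co2_double=True,
    ),
    TracerAssay("acetoclastic_methanogenesis", "acetate", ("acetoclastic_methanogenesis",)),
    TracerAssay(
        "hydrogenotrophic_methanogenesis", "dic", ("hydrogenotrophic_methanogenesis",)
    ),
    TracerAssay("hydrogenotrophic_acetogenesis", "dic", ("hydrogenotrophic_acetogenesis",)),
    TracerAssay(
        "methylotrophic_methanogenesis", "methylamine", ("methylotrophic_methanogenesis",)
    ),
)
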