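# thermoslurry

Quantitative machinery for thermal-gradient anaerobic sediment slurry
experiments: coastal sediment is slurried into sealed vials, incubated at
fixed temperatures between 0 and 80 °C for up to 100 days, and monitored by
pore-water/headspace chemistry, ¹⁴C radiotracer turnover and 16S rRNA qPCR.
The package is for biogeochemists who want to analyse such experiments —
or rehearse the full analysis on synthetic experiments with known ground
truth before committing to the bench.

It provides, as composable stages:

- **Simulator** — coupled substrate pools (SO₄²⁻, H₂, CH₄, acetate,
  methylamine, NH₄⁺, DIC, metal oxide) driven by anaerobic processes that
  are active inside Gaussian *temperature windows of opportunity*, with
  Monod substrate limitation, thermal activation of sedimentary organic
  matter, measurement noise and detection limits; every true rate is
  recorded, so downstream estimators can be validated exactly.
- **Rate estimation** — radiotracer turnover
  `rate = (product activity / added activity) · pool / duration`
  (×2 for acetate oxidation to CO₂, two CO₂ per acetate), averaged as the
  mean of three time-point means; sulphate removal rates from
  concentration differences between sampling points.
- **Kinetics** — Arrhenius fits `ln k = ln A − Ea/(RT)`, two-regime fits
  with an exhaustive break search, and
  `Q10 = exp((Ea/R)·ΔT/(T₁T₂))` over the 10–20 °C convention.
- **Thermodynamics** — in-situ Gibbs energies
  `ΔG′ = ΔG°(T) + RT ln Q` for the six core catabolic reactions, with
  Gibbs–Helmholtz temperature correction and Henry-law gas handling.
- **Carbon balance** — signed per-process CO₂ factors summed into a net
  mineralization balance across temperature and time.
- **Partitioning** — a stoichiometric lower bound on the hydrogenotrophic
  fraction of sulphate reduction, and piecewise-linear breakpoint detection
  for critical temperatures.
- **Cell abundances** — 16S gene copies to cells (4.19 copies per
  bacterial, 1.71 per archaeal cell).

## Worked example

```python
import numpy as np
from thermoslurry import q10_from_ea, fit_arrhenius, simulate
from thermoslurry.catalogue import default_design, default_processes, default_sources
from thermoslurry.observe import observe_concentrations, observe_tracers
from thermoslurry.io import aggregate_tracer_rates
from thermoslurry.rates import sulphate_removal_rates, max_rate_profile
from thermoslurry.partition import partition_profile

# the temperature sensitivity implied by an activation energy, 10-20 C
print("Q10 at Ea=8.9 kJ/mol: %.1f" % q10_from_ea(8.9).q10)
print("Q10 at Ea=56.8 kJ/mol: %.1f" % q10_from_ea(56.8).q10)

# a full synthetic experiment: 0-80 C, 100 days, exact observations
design = default_design(seed=1, noise_cv=0.0)
sim = simulate(design, default_processes(), default_sources())
print("acetate at 55 C, day 100: %.2f mM" % (sim.at(55, 100, "acetate") / 1000))

so4 = sim.state[:, :, sim.species_index("sulphate")]
decline = (so4[:, 0] - so4[:, -1]) / so4[:, 0]
print("sulphate removal up to %.0f C" % sim.temperatures[decline > 0.05].max())

rates = aggregate_tracer_rates(observe_tracers(sim, design))
rates += sulphate_removal_rates(observe_concentrations(sim, design))
prof = partition_profile(rates, pairing="max")
print(">=50%% hydrogenotrophic sulphate reduction from %.0f C"
      % prof.threshold_temperature)
```

prints

```
Q10 at Ea=8.9 kJ/mol: 1.1
Q10 at Ea=56.8 kJ/mol: 2.3
acetate at 55 C, day 100: 2.11 mM
sulphate removal up to 73 C
>=50% hydrogenotrophic sulphate reduction from 42 C
```

Reading the output: a process with a low activation energy (8.9 kJ mol⁻¹)
barely responds to a 10 °C warming (Q10 1.1), while a 56.8 kJ mol⁻¹
process more than doubles. In the simulated slurries, acetate piles up past
1 mM at 55 °C because its mesophilic consumers have shut down while
thermal activation of organic matter keeps supplying it; sulphate removal
persists to ~73 °C, the upper window of the thermophilic H₂-driven
sulphate reducers; and from ~42 °C upward at least half of sulphate
reduction runs on H₂ rather than acetate — the critical-temperature switch
from organotrophic to lithotrophic metabolism.

The same pipeline runs from the shell over CSV tables:

```sh
thermoslurry run --config examples/demo.yaml --seed 1 --out out/
thermoslurry kinetics --rates out/rates.csv --process sulphate_removal \
    --break-grid 30:60:1 --temp-range 11:69 --out out/kinetics_srr.csv
```

Table schemas are documented in `docs/schemas.md`, the model and its
assumptions in `docs/methods.md`.

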