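# Methods

`thermoslurry` models and analyses sealed anaerobic sediment-slurry
incubations distributed along a 0–80 °C thermal gradient for up to 100
days. This note documents the model, its parameters, the numerical choices,
and what the synthetic experiments do and do not establish about real data.

## Units and conventions

One cm³ of slurry is treated as one mL, so a concentration in µM is
numerically a pool in nmol cm⁻³ and every rate is in nmol cm⁻³ day⁻¹.
Headspace gases (H₂, CH₄, CO₂/DIC) are carried as µM gas-equivalent
referenced to slurry volume. Temperatures are stored in °C and converted to
kelvin (T + 273.15) only inside the kinetics and thermodynamics modules.

## The slurry simulator

State: eight pools — sulphate, H₂, CH₄, acetate, methylamine, ammonium,
DIC (a single pool; no carbonate speciation) and sedimentary metal oxide.

Each anaerobic process has a stoichiometry (signed mol per mol of reaction
advance), a reporting species for its rate, Monod half-saturation constants
for its substrates, a lag (`onset_day`) and one or more asymmetric Gaussian
*temperature windows of opportunity*:

    w(T) = weight · exp(−(T − T_opt)² / 2σ²),  σ = σ_left below T_opt,
                                               σ = σ_right above,

combined across windows by maximum. The instantaneous rate is

    r(T, t) = r_max · w(T) · Π_substrates c/(c + K) · [t ≥ onset].

The windows are phenomenology, not mechanism: the study system shows
activity zones (e.g. methylamine-driven methanogenesis only below ~43 °C,
hydrogenotrophic sulphate reduction between ~43 and ~73 °C), and the
Gaussian-window catalogue reproduces those zones without resolving the
underlying community dynamics.

Integration is explicit Euler at dt = 0.1 day (pool dynamics are slow and
smooth at that step) with a per-step limiting-substrate clamp: if a step
would consume more of any substrate than is present, every process
consuming that substrate is scaled down so consumption exactly exhausts the
pool, keeping stoichiometry exact at depletion. Pools therefore never go
negative for any configuration.

Thermal activation of sedimentary organic matter is modelled as
temperature-dependent source terms releasing acetate, methylamine and H₂: a
mesophilic fermentative window centred near ambient temperature, plus
logistic terms switching on near 48–50 °C that supply the H₂ driving
thermophilic sulphate reduction and the acetate that accumulates above
50 °C. All organic carbon added this way is recorded in a cumulative carbon
ledger, giving the exact identity

    Δ(DIC + CH₄ + 2·acetate + methylamine) = ledgered carbon,

used as an independent mass-balance oracle in the tests (≤1e−6 relative).

### Default catalogue and calibration

Window positions follow the observed activity zones; amplitudes were
calibrated once against the reported maximum rates (acetate oxidation
~1.6 µmol cm⁻³ day⁻¹ at 25 °C, sulphate reduction ~0.6 µmol cm⁻³ day⁻¹ at
69 °C) and qualitative surfaces: sulphate removal bimodal with optima near
29 and 65 °C and an upper limit near 73 °C; methylamine turnover ceasing
above ~43 °C; acetate exceeding 1 mM by day 100 at and above 50 °C; at
least half of sulphate reduction hydrogenotrophic from ~42–43 °C upward.
Low-temperature acetoclastic sulphate reduction capacity (r_max = 100) is
deliberately far below acetate-oxidation capacity (r_max = 850), consistent
with acetate oxidation exceeding sulphate reduction many-fold below 43 °C;
that is what leaves mesophilic sulphate only partially removed while
H₂-driven thermophilic sulphate reduction removes it completely. Initial
pools (unamended): 12 mM sulphate, 45 µM H₂, 10 µM acetate, 50 µM
methylamine, 0.5 mM ammonium, 30 mM DIC, 0.5 M metal oxide. The amended
scenario overrides acetate and methylamine to 2 mM and H₂ to 36 mM
gas-equivalent. Everything is config-overridable; anaerobic methane and
ammonium oxidation ship off by default.

### Observation model

Measurement noise is multiplicative lognormal with unit mean (CV 0.05 by
default) — concentrations cannot go negative. Values under a species
detection limit (1 µM for acetate, 120 µM for methylamine) are reported *at*
the limit with a below-detection flag (left-censoring). Radiotracer
incubations are synthesized in triplicate at three increasing durations
(default 7, 14 and 29 minutes — short enough that label turnover stays
linear even for the acetate pool, whose turnover time can fall below one
hour); the product-activity fraction is rate × duration / pool with the
pool taken at incubation start. qPCR tables come from a simple abundance
model: cell densities grow with the cumulative substrate turnover of the
processes each domain carries (sulphate/metal reducers and acetogens for
Bacteria, methanogens for Archaea) and decay under a thermal mortality term
above ~60 °C; copies = cells × copies-per-cell (4.19 bacterial, 1.71
archaeal).

## Rate estimation

Tracer turnover uses the first-order single-time-point form

    rate = (product activity / added activity) · pool / duration,

without back-reaction or isotope-fractionation corrections; acetate
oxidation to CO₂ is multiplied by 2 (two CO₂ per acetate). Replicates are
averaged within each of the three incubation durations and the estimate is
the unweighted mean of the (≤3) time-point means, with dispersion the
sample sd of those means. Sulphate removal rates are concentration
differences between consecutive sampling points assigned to the interval
midpoint (unbiased for a linear decline); negative differences are reported
as 0 with the raw value retained. Arrhenius analysis uses the per-
temperature maximum rate over time.

## Kinetics

Ordinary least squares of ln k on 1/T gives Ea = −slope·R (R = 8.314
J K⁻¹ mol⁻¹); zero rates cannot be logged and are excluded (and counted),
never pseudo-counted. Q10 is evaluated over the 10–20 °C convention
(283.15/293.15 K) as exp((Ea/R)·ΔT/(T₁T₂)); reporting rounds Ea and Q10 to
one decimal. The two-regime fit searches a candidate-break grid
exhaustively, fits both sides in ln space and minimizes total SSE, ties
resolved toward the lower temperature; when no candidate leaves three
positive points on each side, the single-regime fit is returned flagged.
The `improvement` statistic (1 − SSE₂/SSE₁) is reported, not thresholded:
under a noisy null the exhaustive search inflates it by selection, so
judgements should compare it against the improvement a genuine break
produces. A numerically zero single-fit SSE reports improvement 0.

## Thermodynamics

ΔG°′ is corrected to temperature with the integrated Gibbs–Helmholtz
relation at constant ΔH° (ΔG°(T) = ΔG°(T₀)·T/T₀ + ΔH°·(1 − T/T₀),
T₀ = 298.15 K) and to in-situ conditions by R·T·ln Q. Activities: dissolved
species in mol L⁻¹, gases in bar, water 1, H⁺ relative to pH 7 (the bundled
ΔG°′ values use the primed convention); activity coefficients are 1 — this
is a concentration-quotient screen, not a speciation model. The six bundled
reactions (hydrogenotrophic methanogenesis / acetogenesis / sulphate
reduction; acetoclastic methanogenesis / sulphate reduction; methylamine
methanogenesis) carry ΔG°′/ΔH° compiled from standard formation-energy
tabulations and live in an editable YAML, element- and charge-checked at
load. Dissolved gas-equivalent pools convert to partial pressures through
a bundled, linearly interpolated Henry-constant table; DIC enters as CO₂
through a fixed CO₂ fraction (default 0.05). A reaction is "open" when
ΔG′ < −10 kJ per mol reaction (configurable). A zero substrate activity
returns a −∞ sentinel with a flag rather than pretending infinite
favourability is physical.

## Carbon balance

Signed CO₂ factors per unit of each process's reported rate:
+2 acetoclastic metal reduction and acetoclastic sulphate reduction (per
acetate), +1 acetate oxidation (already in CO₂ units), +1 acetoclastic
methanogenesis, +0.25 methylamine methanogenesis (4 CH₃NH₂ → 3 CH₄ + CO₂),
−1 hydrogenotrophic methanogenesis, −2 hydrogenotrophic acetogenesis, 0
hydrogenotrophic sulphate reduction. These are stoichiometric
reconstructions (the source compilation for the factors is not public) and
are fully overridable; a process without a factor is an error, never a
silent default. Net = exact sum of contributions; summary means are taken
below vs at/above a split temperature (default 43 °C). On noise-free
simulated truth the factor-weighted rate sum reproduces d(DIC)/dt cell by
cell, which the tests assert within 5%.

## Partitioning and breakpoints

With 1:1 acetate:sulphate and 4:1 H₂:sulphate stoichiometries, the
acetate-fuelled share of sulphate reduction is at most the measured acetate
oxidation rate (CO₂-unit rates halved back to acetate units), giving the
lower bound fraction_h2_min = (SRR − min(SRR, acox))/SRR. Other organic
donors are deliberately folded into the non-acetate bound ("at least").
Default pairing compares per-temperature maxima over time; timewise pairing
(nearest sampling time) is the mode in which the bound is exact against
instantaneous truth, and is switchable. The breakpoint detector is the same
exhaustive two-segment least squares as the kinetics module but on linear
axes. With a continuous kink, the kink point lies on both segments, so the
break is identified only up to one data spacing (the tie rule returns the
lower candidate); sharper identification needs either dense profiles or a
genuine discontinuity between regimes.

## Validation scale and scope

The shipped validation runs use the full 0–80 °C grid at 1 °C steps, 100
days at dt = 0.1 day (a run takes well under a minute), 200-seed Monte
Carlo studies for Arrhenius/break recovery, and a 92-point profile for
noisy breakpoint recovery. Partition-bound validation uses exact
(noise-free) observations: differencing a 12 mM sulphate pool at 5%
measurement noise produces spurious removal rates of the same order as the
small mesophilic signal, a genuine limitation of difference-based rates
that the noisy end-to-end tests would otherwise re-discover as trivial
bound violations.

What passing tests show: the estimators invert the simulator's own
generating model (turnover formula, window kinetics, lognormal noise) at
the stated tolerances, and the search procedures match brute-force oracles
exactly. What they do not show: that real slurries follow Gaussian windows
or first-order turnover, that tracer back-reactions and isotope effects are
negligible, or that the reconstructed CO₂ factors match the original
bookkeeping — those remain modelling assumptions.

## Known limitations

- No carbonate speciation, ionic-strength corrections, or pressure terms.
- The unamended H₂ pool is a one-time initial 45 µM (no replenishment path
  besides organic-matter activation).
- Amended-scenario community feedbacks (e.g. 10× bacterial growth) are not
  modelled beyond larger substrate pools.
- Below-detection handling reports the limit itself; no imputation.
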