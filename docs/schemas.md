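# Table schemas

All files are UTF-8 CSV with "." decimal separator, temperatures in °C,
times in days, concentrations in µM (≡ nmol cm⁻³), rates in
nmol cm⁻³ day⁻¹. Every file written by the package starts with a
header-comment block:

    # thermoslurry v<version>
    # config_hash: <12-hex digest of the run configuration>
    # schema: docs/schemas.md

Readers skip lines starting with `#`.

## concentrations.csv (long format)

| column | type | meaning |
|---|---|---|
| temperature | float | incubation temperature |
| time | float | sampling day |
| species | str | pool name (sulphate, hydrogen, methane, acetate, methylamine, ammonium, dic, metal_oxide) |
| replicate | int | replicate vial, 1-based |
| value | float | concentration; censored rows hold the detection limit. On input, `<LIMIT` strings (e.g. `<1`) are accepted |
| below_detection | bool | left-censoring flag |

## tracers.csv

| column | type | meaning |
|---|---|---|
| process | str | assay name (acetate_oxidation, acetoclastic_methanogenesis, hydrogenotrophic_methanogenesis, hydrogenotrophic_acetogenesis, methylotrophic_methanogenesis) |
| temperature | float | |
| start_day | float | incubation start |
| duration | float | days |
| added_activity | float | label added (arbitrary activity units) |
| product_activity | float | label recovered in product |
| pool | float | substrate pool at start, µM |
| replicate | int | |
| timepoint_index | int | 1..3, increasing duration |
| zero_pool | bool | warning flag: pool was zero |

## qpcr.csv

domain (Bacteria|Archaea), temperature, time, replicate, copies_per_ml.

## rates.csv

process, temperature, time, rate, sd, n, raw_rate (pre-clamp value where
clamping applied, else = rate), flags (`|`-joined: clamped,
single_timepoint, zero_pool). `acetate_oxidation` rates are in CO₂ units
(doubled); other tracer assays in substrate units; `sulphate_removal` rows
are interval rates assigned to interval midpoints.

## kinetics.csv

process, side (left|right of break), ea_kj_mol (1 d.p.), ln_a, r_squared,
q10 (1 d.p., 10–20 °C convention), break_temp, improvement, n_points,
n_excluded (non-positive rates dropped before logging), fallback.

## gibbs.csv

reaction, temperature, time, dg_prime (kJ per mol reaction), open
(ΔG′ below the configured threshold).

## balance.csv / balance_summary.csv

balance.csv: temperature, time, one signed CO₂-rate column per process,
net (exact row sum). balance_summary.csv: split_temp, mean_below,
mean_above, ratio_below_over_above.

## partition.csv

temperature, time, srr, acox_acetate_units, fraction_h2_min, degenerate.

## cells.csv

domain, temperature, time, cells_per_ml, sd, n, single_replicate,
divisor_used, archaeal_share (fraction of total mean cells).

## true_rates.csv (simulator ground truth)

process, temperature, time, rate — instantaneous rates in each process's
reporting unit at the design sampling times.

## run_report.csv

key/value pairs: config_hash, version, per-output row counts, warnings.
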