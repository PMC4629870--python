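# Catabolic reactions screened for in-situ favourability.
#
# dg0 / dh0 are kJ per mol reaction at 298.15 K under the pH-7 (primed)
# convention, compiled from standard formation energies and enthalpies of
# the anaerobe-energetics literature (Thauer-style tabulations).  They are
# editable calibration data, not measured values from any one experiment.
#
# Species activities: dissolved species in mol/L, gases in bar, water 1,
# "H+" relative to 1e-7 (so pH 7 gives activity 1).

species:
  H2:             {phase: gas,       elements: {H: 2},             charge: 0}
  CO2:            {phase: gas,       elements: {C: 1, O: 2},       charge: 0}
  CH4:            {phase: gas,       elements: {C: 1, H: 4},       charge: 0}
  H2O:            {phase: water,     elements: {H: 2, O: 1},       charge: 0}
  "H+":           {phase: proton,    elements: {H: 1},             charge: 1}
  acetate:        {phase: dissolved, elements: {C: 2, H: 3, O: 2}, charge: -1}
  sulphate:       {phase: dissolved, elements: {S: 1, O: 4},       charge: -2}
  sulphide:       {phase: dissolved, elements: {H: 1, S: 1},       charge: -1}  # HS-
  methylammonium: {phase: dissolved, elements: {C: 1, H: 6, N: 1}, charge: 1}
  ammonium:       {phase: dissolved, elements: {N: 1, H: 4},       charge: 1}

reactions:
  hydrogenotrophic_methanogenesis:
    stoichiometry: {H2: -4, CO2: -1, CH4: 1, H2O: 2}
    dg0: -130.7
    dh0: -253.0
  hydrogenotrophic_acetogenesis:
    stoichiometry: {H2: -4, CO2: -2, acetate: 1, "H+": 1, H2O: 2}
    dg0: -94.9
    dh0: -270.6
  hydrogenotrophic_sulphate_reduction:
    stoichiometry: {H2: -4, sulphate: -1, "H+": -1, sulphide: 1, H2O: 4}
    dg0: -152.3
    dh0: -251.5
  acetoclastic_methanogenesis:
    stoichiometry: {acetate: -1, "H+": -1, CH4: 1, CO2: 1}
    dg0: -35.9
    dh0: 17.7
  acetoclastic_sulphate_reduction:
    stoichiometry: {acetate: -1, sulphate: -1, "H+": -2, CO2: 2, sulphide: 1, H2O: 2}
    dg0: -57.4
    dh0: 19.1
  methylotrophic_methanogenesis:
    stoichiometry: {methylammonium: -4, H2O: -2, CH4: 3, CO2: 1, ammonium: 4}
    dg0: -225.4
    dh0: -235.0
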