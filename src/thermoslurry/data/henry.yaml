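# Henry solubility constants K_H (mol L-1 bar-1) vs temperature (degC),
# linearly interpolated; used to convert dissolved gas-equivalent pools
# (uM referenced to slurry volume) into equivalent partial pressures.
H2:  {0: 9.8e-4, 10: 8.8e-4, 25: 7.8e-4, 40: 7.3e-4, 60: 7.0e-4, 80: 7.1e-4}
CH4: {0: 2.5e-3, 10: 1.9e-3, 25: 1.4e-3, 40: 1.2e-3, 60: 1.0e-3, 80: 9.5e-4}
CO2: {0: 7.6e-2, 10: 5.3e-2, 25: 3.4e-2, 40: 2.4e-2, 60: 1.7e-2, 80: 1.3e-2}
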