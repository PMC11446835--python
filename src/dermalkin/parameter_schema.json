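{
  "description": "Parameter schema for the four-compartment transdermal ethanol model. Keys match the model symbols used in config files and ModelParameters.",
  "parameters": {
    "beta_b": {"description": "Solubility of ethanol in blood", "units": "mL ethanol/(100 mL medium)/Torr", "default": 232.0, "uncertainty_fraction": 0.10, "varied": true},
    "beta_e": {"description": "Solubility of ethanol in epidermis", "units": "mL ethanol/(100 mL medium)/Torr", "default": 232.0, "uncertainty_fraction": 0.20, "varied": true},
    "beta_s": {"description": "Solubility of ethanol in stratum corneum", "units": "mL ethanol/(100 mL medium)/Torr", "default": 211.0, "uncertainty_fraction": 0.25, "varied": true},
    "D_e": {"description": "Molecular diffusivity of ethanol in epidermis", "units": "cm^2/s", "default": 5e-06, "uncertainty_fraction": 0.25, "varied": true},
    "D_s": {"description": "Molecular diffusivity of ethanol in stratum corneum", "units": "cm^2/s", "default": 5e-10, "uncertainty_fraction": 0.50, "varied": true},
    "L_e": {"description": "Thickness of epidermis", "units": "cm", "default": 0.02, "uncertainty_fraction": 0.25, "varied": true},
    "L_s": {"description": "Thickness of stratum corneum", "units": "cm", "default": 0.0015, "uncertainty_fraction": 0.25, "varied": true},
    "L_g": {"description": "Thickness of supradermal gas compartment", "units": "cm", "default": 0.5, "uncertainty_fraction": 0.30, "varied": true},
    "A_c": {"description": "Capillary exchange surface area", "units": "cm^2", "default": 0.075, "uncertainty_fraction": 0.50, "varied": true},
    "Q_dot": {"description": "Capillary blood flow", "units": "mL/s", "default": 0.0004, "uncertainty_fraction": 0.30, "varied": true},
    "V_dot": {"description": "Convective gas (ventilation) flow above the skin", "units": "mL/s", "default": 5e-05, "uncertainty_fraction": 0.50, "varied": true},
    "beta_g": {"description": "Solubility of ethanol in the gas phase", "units": "mL ethanol/(100 mL gas)/Torr", "default": 0.132, "varied": false},
    "L_c": {"description": "Capillary compartment thickness (one blood-cell diameter)", "units": "cm", "default": 0.0007, "varied": false},
    "A": {"description": "Skin patch / gas compartment surface area", "units": "cm^2", "default": 1.0, "varied": false},
    "T": {"description": "Body temperature", "units": "K", "default": 310.15, "varied": false},
    "M_etoh": {"description": "Ethanol molar mass", "units": "g/mol", "default": 46.07, "varied": false},
    "R_gas": {"description": "Universal gas constant", "units": "Torr cm^3/(mol K)", "default": 62360.0, "varied": false}
  },
  "notes": "The eleven parameters with 'varied': true carry independent uniform (rectangular) uncertainty distributions of the given half-width fraction about the default. The remaining entries are fixed constants."
}
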