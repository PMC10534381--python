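{
  "version": 1,
  "description": "Physical and electrical properties of the separated cell species: circulating tumor cells (CTC), white blood cells (WBC) and platelets (PLT). Single-shell model parameters: cytoplasm sphere covered by a thin membrane.",
  "species": {
    "CTC": {
      "diameter_um": 15.0,
      "membrane_thickness_nm": 7.0,
      "cytoplasm_conductivity_S_per_m": 1.0,
      "membrane_conductivity_S_per_m": 9e-07,
      "cytoplasm_relative_permittivity": 50.0,
      "membrane_relative_permittivity": 12.5
    },
    "WBC": {
      "diameter_um": 12.0,
      "membrane_thickness_nm": 7.0,
      "cytoplasm_conductivity_S_per_m": 0.18,
      "membrane_conductivity_S_per_m": 9e-06,
      "cytoplasm_relative_permittivity": 80.0,
      "membrane_relative_permittivity": 10.0
    },
    "PLT": {
      "diameter_um": 1.8,
      "membrane_thickness_nm": 8.0,
      "cytoplasm_conductivity_S_per_m": 0.25,
      "membrane_conductivity_S_per_m": 1e-06,
      "cytoplasm_relative_permittivity": 50.0,
      "membrane_relative_permittivity": 6.0
    }
  }
}
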