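# Proposed (optimum) separator configuration: four electrodes at +-2.0 V,
# 40 um channel width, buffer 850 um/s, cell inlet 134 um/s.
geometry:
  channel_width_um: 40.0
  n_electrodes: 4
drive:
  amplitude_V: 2.0
  n_electrodes: 4
  frequency_Hz: 96000.0
flow:
  v_blood_um_per_s: 134.0
  v_buffer_um_per_s: 850.0
medium:
  electrical_conductivity_S_per_m: 0.055
  relative_permittivity: 80.0
population:
  n_per_species: 20
  placement: uniform_grid
  release_margin: 0.1
tracer:
  t_end_s: 8.0
mesh_level: fine
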