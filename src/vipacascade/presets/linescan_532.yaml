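# 532 nm line-scanning spectrometer: 110 um line source, VIPA + one
# high-finesse etalon.  Same matching logic as the confocal preset; swap the
# etalon for two R = 75% stages for the dual low-finesse cascade.
geometry:
  wavelength_nm: 532.0
  f_collimator_mm: 75.0
  f_imaging_mm: 300.0
  pixel_um: 0.15
  pixel_x_um: 2.0
  sensor: [20000, 256]
cavities:
  - {thickness_mm: 3.3700000, index: 1.45, r_front: 1.00, r_back: 0.92, tilt_y_deg: 2.0, tilt_x_deg: 0.0, sigma_nm: 0.0}
  - {thickness_mm: 3.3700025, index: 1.45, r_front: 0.94, r_back: 0.94, tilt_y_deg: 2.0, tilt_x_deg: 0.1, sigma_nm: 0.0}
source:
  kind: line
  line_length_um: 110.0
  spectrum:
    - {offset_ghz: 0.0, amplitude: 1.0}
seed: 0
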