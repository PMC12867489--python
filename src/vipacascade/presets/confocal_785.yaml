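# 785 nm confocal spectrometer: VIPA + one high-finesse etalon.
# Cavity and focal-length values follow the published instrument; the sensor
# grid is an oversampled ideal detector (>= 64 row pixels per fringe FWHM).
# The etalon thickness offset (+2.5 nm) together with its 0.1 deg x-tilt
# keeps the etalon resonances coincident with the VIPA's.
geometry:
  wavelength_nm: 785.0
  f_collimator_mm: 50.0
  f_imaging_mm: 200.0
  pixel_um: 0.15
  pixel_x_um: 1.0
  sensor: [20000, 64]
cavities:
  - {thickness_mm: 3.3700000, index: 1.45, r_front: 1.00, r_back: 0.92, tilt_y_deg: 2.0, tilt_x_deg: 0.0, sigma_nm: 0.0}
  - {thickness_mm: 3.3700025, index: 1.45, r_front: 0.94, r_back: 0.94, tilt_y_deg: 2.0, tilt_x_deg: 0.1, sigma_nm: 0.0}
source:
  kind: point
  gaussian_diameter_um: 5.0
  spectrum:
    - {offset_ghz: 0.0, amplitude: 1.0}
seed: 0
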