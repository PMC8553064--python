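# Full study design at reduced grid size (64x64): four sound conditions
# plus the inanimate phantom, two plant ages, six plants, the standard
# 10 min blank / 20 s record / 1 min exposure schedule, and the
# stomatal time-course generator. Usable directly with:
#   biospeckle run-all --config examples/study.yaml --out results/
study:
  conditions:
  - control
  - 100Hz
  - 1kHz
  - 10kHz
  - phantom
  ages:
  - 14
  - 30
  n_plants: 6
  acquisitions_per_cycle: 5
  cycles: 3
  fps: 15.0
  duration_s: 20.0
  shape:
  - 64
  - 64
  geometry:
    wavelength_nm: 635.0
    distance_mm: 167.0
    beam_width_mm: 2.45
    pixel_pitch_um: 5.2
  camera:
    bit_depth: 8
    readout_noise_e: 25.0
    full_well_scale: 50.0
  rho_map: null
  between_plant_plateau_sd: 0.05
  target_mean_gray: null
schedule:
  blank_s: 600.0
  record_s: 20.0
  fps: 15.0
  exposure_s: 60.0
  acquisitions_per_cycle: 5
  cycles: 3
  conditions:
  - control
  - 100Hz
  - 1kHz
  - 10kHz
stomata:
  major_mean_um: 25.0
  minor_mean_um: 15.0
  between_stoma_cv: 0.08
  effect_fraction: 0.06
  recovery_tau_min: 3.0
  fluctuation_cv: 0.015
  n_seedlings: 3
  leaves_per_seedling: 3
  stomata_per_leaf: 5
  times_min:
  - -10.0
  - 0.0
  - 10.0
  - 20.0
  - 30.0
  conditions:
  - control
  - sound_10kHz
  sound_condition: sound_10kHz
master_seed: 1
include_stomata: true
n_dark_frames: 50
early_window_s: 5.0
control_condition: control
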