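# Phenotype presets for the synthetic spheroid generator.
#
# follower: compact, branchless, slow linear growth.
# leader:   extensive chain-like branching (quadratic elongation) plus
#           detaching single cells.
# parental: intermediate morphology and rates.
#
# Shared imaging conditions: 10-minute frame interval, 5 focal planes with a
# linear illumination ramp (1.0 mid-plane to 0.4 extremes, the generator
# default), mild photobleaching and moderate additive noise relative to the
# 170-unit foreground/background contrast.

follower:
  core_radius_0: 12.0
  core_growth_rate: 2.0
  n_branches: 0
  branch_angles: []
  branch_length_coeffs: [0.0, 0.0]
  branch_width: 4.0
  frame_interval: 10.0
  n_frames: 30
  image_shape: [128, 128]
  n_z: 5
  bleach_rate: 0.02
  noise_sd: 10.0
  fg_level: 200.0
  bg_level: 30.0
  single_cell_events: []
  seed: 0

leader:
  core_radius_0: 10.0
  core_growth_rate: 3.0
  n_branches: 6
  branch_angles: [0.0, 1.0471975511965976, 2.0943951023931953,
                  3.141592653589793, 4.1887902047863905, 5.235987755982988]
  branch_length_coeffs: [0.5, 2.0]
  branch_width: 4.0
  frame_interval: 10.0
  n_frames: 30
  image_shape: [128, 128]
  n_z: 5
  bleach_rate: 0.02
  noise_sd: 10.0
  fg_level: 200.0
  bg_level: 30.0
  single_cell_events:
    - [1.5, 0.5235987755982988, 5.0, 3.0]
    - [2.5, 3.6651914291880923, 5.0, 3.0]
  seed: 0

parental:
  core_radius_0: 11.0
  core_growth_rate: 2.5
  n_branches: 3
  branch_angles: [0.3, 2.4, 4.5]
  branch_length_coeffs: [0.25, 1.5]
  branch_width: 4.0
  frame_interval: 10.0
  n_frames: 30
  image_shape: [128, 128]
  n_z: 5
  bleach_rate: 0.02
  noise_sd: 10.0
  fg_level: 200.0
  bg_level: 30.0
  single_cell_events:
    - [2.0, 5.5, 4.0, 3.0]
  seed: 0
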