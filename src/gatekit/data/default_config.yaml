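# gatekit default configuration.
# Every tunable default of the analysis lives here; user configs are
# deep-merged over this file.

selection:
  # KcsA pore-domain segment preset (inclusive residue ranges); names
  # starting with "loop" are excluded unless include_loops is true
  segments:
    TM1: [29, 51]
    loop_turret: [52, 61]
    P-helix: [62, 74]
    SF: [75, 79]
    loop_sf_tm2: [80, 85]
    TM2: [86, 118]
  backbone_atoms: [N, CA, C, O]
  include_loops: false

prepare:
  first_res: 29
  last_res: 118
  # wild-type correction: relabel this residue in intermediate/open
  # deposited structures (name-only, no side-chain rebuilding)
  relabel: {resseq: 117, new_name: ARG}

toy:
  n_subunits: 4
  beads_per_helix: 6
  double_well_bias: 40.0    # kJ/mol, open-basin penalty (closed deeper)
  temperature: 310.0        # K
  friction: 50.0            # ps^-1

ed:
  n_steps: 3000
  drive_fraction: 0.6667    # target reached after two thirds of the run
  success_rmsd_opening: 0.2   # nm
  success_rmsd_closing: 0.23  # nm
  replicas: 3
  dt: 0.002                 # ps
  # reference atomistic increments (nm per 2 fs step) for 4/1/2/3
  # driven subunits; toy runs rescale automatically to the pacing rule
  reference_increments:
    4: 1.28e-6
    1: 1.89e-7
    2: 6.27e-7
    3: 9.24e-7

umbrella:
  n_windows: 39
  default_k: 1.0            # kJ mol^-1 nm^-2 (reference protocol)
  boosted_k: 100.0          # kJ mol^-1 nm^-2 for barrier windows
  boosted_set: []
  # desk-scale presets: the analytic-landscape oracle uses a stiffer
  # uniform k for histogram overlap at 39 windows; the toy channel
  # needs a much stiffer bias against its collective barrier
  landscape_k: 30.0
  toy_k: 1200.0
  n_samples: 20000
  discard_first_fraction: 0.5
  n_bins: 200
  tolerance: 1.0e-7         # kJ/mol on the window constants
  n_bootstrap: 50

pore:
  z_step: 0.025             # nm
  n_anneal: 250
  lateral_bound: 2.0        # nm
  radii:                    # element hard-sphere radii, nm
    C: 0.185
    N: 0.175
    O: 0.165
    S: 0.200

rotamer:
  up_range: [-72.0, -55.0]      # degrees
  down_range: [-185.0, -166.0]  # degrees (wraps across -180)
  mode: strict

hbond:
  d_cut: 0.35               # nm donor-acceptor
  angle_cut: 30.0           # degrees H-D-A

dihedral_trace:
  p_up_to_down: 0.002
  p_down_to_up: 0.002
  noise_sd: 8.0             # degrees
  n_steps: 10000
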