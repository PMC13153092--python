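# Study configuration (lengths in millimetres).
# Omitted blocks fall back to the built-in clinical presets.

timepoints: [preop, week1, month6]

geometry:
  max_cell_size: 0.65            # grid-independent size of the study protocol
  boundary_layer:
    first_layer_height: 0.065
    growth_rate: 1.2
    n_layers: 5
  n_samples: 200
  # per-spec overrides (mm); branch lengths are placeholders, not measurements
  # overrides:
  #   stenosis_length: 10

fluid:
  density: 1060
  model: carreau_yasuda          # or: newtonian (then set mu)
  mu0: 0.056
  mu_inf: 0.00345
  lambda: 3.313
  a: 2.0
  n: 0.3568

outlets:                         # three-element Windkessel per branch terminal
  RAPV: {Rc: 2.7175e8, Rd: 1.9017e9, C: 9.4916e-9, Pd: 0}
  RPPV: {Rc: 2.4875e8, Rd: 1.8697e9, C: 9.4916e-9, Pd: 0}

solver:
  dt: 0.005
  max_steps: 1000
  residual_tol: 1.0e-5
  monitor_window: 100
  monitor_tol: 1.0e-3
  wk3_coupling: steady           # or: transient (backward-Euler RCR ODE)

grid_study:
  sizes: [0.85, 0.75, 0.65, 0.60]

network:
  expansion_coefficient: 1.0     # Borda-Carnot Kt
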