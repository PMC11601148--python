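# End-to-end demo: the four study sequences through every stage.
# Run with:  peptide-nanoform run --config examples/demo_run.yaml --out run/
peptides:
  F8: FEFKFEFK
  FP: FEFKPEFK
  KPE: FEFKPEFKF
  EPK: FEFEPKFKF
seed: 17

charge:
  ph_min: 0.0
  ph_max: 14.0
  ph_step: 0.05

titration:
  conc_mg_ml: 1.0
  titrant_molarity: 0.025
  n_injections: 60
  max_ratio: 6.0
  initial_ph: 2.6
  pka_shifts: {}
  fit_class: E

saxs:
  # flat-ribbon cross-section geometry at 5 mg/mL
  r_minor: 4.761
  axis_ratio: 2.783
  length: 733.71
  noise: multiplicative
  noise_level: 0.01
  fit_q_range: [0.1, 7.0]
  fixed: [length, scale]
  init_perturbation: 1.3
  power_law_window: [0.086, 0.15]
  guinier_window: [0.086, 0.13]

waxs:
  prominence: 0.05
  tolerance: 0.05
  noise_sigma: 0.002
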