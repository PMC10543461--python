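sim:
  n_patients: 800
  seed: 9
  baseline_hazard: 0.2
  planted_effects: {RX_RISK: 4.0}
  carrier_probs: {RX_RISK: 0.5}
  encounters_per_patient: [6.0, 1.0]
  followup_days: 90
  events_per_encounter: 3.0
  n_zip_codes: 15
  planted_emission_prob: 1.0
  planted_initial_emission: true
  planted_encounter_prob: 0.2
cohort:
  split_ratios: [8, 1, 1]
model:
  architecture: tlstm
  embedding_dim: 24
  hidden_size: 24
  num_layers: 2
  max_epochs: 12
  batch_size: 64
encoding:
  min_patient_count: 5
  max_visits: 12
contribution:
  samples: all
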