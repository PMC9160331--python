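# Intragastric-infusion test with taste as a predictor of internal change.
# Three sodium-depleted groups over 100 trials (600 s in the modelled assay,
# i.e. 6 s per trial, recorded here as commentary only):
#   control          - depleted start (H0 = 0)
#   ig_infusion      - saltwater pre-loaded into the gut: half-satisfied
#                      start (H0 = H*/2), no taste experienced
#   oral_stimulation - depleted start plus a strong ambient salty taste on
#                      every trial; the ambient taste enters the reward
#                      prediction for every action but never the state.
# Taste predictors start at the true intake (pre-learned taste).
name: sim2_infusion
n_agents: 100
base_seed: 20220521
groups:
  - label: control
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 100
    reward_mode: predicted_taste
    initial_state: [0.0]
    drive:
      setpoint: [50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [30.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0], initial_q: 0.0}
      - {label: intake, intake: [2.5], initial_q: 0.0}
  - label: ig_infusion
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 100
    reward_mode: predicted_taste
    initial_state: [25.0]
    drive:
      setpoint: [50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [30.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0], initial_q: 0.0}
      - {label: intake, intake: [2.5], initial_q: 0.0}
  - label: oral_stimulation
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 100
    reward_mode: predicted_taste
    initial_state: [0.0]
    ambient_stimulus: [40.0]
    drive:
      setpoint: [50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [30.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0], initial_q: 0.0}
      - {label: intake, intake: [2.5], initial_q: 0.0}
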