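# Two-bottle preference test: two internal dimensions (water, sodium) and
# three actions (do nothing, water intake, saltwater intake). Saltwater
# delivers a positive water component as well as sodium, so it partially
# relieves thirst; plain water delivers water only. Four depletion groups:
# depleted dimensions start at 0, fulfilled ones at the setpoint.
# Taste predictors start at the true intake (pre-learned taste).
name: sim3_two_bottle
n_agents: 100
base_seed: 20220522
groups:
  - label: control
    n_dimensions: 2
    dimension_labels: [water, sodium]
    n_trials: 200
    reward_mode: predicted_taste
    initial_state: [50.0, 50.0]
    drive:
      setpoint: [50.0, 50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0, 150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 0.0}
  - label: sodium_depleted
    n_dimensions: 2
    dimension_labels: [water, sodium]
    n_trials: 200
    reward_mode: predicted_taste
    initial_state: [50.0, 0.0]
    drive:
      setpoint: [50.0, 50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0, 150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 0.0}
  - label: water_depleted
    n_dimensions: 2
    dimension_labels: [water, sodium]
    n_trials: 200
    reward_mode: predicted_taste
    initial_state: [0.0, 50.0]
    drive:
      setpoint: [50.0, 50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0, 150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 0.0}
  - label: water_salt_depleted
    n_dimensions: 2
    dimension_labels: [water, sodium]
    n_trials: 200
    reward_mode: predicted_taste
    initial_state: [0.0, 0.0]
    drive:
      setpoint: [50.0, 50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0, 150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 0.0}
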