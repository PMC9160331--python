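# Chemogenetic (DREADD) manipulation of the tonic LPBN suppression of
# sodium appetite, in the two-bottle setting of sim3_two_bottle. The
# saltwater action carries a constant negative selection-time bias (lpbn);
# DREADD groups cancel it with an equal additive term (drd = lpbn). The
# initial saltwater Q equals lpbn so effective values start level and the
# first choice is uniform. Depleted dimension starts at 0.
name: sim4_dreadd
n_agents: 100
base_seed: 20220523
groups:
  - label: water_depleted_control
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
    bias: {lpbn: 4.0, drd: 4.0, dreadd_on: false, biased_action: saltwater_intake}
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 4.0}
  - label: water_depleted_dreadd
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
    bias: {lpbn: 4.0, drd: 4.0, dreadd_on: true, biased_action: saltwater_intake}
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 4.0}
  - label: sodium_depleted_control
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
    bias: {lpbn: 4.0, drd: 4.0, dreadd_on: false, biased_action: saltwater_intake}
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 4.0}
  - label: sodium_depleted_dreadd
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
    bias: {lpbn: 4.0, drd: 4.0, dreadd_on: true, biased_action: saltwater_intake}
    actions:
      - {label: do_nothing, intake: [0.0, 0.0], initial_q: 0.0}
      - {label: water_intake, intake: [2.5, 0.0], initial_q: 0.0}
      - {label: saltwater_intake, intake: [1.0, 2.5], initial_q: 4.0}
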