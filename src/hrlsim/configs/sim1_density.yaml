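# Saltwater-concentration preference: sodium-replete agents (H0 = H*) lick
# either high-density saltwater (large intake per trial) or low-density
# saltwater (small intake per trial). Replete animals prefer the weaker
# solution: every intake overshoots the setpoint, and the stronger solution
# overshoots more, so its action value is punished harder.
name: sim1_density
n_agents: 100
base_seed: 20220520
groups:
  - label: low_density
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 200
    reward_mode: actual_intake
    initial_state: [50.0]
    drive:
      setpoint: [50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0], initial_q: 0.0}
      - {label: intake, intake: [0.5], initial_q: 0.0}
  - label: high_density
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 200
    reward_mode: actual_intake
    initial_state: [50.0]
    drive:
      setpoint: [50.0]
      exponent_n: 4.0
      exponent_m: 3.0
    decay:
      tau: [150.0]
    learning:
      alpha_q: 0.07
      alpha_khat: 0.2
    policy:
      beta: 1.0
    actions:
      - {label: do_nothing, intake: [0.0], initial_q: 0.0}
      - {label: intake, intake: [2.5], initial_q: 0.0}
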