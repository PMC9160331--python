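# Sodium-depleted intake test: one sodium dimension, do-nothing vs intake,
# reward computed from the actual intake. Calibrated so a 100-agent cohort
# reproduces the canonical regulation timeline (intake probability near 1
# by ~trial 20, setpoint overshoot ~trial 80, return below setpoint ~trial 140).
name: sim1_intake
n_agents: 100
base_seed: 20220519
groups:
  - label: default
    n_dimensions: 1
    dimension_labels: [sodium]
    n_trials: 200
    reward_mode: actual_intake
    initial_state: [0.0]
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
      - {label: intake, intake: [1.0], initial_q: 0.0}
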