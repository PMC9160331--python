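import numpy as np
import pytest

from hrlsim import (
    ActionSpec,
    AgentConfiguration,
    BUILTIN_EXPERIMENTS,
    DecayParameters,
    DriveParameters,
    LearningParameters,
    PolicyParameters,
    build_experiment,
    build_sim1_intake,
    run_experiment,
    summarize_cohort,
)


def make_config(**overrides) -> AgentConfiguration:
    """A small valid one-dimensional configuration for unit tests."""
    defaults = dict(
        n_dimensions=1,
        actions=(
            ActionSpec("do_nothing", intake=[0.0]),
            ActionSpec("intake", intake=[1.0]),
        ),
        drive=DriveParameters(setpoint=[50.0]),
        decay=DecayParameters(tau=[150.0]),
        learning=LearningParameters(alpha_q=0.07, alpha_khat=0.2),
        policy=PolicyParameters(beta=1.0),
        initial_state=[0.0],
        n_trials=50,
        seed=7,
    )
    defaults.update(overrides)
    return AgentConfiguration(**defaults)


@pytest.fixture(scope="session")
def sim1_cohort():
    """The shipped Simulation 1 configuration run as a 100-agent cohort."""
    defn = build_sim1_intake()
    return run_experiment(defn, n_agents=100)["default"]


@pytest.fixture(scope="session")
def cohort_counts():
    """Median per-action total counts for every built-in experiment,
    100 agents per group at the shipped base seeds."""
    out = {}
    for name in BUILTIN_EXPERIMENTS:
        if name == "sim1_intake":
            continue
        defn = build_experiment(name)
        res = run_experiment(defn, n_agents=100)
        out[name] = {
            label: summarize_cohort(trajs, label).total_counts()
            for label, trajs in res.items()
        }
    return out
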