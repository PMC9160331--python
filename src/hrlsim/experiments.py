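"""The four built-in simulation experiments, cohort summaries and
landmark-timing statistics.

Experiments
-----------
``sim1_intake``
    Sodium homeostasis: one internal dimension (sodium), actions
    do-nothing / intake, sodium-depleted start, reward from actual
    intake.  The canonical homeostatic-regulation demonstration.
``sim1_density``
    Concentration preference: sodium-replete agents offered high- vs
    low-density saltwater (larger vs smaller intake per trial).
``sim2_infusion``
    Intragastric-infusion test: control, IG-infusion (half-satisfied
    initial sodium state, taste never experienced) and oral-stimulation
    (ambient salty taste on every trial) groups; reward from the taste
    predictor.
``sim3_two_bottle``
    Two-bottle preference test: two internal dimensions (water, sodium),
    actions do-nothing / water / saltwater, four depletion groups.
``sim4_dreadd``
    Chemogenetic manipulation: tonic LPBN suppression of the saltwater
    action with or without DREADD cancellation, in water- and
    sodium-depleted agents.

All parameter values live in the shipped per-experiment YAML files
(``hrlsim/configs``), which are the single source of truth; the
builders simply load them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .agent import AgentConfiguration, Trajectory, derive_seed, run_cohort
from .core import ConfigurationError

__all__ = [
    "ExperimentDefinition",
    "CohortSummary",
    "LandmarkStats",
    "BUILTIN_EXPERIMENTS",
    "build_experiment",
    "build_sim1_intake",
    "build_sim1_density",
    "build_sim2_infusion",
    "build_sim3_two_bottle",
    "build_sim4_dreadd",
    "run_experiment",
    "summarize_cohort",
    "landmark_trials",
]


@dataclass(frozen=True)
class ExperimentDefinition:
    """A named set of agent groups run as same-size cohorts."""

    name: str
    groups: tuple[tuple[str, AgentConfiguration], ...]
    n_agents: int
    base_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple((str(l), c) for l, c in self.groups))
        labels = [l for l, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"group labels must be unique, got {labels}")
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.groups)

    def group(self, label: str) -> AgentConfiguration:
        for l, cfg in self.groups:
            if l == label:
                return cfg
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_agents": self.n_agents,
            "base_seed": self.base_seed,
            "groups": [
                {"label": label, **cfg.to_dict()} for label, cfg in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDefinition":
        try:
            groups = tuple(
                (g["label"], AgentConfiguration.from_dict(g)) for g in d["groups"]
            )
            return cls(
                name=str(d["name"]),
                groups=groups,
                n_agents=int(d["n_agents"]),
                base_seed=int(d["base_seed"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing configuration field: {exc.args[0]!r}") from exc


def _load_builtin(name: str) -> ExperimentDefinition:
    path = resources.files("hrlsim").joinpath(f"configs/{name}.yaml")
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    defn = ExperimentDefinition.from_dict(data)
    if defn.name != name:
        raise ConfigurationError(
            f"shipped config {name}.yaml declares name {defn.name!r}"
        )
    return defn


def build_sim1_intake() -> ExperimentDefinition:
    """Sodium-depleted intake test (one group, reward from actual intake)."""
    return _load_builtin("sim1_intake")


def build_sim1_density() -> ExperimentDefinition:
    """Saltwater-concentration preference in replete agents (two groups)."""
    return _load_builtin("sim1_density")


def build_sim2_infusion() -> ExperimentDefinition:
    """Intragastric-infusion test (control / IG-infusion / oral-stimulation)."""
    return _load_builtin("sim2_infusion")


def build_sim3_two_bottle() -> ExperimentDefinition:
    """Two-bottle preference test with water and sodium states (four groups)."""
    return _load_builtin("sim3_two_bottle")


def build_sim4_dreadd() -> ExperimentDefinition:
    """LPBN suppression with and without DREADD cancellation (four groups)."""
    return _load_builtin("sim4_dreadd")


BUILTIN_EXPERIMENTS = {
    "sim1_intake": build_sim1_intake,
    "sim1_density": build_sim1_density,
    "sim2_infusion": build_sim2_infusion,
    "sim3_two_bottle": build_sim3_two_bottle,
    "sim4_dreadd": build_sim4_dreadd,
}


def build_experiment(name: str) -> ExperimentDefinition:
    """Build a built-in experiment by name."""
    try:
        builder = BUILTIN_EXPERIMENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown experiment {name!r}; valid names: {sorted(BUILTIN_EXPERIMENTS)}"
        ) from None
    return builder()


def run_experiment(
    defn: ExperimentDefinition,
    n_agents: int | None = None,
    base_seed: int | None = None,
) -> dict[str, list[Trajectory]]:
    """Run every group of an experiment as an ``n_agents`` cohort.

    Group ``g`` draws its cohort base seed from ``(base_seed, g)``, and
    each agent within a cohort from ``(cohort seed, agent index)``, so
    all streams are disjoint and the whole run is reproducible from
    ``base_seed`` alone.
    """
    n = defn.n_agents if n_agents is None else int(n_agents)
    seed = defn.base_seed if base_seed is None else int(base_seed)
    results: dict[str, list[Trajectory]] = {}
    for gi, (label, cfg) in enumerate(defn.groups):
        results[label] = run_cohort(cfg, n, base_seed=derive_seed(seed, gi))
    return results


@dataclass
class CohortSummary:
    """Across-agent per-trial mean/SD of the plotted variables, plus
    per-agent total action counts.

    ``mean`` and ``sd`` are trial-indexed frames with one column per
    internal dimension (``H_<dim>``), per action value (``Q_<action>``),
    per choice probability (``P_<action>``) and the reward.  The SD uses
    the cohort as the full population (divisor ``n``), matching the
    mean +/- 2 SD bands plotted for simulated cohorts.
    """

    label: str
    mean: pd.DataFrame
    sd: pd.DataFrame
    action_counts: pd.DataFrame  # index agent_id, one column per action

    def total_counts(self) -> pd.Series:
        """Cohort median of per-agent total counts, one entry per action."""
        return self.action_counts.median(axis=0)


def _trajectory_columns(cfg: AgentConfiguration) -> list[str]:
    cols = [f"H_{d}" for d in cfg.dimension_labels]
    cols += [f"Q_{a}" for a in cfg.action_labels]
    cols += [f"P_{a}" for a in cfg.action_labels]
    cols += ["reward"]
    return cols


def _trajectory_matrix(traj: Trajectory) -> np.ndarray:
    return np.column_stack(
        [traj.states, traj.q_values, traj.probabilities, traj.rewards]
    )


def summarize_cohort(trajectories: list[Trajectory], label: str = "") -> CohortSummary:
    """Reduce a cohort to per-trial mean/SD curves and per-agent counts."""
    if not trajectories:
        raise ValueError("cannot summarize an empty cohort")
    n_trials = len(trajectories[0])
    if any(len(t) != n_trials for t in trajectories):
        raise ValueError("all trajectories in a cohort must have equal length")
    cfg = trajectories[0].config
    cols = _trajectory_columns(cfg)
    cube = np.stack([_trajectory_matrix(t) for t in trajectories])  # (agent, trial, var)
    index = pd.RangeIndex(n_trials, name="trial")
    mean = pd.DataFrame(cube.mean(axis=0), index=index, columns=cols)
    sd = pd.DataFrame(cube.std(axis=0, ddof=0), index=index, columns=cols)
    counts = pd.DataFrame(
        [t.action_counts() for t in trajectories],
        index=pd.Index([t.agent_id for t in trajectories], name="agent_id"),
    )
    return CohortSummary(label=label, mean=mean, sd=sd, action_counts=counts)


@dataclass
class LandmarkStats:
    """First-crossing trial indices per agent (NaN where never crossed)
    and their cohort medians over the agents where defined.

    Landmarks, in the order they occur in a regulation episode:

    * ``probability_crossing`` — first trial whose pre-draw intake
      probability exceeds the threshold;
    * ``setpoint_crossing`` — first trial whose internal state (watched
      dimension) strictly exceeds the setpoint;
    * ``setpoint_return`` — first trial strictly after the overshoot at
      which the state falls back strictly below the setpoint.
    """

    probability_threshold: float
    probability_crossing: np.ndarray
    setpoint_crossing: np.ndarray
    setpoint_return: np.ndarray

    @staticmethod
    def _median(values: np.ndarray) -> float:
        defined = values[~np.isnan(values)]
        return float(np.median(defined)) if defined.size else float("nan")

    @property
    def median_probability_crossing(self) -> float:
        return self._median(self.probability_crossing)

    @property
    def median_setpoint_crossing(self) -> float:
        return self._median(self.setpoint_crossing)

    @property
    def median_setpoint_return(self) -> float:
        return self._median(self.setpoint_return)


def _first_index(mask: np.ndarray, start: int = 0) -> float:
    hits = np.nonzero(mask[start:])[0]
    return float(start + hits[0]) if hits.size else float("nan")


def landmark_trials(
    trajectories: list[Trajectory],
    probability_threshold: float,
    intake_action: str = "intake",
    dimension: int = 0,
) -> LandmarkStats:
    """Per-agent landmark timings for a regulation episode.

    ``intake_action`` names the action whose choice probability is
    watched; ``dimension`` selects the internal-state component compared
    with its setpoint.
    """
    if not (0.0 < probability_threshold < 1.0):
        raise ValueError("probability_threshold must be in (0, 1)")
    if not trajectories:
        raise ValueError("need at least one trajectory")
    p_cross, s_cross, s_return = [], [], []
    for traj in trajectories:
        cfg = traj.config
        ai = cfg.action_labels.index(intake_action)
        setpoint = cfg.drive.setpoint[dimension]
        probs = traj.probabilities[:, ai]
        states = traj.states[:, dimension]
        p_cross.append(_first_index(probs > probability_threshold))
        crossing = _first_index(states > setpoint)
        s_cross.append(crossing)
        if np.isnan(crossing):
            s_return.append(float("nan"))
        else:
            s_return.append(_first_index(states < setpoint, start=int(crossing) + 1))
    return LandmarkStats(
        probability_threshold=probability_threshold,
        probability_crossing=np.array(p_cross),
        setpoint_crossing=np.array(s_cross),
        setpoint_return=np.array(s_return),
    )
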