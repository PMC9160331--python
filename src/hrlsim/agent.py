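"""Trial loop: binding homeostatic dynamics and value learning into an agent.

Each trial executes, in order:

1. selection-time values (tonic bias applied if configured),
2. softmax choice probabilities,
3. action draw,
4. reward-input vector — the taken action's true intake ``K`` in
   ``actual_intake`` mode, or its taste predictor ``K_hat`` (plus any
   ambient oral stimulus) in ``predicted_taste`` mode,
5. drive-reduction reward,
6. Rescorla-Wagner update of the taken action's value,
7. delta-rule update of the taken action's taste predictor,
8. state transition with the taken action's *true* intake only (an
   ambient oral stimulus enters the reward prediction, never the state).

Episodes and cohorts are fully seed-controlled: per-agent seeds derive
deterministically from ``(base_seed, agent_index)`` through numpy's
``SeedSequence`` so streams are disjoint and platform-stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ConfigurationError,
    DecayParameters,
    DriveParameters,
    as_state,
    drive,
    next_state,
    reward,
)
from .learning import (
    ActionValueTable,
    BiasParameters,
    LearningParameters,
    PolicyParameters,
    action_probabilities,
    effective_values,
    sample_action,
    update_action_value,
    update_taste_predictor,
)

__all__ = [
    "ActionSpec",
    "AgentConfiguration",
    "TrialRecord",
    "Trajectory",
    "Agent",
    "run_agent",
    "run_cohort",
    "derive_seed",
    "config_digest",
]

REWARD_MODES = ("actual_intake", "predicted_taste")


@dataclass(frozen=True)
class ActionSpec:
    """One available action.

    Parameters
    ----------
    label : str
        Action identifier (e.g. ``do_nothing``, ``intake``).
    intake : array-like
        True per-trial nutrient delivery ``K`` (componentwise >= 0).
    taste_predictor : array-like, optional
        Initial taste predictor ``K_hat_0``.  ``None`` means the taste is
        pre-learned: the predictor starts at the true intake.
    initial_q : float
        Initial action value ``Q_0(a)``.
    """

    label: str
    intake: np.ndarray
    taste_predictor: np.ndarray | None = None
    initial_q: float = 0.0

    def __post_init__(self) -> None:
        k = as_state(self.intake)
        if np.any(k < 0):
            raise ConfigurationError(f"action {self.label!r}: intake must be >= 0, got {k!r}")
        object.__setattr__(self, "intake", k)
        if self.taste_predictor is not None:
            object.__setattr__(
                self, "taste_predictor", as_state(self.taste_predictor, k.size)
            )
        if not np.isfinite(self.initial_q):
            raise ConfigurationError(f"action {self.label!r}: initial_q must be finite")

    @property
    def initial_predictor(self) -> np.ndarray:
        if self.taste_predictor is None:
            return self.intake.copy()
        return self.taste_predictor.copy()


@dataclass(frozen=True)
class AgentConfiguration:
    """Complete, validated description of one simulated agent."""

    n_dimensions: int
    actions: tuple[ActionSpec, ...]
    drive: DriveParameters
    decay: DecayParameters
    learning: LearningParameters
    policy: PolicyParameters
    initial_state: np.ndarray
    n_trials: int
    seed: int = 0
    reward_mode: str = "actual_intake"
    bias: BiasParameters | None = None
    ambient_stimulus: np.ndarray | None = None
    dimension_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = self.n_dimensions
        if n < 1:
            raise ConfigurationError("n_dimensions must be >= 1")
        object.__setattr__(self, "actions", tuple(self.actions))
        if len(self.actions) < 1:
            raise ConfigurationError("at least one action is required")
        labels = [a.label for a in self.actions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"action labels must be unique, got {labels}")
        null_actions = [a.label for a in self.actions if not np.any(a.intake)]
        if len(null_actions) != 1:
            raise ConfigurationError(
                "exactly one action must have all-zero true intake (do-nothing), "
                f"found {null_actions or 'none'}"
            )
        for a in self.actions:
            if a.intake.size != n:
                raise ConfigurationError(
                    f"action {a.label!r}: intake has {a.intake.size} dimensions, expected {n}"
                )
        if self.drive.n_dimensions != n:
            raise ConfigurationError("drive setpoint dimension mismatch")
        if self.decay.tau.size != n:
            raise ConfigurationError("decay tau dimension mismatch")
        object.__setattr__(self, "initial_state", as_state(self.initial_state, n))
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.reward_mode not in REWARD_MODES:
            raise ConfigurationError(
                f"reward_mode must be one of {REWARD_MODES}, got {self.reward_mode!r}"
            )
        if self.ambient_stimulus is not None:
            object.__setattr__(
                self, "ambient_stimulus", as_state(self.ambient_stimulus, n)
            )
            if self.reward_mode != "predicted_taste":
                raise ConfigurationError(
                    "an ambient oral stimulus requires reward_mode='predicted_taste'"
                )
        if self.bias is not None and self.bias.biased_action not in labels:
            raise ConfigurationError(
                f"bias.biased_action {self.bias.biased_action!r} is not an action label"
            )
        if self.dimension_labels is None:
            default = ("sodium",) if n == 1 else tuple(f"dim{i}" for i in range(n))
            object.__setattr__(self, "dimension_labels", default)
        else:
            dl = tuple(self.dimension_labels)
            if len(dl) != n:
                raise ConfigurationError("dimension_labels length mismatch")
            object.__setattr__(self, "dimension_labels", dl)

    @property
    def action_labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.actions)

    def to_dict(self) -> dict:
        """Plain-data representation (round-trips through YAML/JSON)."""
        d: dict = {
            "n_dimensions": self.n_dimensions,
            "dimension_labels": list(self.dimension_labels),
            "n_trials": self.n_trials,
            "seed": int(self.seed),
            "reward_mode": self.reward_mode,
            "initial_state": self.initial_state.tolist(),
            "drive": {
                "setpoint": self.drive.setpoint.tolist(),
                "exponent_n": self.drive.exponent_n,
                "exponent_m": self.drive.exponent_m,
            },
            "decay": {"tau": self.decay.tau.tolist()},
            "learning": {
                "alpha_q": self.learning.alpha_q,
                "alpha_khat": self.learning.alpha_khat,
            },
            "policy": {"beta": self.policy.beta},
            "actions": [
                {
                    "label": a.label,
                    "intake": a.intake.tolist(),
                    "taste_predictor": None
                    if a.taste_predictor is None
                    else a.taste_predictor.tolist(),
                    "initial_q": a.initial_q,
                }
                for a in self.actions
            ],
            "bias": None
            if self.bias is None
            else {
                "lpbn": self.bias.lpbn,
                "drd": self.bias.drd,
                "dreadd_on": self.bias.dreadd_on,
                "biased_action": self.bias.biased_action,
            },
            "ambient_stimulus": None
            if self.ambient_stimulus is None
            else self.ambient_stimulus.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgentConfiguration":
        try:
            actions = tuple(
                ActionSpec(
                    label=a["label"],
                    intake=a["intake"],
                    taste_predictor=a.get("taste_predictor"),
                    initial_q=float(a.get("initial_q", 0.0)),
                )
                for a in d["actions"]
            )
            drv = d["drive"]
            return cls(
                n_dimensions=int(d["n_dimensions"]),
                actions=actions,
                drive=DriveParameters(
                    setpoint=drv["setpoint"],
                    exponent_n=float(drv.get("exponent_n", 4.0)),
                    exponent_m=float(drv.get("exponent_m", 3.0)),
                ),
                decay=DecayParameters(tau=d["decay"]["tau"]),
                learning=LearningParameters(
                    alpha_q=float(d["learning"]["alpha_q"]),
                    alpha_khat=float(d["learning"]["alpha_khat"]),
                ),
                policy=PolicyParameters(beta=float(d["policy"]["beta"])),
                initial_state=d["initial_state"],
                n_trials=int(d["n_trials"]),
                seed=int(d.get("seed", 0)),
                reward_mode=d.get("reward_mode", "actual_intake"),
                bias=None
                if d.get("bias") is None
                else BiasParameters(
                    lpbn=float(d["bias"]["lpbn"]),
                    drd=float(d["bias"].get("drd", 0.0)),
                    dreadd_on=bool(d["bias"].get("dreadd_on", False)),
                    biased_action=d["bias"].get("biased_action", "saltwater_intake"),
                ),
                ambient_stimulus=d.get("ambient_stimulus"),
                dimension_labels=None
                if d.get("dimension_labels") is None
                else tuple(d["dimension_labels"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing configuration field: {exc.args[0]!r}") from exc


def config_digest(config: AgentConfiguration) -> str:
    """Stable hexadecimal digest of the fully resolved configuration."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TrialRecord:
    """Everything observed on one trial (the plotted variables: internal
    state H, action values Q, selected action, choice probabilities
    before the draw, and reward R)."""

    trial: int
    action: str
    reward: float
    state: np.ndarray  # internal state after the transition
    q: np.ndarray  # action values after the update
    probs: np.ndarray  # choice probabilities before the draw


@dataclass
class Trajectory:
    """One agent's episode: consecutive trial records plus provenance."""

    agent_id: int
    config_digest: str
    records: list[TrialRecord]
    config: AgentConfiguration

    def __len__(self) -> int:
        return len(self.records)

    @property
    def states(self) -> np.ndarray:
        """(n_trials, n_dimensions) array of post-transition states."""
        return np.stack([r.state for r in self.records])

    @property
    def q_values(self) -> np.ndarray:
        return np.stack([r.q for r in self.records])

    @property
    def probabilities(self) -> np.ndarray:
        return np.stack([r.probs for r in self.records])

    @property
    def rewards(self) -> np.ndarray:
        return np.array([r.reward for r in self.records])

    @property
    def actions(self) -> list[str]:
        return [r.action for r in self.records]

    def action_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in self.config.action_labels}
        for r in self.records:
            counts[r.action] += 1
        return counts


class Agent:
    """Mutable simulation state for one agent (values, predictors, H)."""

    def __init__(self, config: AgentConfiguration):
        self.config = config
        self.reset()

    def reset(self) -> None:
        cfg = self.config
        self.state = cfg.initial_state.copy()
        self.values = ActionValueTable(
            labels=cfg.action_labels,
            q=np.array([a.initial_q for a in cfg.actions], dtype=float),
        )
        self.predictors = [a.initial_predictor for a in cfg.actions]
        self.trial = 0

    def step(self, rng: np.random.Generator) -> TrialRecord:
        cfg = self.config
        values = effective_values(self.values, cfg.bias)
        probs = action_probabilities(values, cfg.policy)
        a = sample_action(probs, rng)
        chosen = cfg.actions[a]

        if cfg.reward_mode == "actual_intake":
            reward_input = chosen.intake
        else:
            reward_input = self.predictors[a]
            if cfg.ambient_stimulus is not None:
                reward_input = reward_input + cfg.ambient_stimulus
        r = reward(self.state, reward_input, cfg.drive, cfg.decay)

        self.values.q[a] = update_action_value(self.values.q[a], r, cfg.learning.alpha_q)
        self.predictors[a] = update_taste_predictor(
            self.predictors[a], chosen.intake, cfg.learning.alpha_khat
        )
        self.state = next_state(self.state, chosen.intake, cfg.decay)

        record = TrialRecord(
            trial=self.trial,
            action=chosen.label,
            reward=r,
            state=self.state.copy(),
            q=self.values.q.copy(),
            probs=probs,
        )
        self.trial += 1
        return record


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic, platform-stable child seed for ``(base_seed, index)``."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(2, dtype=np.uint32).astype(np.uint64)[0])


def run_agent(config: AgentConfiguration, agent_id: int = 0) -> Trajectory:
    """Run one full episode; deterministic given ``config.seed``."""
    agent = Agent(config)
    rng = np.random.default_rng(config.seed)
    records = [agent.step(rng) for _ in range(config.n_trials)]
    return Trajectory(
        agent_id=agent_id,
        config_digest=config_digest(config),
        records=records,
        config=config,
    )


def run_cohort(
    config: AgentConfiguration, n_agents: int, base_seed: int
) -> list[Trajectory]:
    """Run ``n_agents`` independent episodes.

    Agent ``i`` uses the seed derived from ``(base_seed, i)``; the
    trajectories are independent across agents and reproducible.
    """
    if n_agents < 1:
        raise ConfigurationError("n_agents must be >= 1")
    out = []
    for i in range(n_agents):
        cfg_i = replace(config, seed=derive_seed(base_seed, i))
        out.append(run_agent(cfg_i, agent_id=i))
    return out
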