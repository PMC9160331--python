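"""Value learning and stochastic action selection.

Action values follow a one-step Rescorla-Wagner rule driven by the
reward prediction error, choices follow a softmax policy with inverse
temperature ``beta``, and taste predictors (the expected internal-state
change signalled by an action's taste) follow the same delta rule
toward the action's true intake.

A tonic selection-time bias models suppression of sodium appetite by
LPBN (lateral parabrachial nucleus) neurons: a constant is subtracted
from the biased action's value *only when choosing*; stored values are
never touched.  Chemogenetic (DREADD) silencing of those neurons is the
cancellation of that bias by an additive term of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError

__all__ = [
    "ActionValueTable",
    "PolicyParameters",
    "LearningParameters",
    "BiasParameters",
    "effective_values",
    "action_probabilities",
    "sample_action",
    "update_action_value",
    "update_taste_predictor",
]

_PROB_TOL = 1e-9


@dataclass
class ActionValueTable:
    """Ordered action labels with their current values ``Q(a)``."""

    labels: tuple[str, ...]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or self.q.size != len(self.labels):
            raise ConfigurationError(
                f"need one value per action: {len(self.labels)} labels, q shape {self.q.shape}"
            )
        if not np.all(np.isfinite(self.q)):
            raise ConfigurationError("action values must be finite")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"unknown action {label!r}; known actions: {list(self.labels)}"
            ) from None


@dataclass(frozen=True)
class PolicyParameters:
    """Softmax inverse temperature ``beta >= 0`` (0 gives uniform choice)."""

    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.beta >= 0 and np.isfinite(self.beta)):
            raise ConfigurationError(f"beta must be a finite value >= 0, got {self.beta}")


@dataclass(frozen=True)
class LearningParameters:
    """Learning rates for action values (``alpha_q``) and taste predictors
    (``alpha_khat``); each in (0, 1].  ``alpha_khat = 0`` is additionally
    allowed to freeze pre-learned taste expectations."""

    alpha_q: float
    alpha_khat: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_q <= 1.0):
            raise ConfigurationError(f"alpha_q must be in (0, 1], got {self.alpha_q}")
        if not (0.0 <= self.alpha_khat <= 1.0):
            raise ConfigurationError(f"alpha_khat must be in [0, 1], got {self.alpha_khat}")


@dataclass(frozen=True)
class BiasParameters:
    """Tonic negative selection bias on one action, with optional DREADD
    cancellation.

    At selection time the biased action's value becomes
    ``Q' = Q - lpbn`` (control) or ``Q' = Q - lpbn + drd`` (DREADD on).
    ``Q'`` is ephemeral: learning always updates the stored ``Q``.
    """

    lpbn: float
    drd: float = 0.0
    dreadd_on: bool = False
    biased_action: str = "saltwater_intake"

    def __post_init__(self) -> None:
        if not (self.lpbn >= 0 and np.isfinite(self.lpbn)):
            raise ConfigurationError(f"lpbn must be >= 0, got {self.lpbn}")
        if not (self.drd >= 0 and np.isfinite(self.drd)):
            raise ConfigurationError(f"drd must be >= 0, got {self.drd}")


def effective_values(table: ActionValueTable, bias: BiasParameters | None) -> np.ndarray:
    """Selection-time values ``Q'``: the stored values with the tonic bias
    (and its DREADD cancellation, if active) applied to the biased action.

    Returns a fresh array; the stored table is never modified.
    """
    values = table.q.copy()
    if bias is not None:
        i = table.index(bias.biased_action)
        # net offset computed first so an exact DREADD cancellation
        # (drd == lpbn) leaves the value bit-identical to the unbiased one
        delta = -bias.lpbn + (bias.drd if bias.dreadd_on else 0.0)
        values[i] += delta
    return values


def action_probabilities(values, policy: PolicyParameters) -> np.ndarray:
    """Softmax choice probabilities ``P(a) ∝ exp(beta * Q'(a))``.

    Computed with max-subtraction for numerical stability, which leaves
    the result unchanged (softmax is invariant under adding a constant
    to all values).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError(f"need a non-empty 1-D value vector, got shape {v.shape}")
    z = policy.beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def sample_action(probs, rng: np.random.Generator) -> int:
    """Draw an action index from a probability vector.

    Uses a single uniform draw against the cumulative distribution so the
    consumed random stream is one number per trial.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < 0):
        raise ValueError("probs must be a non-empty vector of non-negative values")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    u = rng.random()
    return int(min(np.searchsorted(np.cumsum(p), u, side="right"), p.size - 1))


def update_action_value(q: float, reward: float, alpha_q: float) -> float:
    """Rescorla-Wagner update ``Q <- Q + alpha_q * (r - Q)``.

    Only the chosen action's value is updated each trial; the fixed point
    is ``Q = r``.
    """
    return q + alpha_q * (reward - q)


def update_taste_predictor(k_hat, k_actual, alpha_khat: float) -> np.ndarray:
    """Delta-rule update of a taste predictor toward the true intake:
    ``K_hat <- K_hat + alpha_khat * (K - K_hat)`` componentwise."""
    kh = np.asarray(k_hat, dtype=float)
    ka = np.asarray(k_actual, dtype=float)
    if kh.shape != ka.shape:
        raise ValueError(f"predictor/intake shape mismatch: {kh.shape} vs {ka.shape}")
    return kh + alpha_khat * (ka - kh)
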