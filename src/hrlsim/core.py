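"""Homeostatic space primitives.

The agent lives in a metric "homeostatic space" whose axes are internal
physiological variables (water balance, sodium level, ...).  The drive
function measures the deviation of the current internal state ``H`` from
the setpoint ``H*``::

    D(H) = ( sum_i |H*_i - H_i|**n ) ** (1/m)

and reward is defined as drive *reduction* across one state transition:
a move toward the setpoint is rewarding, a move away is punishing.
Between trials each internal dimension loses a fixed fraction ``1/tau_i``
of its level (geometric decay), modelling the natural loss of the
nutrient; intake adds a fixed vector ``K`` on top of the decayed state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "DriveParameters",
    "DecayParameters",
    "as_state",
    "drive",
    "decay_state",
    "next_state",
    "reward",
]


class ConfigurationError(ValueError):
    """A parameter value violates a model invariant."""


def as_state(values, n_dimensions: int | None = None) -> np.ndarray:
    """Coerce ``values`` to a 1-D float array and validate it.

    Internal states must be finite; they may exceed the setpoint and are
    never clipped (with ``tau >= 1`` and ``K >= 0`` a state that starts
    non-negative stays non-negative, so clamping would only hide bugs).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ConfigurationError(f"internal state must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"internal state must be finite, got {arr!r}")
    if n_dimensions is not None and arr.size != n_dimensions:
        raise ConfigurationError(
            f"internal state has {arr.size} dimensions, expected {n_dimensions}"
        )
    return arr


@dataclass(frozen=True)
class DriveParameters:
    """Setpoint and distance exponents of the drive function.

    Parameters
    ----------
    setpoint : array-like
        Ideal internal state ``H*``, one entry per dimension.
    exponent_n : float
        Inner exponent applied to each per-dimension deviation.
    exponent_m : float
        Root applied to the summed deviations; the drive is the
        ``1/exponent_m`` power of the sum.

    Defaults ``n=4, m=3`` follow the original homeostatic
    reinforcement-learning formulation of the drive distance.
    """

    setpoint: np.ndarray
    exponent_n: float = 4.0
    exponent_m: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "setpoint", as_state(self.setpoint))
        if not (self.exponent_n > 0 and np.isfinite(self.exponent_n)):
            raise ConfigurationError(f"exponent_n must be > 0, got {self.exponent_n}")
        if not (self.exponent_m > 0 and np.isfinite(self.exponent_m)):
            raise ConfigurationError(f"exponent_m must be > 0, got {self.exponent_m}")

    @property
    def n_dimensions(self) -> int:
        return self.setpoint.size


@dataclass(frozen=True)
class DecayParameters:
    """Per-dimension temporal decay constants ``tau`` (units: trials).

    Each trial the state is multiplied by ``1 - 1/tau_i``; ``tau = 1``
    means total loss in one step.  ``tau < 1`` would flip the sign of the
    state every trial and is rejected.
    """

    tau: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.tau, dtype=float)
        if arr.ndim == 0:
            arr = arr.reshape(1)
        object.__setattr__(self, "tau", arr)
        if arr.ndim != 1 or not np.all(np.isfinite(arr)) or np.any(arr < 1.0):
            raise ConfigurationError(f"every tau must be a finite value >= 1, got {self.tau!r}")

    @property
    def retention(self) -> np.ndarray:
        """The per-trial multiplier ``1 - 1/tau``."""
        return 1.0 - 1.0 / self.tau


def _check_dims(state: np.ndarray, expected: int, what: str) -> np.ndarray:
    if state.size != expected:
        raise ConfigurationError(f"{what}: dimension mismatch ({state.size} != {expected})")
    return state


def drive(state, params: DriveParameters) -> float:
    """Drive ``D(H)``: distance of ``state`` from the setpoint.

    Zero exactly at the setpoint, strictly positive elsewhere, and
    symmetric in the sign of each deviation.
    """
    h = as_state(state)
    _check_dims(h, params.n_dimensions, "drive")
    dev = np.abs(params.setpoint - h)
    return float(np.sum(dev**params.exponent_n) ** (1.0 / params.exponent_m))


def decay_state(state, decay: DecayParameters) -> np.ndarray:
    """Apply one trial of natural loss: ``H <- (1 - 1/tau) * H``."""
    h = as_state(state)
    _check_dims(h, decay.tau.size, "decay_state")
    return h * decay.retention


def next_state(state, intake, decay: DecayParameters) -> np.ndarray:
    """One-trial state transition: decay first, then add intake ``K``.

    Decay applies on every trial regardless of the action; the
    do-nothing action simply has ``K = 0``.
    """
    h = decay_state(state, decay)
    k = as_state(intake, h.size)
    return h + k


def reward(state, intake_for_reward, drive_p: DriveParameters, decay: DecayParameters) -> float:
    """Drive-reduction reward ``r = D(H_t) - D((1 - 1/tau) H_t + K)``.

    ``intake_for_reward`` is the vector entering the *reward* computation:
    the action's true intake ``K`` when reward tracks actual nutrient
    delivery, or the learned taste predictor ``K_hat`` (possibly plus an
    ambient oral stimulus) when taste is treated as a predictor of the
    internal-state change.  Only the caller's choice of vector differs;
    the arithmetic is identical.
    """
    return drive(state, drive_p) - drive(next_state(state, intake_for_reward, decay), drive_p)
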