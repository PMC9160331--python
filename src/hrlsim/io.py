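"""Configuration files, result tables and run manifests.

Experiment configurations are YAML files (see ``hrlsim/configs`` for the
shipped ones); every model parameter is explicit in the file — there are
no hidden run-time defaults.  Trajectories and cohort summaries are
written as RFC-4180-style CSV (header row, UTF-8, shortest round-trip
float formatting), manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .agent import Trajectory
from .core import ConfigurationError
from .experiments import CohortSummary, ExperimentDefinition

__all__ = [
    "ConfigValidationError",
    "RunManifest",
    "load_config",
    "save_config",
    "definition_digest",
    "trajectories_to_frame",
    "write_trajectories",
    "read_trajectories",
    "write_summaries",
    "write_manifest",
    "read_manifest",
]

log = logging.getLogger("hrlsim")


class ConfigValidationError(ValueError):
    """A configuration file failed schema or invariant validation."""


def load_config(path: str | Path) -> ExperimentDefinition:
    """Load and validate an experiment configuration file.

    Raises ``FileNotFoundError`` for a missing file and
    ``ConfigValidationError`` (naming the offending field where known)
    for anything that parses but violates the schema.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigValidationError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigValidationError(f"{path}: top level must be a mapping")
    try:
        return ExperimentDefinition.from_dict(data)
    except (ConfigurationError, TypeError, ValueError) as exc:
        raise ConfigValidationError(f"{path}: {exc}") from exc


def save_config(defn: ExperimentDefinition, path: str | Path) -> None:
    """Serialize an experiment definition back to YAML (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(defn.to_dict(), fh, sort_keys=False)


def definition_digest(defn: ExperimentDefinition) -> str:
    """Stable digest of a fully resolved experiment definition."""
    canonical = json.dumps(defn.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def trajectories_to_frame(
    trajectories: list[Trajectory], group: str | None = None
) -> pd.DataFrame:
    """Long-format table: one row per (agent, trial)."""
    if not trajectories:
        raise ValueError("cannot serialize an empty trajectory list")
    frames = []
    for traj in trajectories:
        cfg = traj.config
        d: dict = {}
        if group is not None:
            d["group"] = group
        d["agent_id"] = traj.agent_id
        d["trial"] = [r.trial for r in traj.records]
        d["action"] = traj.actions
        d["reward"] = traj.rewards
        states = traj.states
        for j, dim in enumerate(cfg.dimension_labels):
            d[f"H_{dim}"] = states[:, j]
        qs = traj.q_values
        ps = traj.probabilities
        for j, a in enumerate(cfg.action_labels):
            d[f"Q_{a}"] = qs[:, j]
        for j, a in enumerate(cfg.action_labels):
            d[f"P_{a}"] = ps[:, j]
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def write_trajectories(
    trajectories: list[Trajectory] | dict[str, list[Trajectory]],
    path: str | Path,
) -> None:
    """Write trajectories to CSV at full float precision.

    Accepts either a single cohort (list) or a whole experiment's
    ``{group label: cohort}`` mapping, in which case a ``group`` column
    is prepended.  Refuses to write an empty file.
    """
    if isinstance(trajectories, dict):
        if not trajectories:
            raise ValueError("cannot serialize an empty trajectory mapping")
        frame = pd.concat(
            [trajectories_to_frame(trajs, group=label) for label, trajs in trajectories.items()],
            ignore_index=True,
        )
    else:
        frame = trajectories_to_frame(trajectories)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back into a long-format frame.

    Uses the round-trip float parser so values survive write/read
    bit-for-bit.
    """
    return pd.read_csv(path, float_precision="round_trip")


def write_summaries(summaries: list[CohortSummary], path: str | Path) -> None:
    """Write cohort summaries as one long CSV (group, trial, variable rows)."""
    if not summaries:
        raise ValueError("cannot serialize an empty summary list")
    frames = []
    for s in summaries:
        mean = s.mean.add_prefix("mean_")
        sd = s.sd.add_prefix("sd_")
        f = pd.concat([mean, sd], axis=1).reset_index()
        f.insert(0, "group", s.label)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to reproduce a run exactly."""

    experiment: str
    config_digest: str
    base_seed: int
    n_agents: int
    tool_version: str
    created: str  # ISO-8601 UTC timestamp

    @classmethod
    def for_run(
        cls, defn: ExperimentDefinition, n_agents: int, base_seed: int, version: str
    ) -> "RunManifest":
        return cls(
            experiment=defn.name,
            config_digest=definition_digest(defn),
            base_seed=int(base_seed),
            n_agents=int(n_agents),
            tool_version=version,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text(encoding="utf-8")))
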