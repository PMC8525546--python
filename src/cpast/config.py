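"""Run configuration: defaults, YAML loading, validation, hashing.

One structured config drives every command; CLI flags override file values and
the fully resolved config (defaults included) is written alongside the outputs
together with its hash, so any run can be reproduced from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .inference import EFEWeights

__all__ = ["RunConfig", "load_config", "DEFAULT_SEEDS"]

#: Number of seeds per complexity level in sweep/reproduce runs.
DEFAULT_SEEDS = 20


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter set for foraging and categorisation runs."""

    grid_rows: int = 30
    grid_cols: int = 30
    complexities: tuple[int, ...] = (0, 1, 2, 3)
    timesteps: int = 100
    trials: int = 100
    n_seeds: int = DEFAULT_SEEDS
    n_series_seeds: int = DEFAULT_SEEDS
    master_seed: int = 1
    risk_weight: float = 1.0
    ambiguity_weight: float = 1.0
    novelty_weight: float = 24.0
    dirichlet_seed: float = 1.0  # prior count mass per B2 column
    dirichlet_rate: float = 1.0
    pref_pigment: float = 4.0
    pref_background: float = -4.0
    epsilon: float = 1e-3
    max_saccade: int | None = None
    plus_penalty: float = -8.0
    decision_rule: str = "sample"
    band_row: int | None = None
    out_dir: str = "outputs"

    def __post_init__(self) -> None:
        checks = [
            (self.grid_rows >= 1 and self.grid_cols >= 1, "grid dimensions must be >= 1"),
            (len(self.complexities) > 0, "at least one complexity level required"),
            (all(c in (0, 1, 2, 3) for c in self.complexities), "complexities must be in {0,1,2,3}"),
            (self.timesteps >= 4, "timesteps must be >= 4"),
            (self.trials >= 1, "trials must be >= 1"),
            (self.n_seeds >= 1, "n_seeds must be >= 1"),
            (self.n_series_seeds >= 1, "n_series_seeds must be >= 1"),
            (0 <= self.master_seed < 2**31, "master_seed must fit in 31 bits"),
            (self.dirichlet_seed > 0, "dirichlet_seed must be positive"),
            (self.dirichlet_rate > 0, "dirichlet_rate must be positive"),
            (0 < self.epsilon < 0.5, "epsilon must be in (0, 0.5)"),
            (self.risk_weight >= 0 and self.ambiguity_weight >= 0 and self.novelty_weight >= 0,
             "EFE weights must be non-negative"),
            (self.max_saccade is None or self.max_saccade >= 1, "max_saccade must be >= 1 or null"),
            (self.plus_penalty <= 0, "plus_penalty must be <= 0"),
            (self.decision_rule in ("sample", "argmax"), "decision_rule must be 'sample' or 'argmax'"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)
        object.__setattr__(self, "complexities", tuple(int(c) for c in self.complexities))

    @property
    def efe_weights(self) -> EFEWeights:
        return EFEWeights(
            risk=self.risk_weight, ambiguity=self.ambiguity_weight, novelty=self.novelty_weight
        )

    def episode_kwargs(self) -> dict:
        """Keyword arguments for :func:`cpast.foraging.run_episode`."""
        return dict(
            timesteps=self.timesteps,
            weights=self.efe_weights,
            epsilon=self.epsilon,
            dirichlet_seed=self.dirichlet_seed,
            dirichlet_rate=self.dirichlet_rate,
            pref_pigment=self.pref_pigment,
            pref_background=self.pref_background,
            max_saccade=self.max_saccade,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["complexities"] = list(self.complexities)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the resolved configuration.

        The output directory is excluded: it does not affect any result.
        """
        d = self.to_dict()
        d.pop("out_dir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "complexities" in data:
        data["complexities"] = tuple(data["complexities"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(f"unknown config key: {exc}") from exc
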