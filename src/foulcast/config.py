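"""Run configuration: strict key checking, YAML round-trip, seed fan-out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

#: pipeline stages in execution order
STAGES = ("flux", "ftir", "eem", "varpart", "network")


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    ``overrides`` maps stage name → keyword overrides forwarded to that
    stage's generator/analysis calls.  Unknown top-level keys, stages or
    scenarios are rejected so config typos fail loudly.
    """

    scenarios: list[str] = field(default_factory=lambda: ["Ctrl", "Al", "Fe"])
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    overrides: dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "foulcast_run"

    def __post_init__(self) -> None:
        from .synthdata import SCENARIOS

        bad = [s for s in self.scenarios if s not in SCENARIOS]
        if bad:
            raise ValueError(f"unknown scenarios: {bad}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}; expected {STAGES}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        bad = [s for s in self.overrides if s not in STAGES]
        if bad:
            raise ValueError(f"overrides for unknown stages: {bad}")

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"scenarios", "stages", "overrides", "seed", "out_dir"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    # -- deterministic seed fan-out ---------------------------------------

    def stage_seed(self, stage: str, scenario: str | None = None) -> int:
        """Deterministic per-stage, per-scenario sub-seed.

        Derived as ``SeedSequence([seed, stage_index, scenario_index])`` so
        any stage can be re-run in isolation and still see the exact stream
        it saw inside the full pipeline.
        """
        from .synthdata import SCENARIOS

        stage_idx = STAGES.index(stage)
        scen_idx = 0 if scenario is None else SCENARIOS.index(scenario) + 1
        ss = np.random.SeedSequence([self.seed, stage_idx, scen_idx])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
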