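"""Run configuration, seed derivation and schema-validated YAML loading.

A run is described by one nested mapping with sections mirroring the module
configs (task / rnn / timing / training / synth / analysis) plus a global
seed and output directory. Unknown keys are rejected so typos fail loudly,
and every run can write its fully-resolved configuration next to its
outputs. Per-stage seeds derive from the global seed by stable hashing, so
pipeline stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .rnn import TrialTiming
from .synth import SynthConfig
from .task import TaskConfig
from .train import TrainConfig

__all__ = ["RnnInitConfig", "AnalysisConfig", "RunConfig", "derive_seed", "load_config"]


@dataclass(frozen=True)
class RnnInitConfig:
    """Network construction parameters (initialization, not dynamics)."""

    N: int = 200
    conn_prob: float = 0.1
    g: float = 2.0
    tau: float = 20.0
    act_a: float = 6.0
    act_b: float = 0.0
    input_sd: float = 0.9
    baseline_input: float = 1.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared analysis parameters."""

    align_halfwidth: int = 10      # K: relative-trial window around the reversal
    delta: int = 4                 # target-switch delay (trials)
    svr_T0: float = -500.0
    svr_Ti: float = -300.0
    svr_Tf: float = 800.0
    decoder_dk: int = 10
    decoder_dt: float = 160.0
    decoder_dh: float = 20.0


_SECTIONS = {
    "task": TaskConfig,
    "rnn": RnnInitConfig,
    "timing": TrialTiming,
    "training": TrainConfig,
    "synth": SynthConfig,
    "analysis": AnalysisConfig,
}


@dataclass
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    rnn: RnnInitConfig = field(default_factory=RnnInitConfig)
    timing: TrialTiming = field(default_factory=TrialTiming)
    training: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    outdir: str = "runs/default"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"seed": self.seed, "outdir": self.outdir}
        for name in _SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def write_resolved(self, directory: str | Path) -> Path:
        """Write the fully-resolved configuration next to the run's outputs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "config.resolved.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, default=float))
        return path


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def _build_section(cls, data: dict[str, Any], section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run configuration must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed", "outdir"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValueError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, raw[name], name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    return RunConfig(**kwargs)
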