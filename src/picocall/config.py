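"""YAML run configuration with strict key validation.

A :class:`RunConfig` mirrors each stage's own config type in a nested
section.  Unknown keys are rejected with their full dotted path; every run
writes the resolved configuration beside its outputs so results are
reproducible from the artifact directory alone.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

log = logging.getLogger("picocall")


class ConfigError(ValueError):
    pass


@dataclass
class SimulateSection:
    n_reads: int = 50
    read_length: Tuple[int, int] = (800, 1200)
    k: int = 4
    level_spread: float = 1.0
    noise_sd: float = 0.25
    dwell_mean: float = 5.0
    dwell_law: str = "geometric"
    gc_fraction: float = 0.5
    chunk: int = 4000
    overlap: int = 500


@dataclass
class TrainSection:
    learning_rate: float = 2e-3
    beta: float = 0.999
    weight_decay: float = 0.01
    epsilon: float = 1e-8
    batch_size: int = 64
    epochs: int = 5


@dataclass
class SearchSection:
    lambda_hw: float = 0.6
    search_chunks: int = 30_000
    epochs: int = 5
    n_groups: int = 5
    repeats: int = 4
    channel_options: Tuple[int, ...] = (16, 24, 32, 48, 64)
    cost_model: str = "analytic"  # "analytic" or a table path


@dataclass
class DistillSection:
    alpha: float = 0.9
    tau: float = 2.0
    skip_stride: int = 1
    total_epochs: int = 8


@dataclass
class PruneSection:
    mode: str = "unstructured"
    sparsity: float = 0.85
    finetune_epochs: int = 2


@dataclass
class BasecallSection:
    chunk: int = 4000
    overlap: int = 500
    decoder: str = "beam"
    beam_width: int = 8


@dataclass
class EvaluateSection:
    min_identity: float = 50.0


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    train: TrainSection = field(default_factory=TrainSection)
    search: SearchSection = field(default_factory=SearchSection)
    distill: DistillSection = field(default_factory=DistillSection)
    prune: PruneSection = field(default_factory=PruneSection)
    basecall: BasecallSection = field(default_factory=BasecallSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)

    def resolved_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_resolved(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "resolved_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved_dict(), fh, sort_keys=False)
        return path


def _build(cls, data, where: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"{where}: unknown keys {unknown}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_resolve(ftype)):
            kwargs[name] = _build(_resolve(ftype), value, f"{where}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _resolve(ftype):
    # dataclass field types are strings under `from __future__ import annotations`
    if isinstance(ftype, str):
        return globals().get(ftype, ftype)
    return ftype


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data, "config")


def config_from_dict(data: Optional[dict]) -> RunConfig:
    return _build(RunConfig, data or {}, "config")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


class StageTimer:
    """Log per-stage wall time."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.monotonic()
        log.info("stage %s started", self.name)
        return self

    def __exit__(self, *exc):
        log.info("stage %s finished in %.2fs", self.name,
                 time.monotonic() - self.t0)
        return False
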