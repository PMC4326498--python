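"""Study configuration, seed management, and the run manifest.

All randomness flows from a single integer master seed through numpy
``SeedSequence`` spawning: condition index -> per-dataset child sequences,
each split into a generation stream and a permutation stream.  No global
RNG state is touched anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .pointprocess import SimulationConfig

__version__ = "0.1.0"

DEFAULT_RANGE_COUNTS = (1, 10, 50, 100)

_SIM_KEYS = ("side_length", "kappa", "lambda_case", "lambda_control", "cluster_radius")
_STUDY_KEYS = ("range_counts", "n_datasets", "n_perm", "alpha", "method", "seed")
_METHODS = ("pointwise", "simultaneous", "integrated")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce a full simulation study."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    range_counts: tuple[int, ...] = DEFAULT_RANGE_COUNTS
    n_datasets: int = 2000
    n_perm: int = 199
    alpha: float = 0.05
    method: str = "pointwise"
    master_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "range_counts", tuple(int(r) for r in self.range_counts))
        if self.n_datasets < 1:
            raise ConfigError(f"n_datasets must be >= 1, got {self.n_datasets}")
        if any(r < 1 for r in self.range_counts):
            raise ConfigError(f"all range_counts must be >= 1, got {self.range_counts}")
        if self.n_perm < 1:
            raise ConfigError(f"n_perm must be >= 1, got {self.n_perm}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self.sim, k) for k in _SIM_KEYS}
        d.update(range_counts=list(self.range_counts), n_datasets=self.n_datasets,
                 n_perm=self.n_perm, alpha=self.alpha, method=self.method,
                 seed=self.master_seed)
        return d


def config_from_dict(raw: dict) -> StudyConfig:
    """Build a StudyConfig from a flat key/value mapping; unknown keys are a
    hard error (no silent typo tolerance), bad values name the offending key."""
    raw = dict(raw or {})
    known = set(_SIM_KEYS) | set(_STUDY_KEYS)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        sim = SimulationConfig(**{k: raw[k] for k in _SIM_KEYS if k in raw})
    except Exception as exc:
        raise ConfigError(f"invalid simulation parameters: {exc}") from exc
    kw = {}
    if "range_counts" in raw:
        kw["range_counts"] = tuple(raw["range_counts"])
    for src, dst in (("n_datasets", "n_datasets"), ("n_perm", "n_perm"),
                     ("alpha", "alpha"), ("method", "method"), ("seed", "master_seed")):
        if src in raw:
            kw[dst] = raw[src]
    return StudyConfig(sim=sim, **kw)


def load_config(path) -> StudyConfig:
    """Read a JSON or YAML config file (JSON is a YAML subset); an empty file
    yields the full default study configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def save_config(config: StudyConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# seed streams

def condition_sequences(master_seed: int, condition_index: int,
                        n_datasets: int) -> list[np.random.SeedSequence]:
    """Per-dataset seed sequences for one study condition, disjoint across
    conditions and datasets by SeedSequence spawn-key construction."""
    root = np.random.SeedSequence(master_seed, spawn_key=(condition_index,))
    return root.spawn(n_datasets)


def dataset_rngs(seq: np.random.SeedSequence) -> tuple[np.random.Generator, np.random.Generator]:
    """Split one dataset sequence into (generation rng, permutation rng)."""
    gen_seq, perm_seq = seq.spawn(2)
    return np.random.default_rng(gen_seq), np.random.default_rng(perm_seq)


@dataclass
class RunManifest:
    """Provenance record: config snapshot + seed derivation + completion map.

    Together with the package version this suffices to regenerate every
    output (up to floating-point platform variation).
    """

    config: dict
    master_seed: int
    seed_scheme: str = ("SeedSequence(master_seed, spawn_key=(condition_index,))"
                        ".spawn(n_datasets); each child spawns (generation, permutation)")
    version: str = __version__
    completed: dict = field(default_factory=dict)  # condition -> list of dataset ids

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
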