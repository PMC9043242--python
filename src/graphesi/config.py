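"""Run configuration: nested, validated, YAML round-trippable.

A single :class:`RunConfig` carries every stage's parameters plus the
global seed.  Unknown keys are rejected (typos fail loudly).  One global
seed fans out to per-stage seeds through a documented derivation
(:func:`stage_seed`), so stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import hashlib

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "stage_seed"]

#: fixed stage indices for the seed fan-out
STAGES = (
    "make-space",
    "spectrum",
    "simulate",
    "train",
    "localize",
    "benchmark",
    "evaluate",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed < 2**31 from the global seed.

    Uses a counter-based spawn: ``SeedSequence(global_seed,
    spawn_key=(stage_index,))``, so each stage's randomness is independent
    of the others and stable across reruns.
    """
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SpaceConfig(_Section):
    subdivisions: int = 3
    radius_mm: float = 80.0


class GraphConfig(_Section):
    neighbor_order: int = 1


class SpectralConfig(_Section):
    k: int | None = None
    t_f: float | None = None
    k_frac: float = 0.3


class SimulateConfig(_Section):
    n_electrodes: int = 64
    scalp_radius_mm: float = 100.0
    snr_db: list[float] = [20.0, 30.0, 40.0]
    n_samples: int | None = None
    n_patches: int = 1
    T: int = 100
    fs_hz: float = 100.0
    neighbor_scale: float = 0.5
    fractions: list[float] = [0.70, 0.15, 0.15]


class ModelConfig(_Section):
    hidden_size: int = 256
    output_activation: str = "identity"
    standardize: bool = True


class TrainConfig(_Section):
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 20
    lr_decay: float = 0.5
    lr_patience: int = 6
    optimizer: str = "nadam"


class SolversConfig(_Section):
    methods: list[str] = ["mne", "dspm", "sloreta"]
    lambda2: float | None = None


class EvaluateConfig(_Section):
    score_mode: str = "max_abs"


class RunConfig(_Section):
    """Full pipeline configuration with per-stage sections."""

    seed: int = 0
    out_dir: str = "runs"
    space: SpaceConfig = SpaceConfig()
    graph: GraphConfig = GraphConfig()
    spectral: SpectralConfig = SpectralConfig()
    simulate: SimulateConfig = SimulateConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()
    solvers: SolversConfig = SolversConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]
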