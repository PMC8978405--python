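"""Pipeline configuration and deterministic seed management.

Every stochastic stage of the pipeline (negative sampling, walk generation,
skip-gram training, cross-validation splitting, classifier fitting) draws its
seed from a single root seed through :func:`child_seed`, keyed by a stage
name.  Re-running any stage with the same root seed and stage name is
therefore bit-reproducible, and stages are insensitive to each other's
consumption of random numbers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

__all__ = ["PipelineConfig", "child_seed", "child_rng"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from a root seed and a stage name.

    The derivation mixes the stage name's CRC32 into a ``SeedSequence`` so
    that distinct stages get statistically independent streams while the
    mapping stays stable across runs and platforms.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """A NumPy Generator seeded for one named pipeline stage."""
    return np.random.default_rng(child_seed(seed, stage))


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole link-prediction pipeline.

    Defaults follow the method's stated choices where it states them
    (``embedding_dim`` 100, ``activity_threshold`` 5.5 pChEMBL units,
    ``probability_threshold`` 0.99, 90/10 external split with 5x repeated
    10-fold CV, boosted-tree depth 4 / subsample 1 / min_child_weight 2 /
    gamma 0.8) and the node2vec / word2vec reference defaults elsewhere
    (p=q=1, 10 walks of length 80 per node, window 10, 5 negatives,
    5 epochs, initial learning rate 0.025).
    """

    # embedding
    embedding_dim: int = 100
    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    negatives_per_positive: int = 5
    epochs: int = 5
    learning_rate: float = 0.025

    # labelling / candidate extraction
    activity_threshold: float = 5.5
    probability_threshold: float = 0.99

    # evaluation protocol
    external_fraction: float = 0.1
    folds: int = 10
    repeats: int = 5
    beta: float = 2.0

    # classifier
    max_depth: int = 4
    subsample: float = 1.0
    min_child_weight: float = 2.0
    gamma: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.external_fraction < 1:
            raise ValueError(f"external_fraction must lie in (0,1), got {self.external_fraction}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.embedding_dim < 2:
            raise ValueError(f"embedding_dim must be >= 2, got {self.embedding_dim}")
        if not 0 <= self.probability_threshold <= 1:
            raise ValueError("probability_threshold must lie in [0,1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must lie in (0,1]")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("walk bias parameters p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        """Load a config from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)
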