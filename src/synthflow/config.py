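"""Run configuration: a strict, versioned YAML schema.

Unknown keys are rejected rather than ignored — silent typos in config
files are the main reproducibility hazard in pipeline tools.  One root
seed deterministically derives per-stage seeds by hashing the stage
name, so reordering stages cannot silently change results.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "stage_seed", "load_config", "save_config"]

CONFIG_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FixturesSection(_Strict):
    n_blocks: int = 200
    n_triples: int = 2000
    n_corpus: int = 1000
    corpus_max_steps: int = 3
    flip_prob: float = 0.05


class PolicySection(_Strict):
    hidden: int = 128
    conv_layers: int = 1
    dense_layers: int = 3
    lr: float = 4e-4
    epochs: int = 10
    batch_size: int = 64
    holdout_frac: float = 0.1


class TransitionSection(_Strict):
    dim: int = 64
    heads: int = 4
    enc_layers: int = 2
    dec_layers: int = 2
    ff_dim: int = 128
    dropout: float = 0.1
    max_len: int = 72
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    holdout_frac: float = 0.1


class RewardSection(_Strict):
    sa_weight: float = 0.0  # λ in R = R_QSAR + λ·R_SA
    floor: float = 1e-6
    n_trees: int = 500


class TrainingSection(_Strict):
    betas: list[float] = Field(default_factory=lambda: [2.0, 8.0, 32.0])
    rounds: int = 200
    batch: int = 32
    max_len: int = 4
    beam: int = 10
    lr: float = 5e-3
    partition_lr: float = 5e-2
    explore_eps: float = 0.1
    transition_source: str = "oracle"
    start_smiles: str = "O=Cc1ccc(C(=O)O)cc1"  # 4-formylbenzoic acid


class SamplingSection(_Strict):
    n_trajectories: int = 400


class MetricsSection(_Strict):
    qsar_threshold: float = 0.5
    max_pairwise: int = 1500


class GridSection(_Strict):
    side: int = 8
    dims: int = 2
    reward_name: str = "corners"
    betas: list[float] = Field(default_factory=lambda: [1.0, 2.0])
    n_updates: int = 3000
    batch: int = 64
    n_samples: int = 50000
    tv_threshold: float = 0.05
    logz_threshold: float = 0.1


class RunConfig(_Strict):
    version: int = CONFIG_VERSION
    seed: int = 0
    outdir: str = "runs/default"
    fixtures: FixturesSection = Field(default_factory=FixturesSection)
    policy: PolicySection = Field(default_factory=PolicySection)
    transition: TransitionSection = Field(default_factory=TransitionSection)
    reward: RewardSection = Field(default_factory=RewardSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    sampling: SamplingSection = Field(default_factory=SamplingSection)
    metrics: MetricsSection = Field(default_factory=MetricsSection)
    grid: GridSection = Field(default_factory=GridSection)


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed derived from the root seed and the stage name."""
    return (root_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**raw)
    if cfg.version != CONFIG_VERSION:
        raise ValueError(
            f"config version {cfg.version} not supported (expected {CONFIG_VERSION})"
        )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
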