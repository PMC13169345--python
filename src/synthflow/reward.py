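"""Reward functions: QSAR surrogate, synthetic-accessibility reward,
temperature, and the multiobjective combination R = R_QSAR + λ·R_SA.

The QSAR surrogate is a random-forest classifier over ECFP4
fingerprints whose positive-class probability is the base reward.
Because the sampler needs R(x) > 0 (log R enters the training loss)
and forest probabilities can be exactly zero, rewards are clamped
below at a small floor.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .chem import Molecule, ecfp

__all__ = [
    "QsarSurrogate",
    "qsar_fit",
    "sa_score",
    "sa_reward",
    "RewardConfig",
    "combined_reward",
    "temper",
]


def _load_sascorer():
    from rdkit.Chem import RDConfig

    contrib = str(Path(RDConfig.RDContribDir) / "SA_Score")
    if contrib not in sys.path:
        sys.path.append(contrib)
    import sascorer  # noqa: PLC0415

    return sascorer


@dataclass
class QsarSurrogate:
    """Fitted activity classifier over fingerprints."""

    radius: int = 2
    nbits: int = 2048
    n_trees: int = 500
    seed: int = 0
    n_active: int = 0
    n_inactive: int = 0
    _forest: RandomForestClassifier | None = field(default=None, repr=False)
    _cache: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def fitted(self) -> bool:
        return self._forest is not None

    def score(self, mol: Molecule) -> float:
        """Positive-class probability on the molecule's fingerprint."""
        if not self.fitted:
            raise RuntimeError("QSAR surrogate is not fitted")
        if mol.smiles not in self._cache:
            fp = ecfp(mol, self.radius, self.nbits)[None, :]
            self._cache[mol.smiles] = float(self._forest.predict_proba(fp)[0, 1])
        return self._cache[mol.smiles]

    def score_fingerprints(self, fps: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("QSAR surrogate is not fitted")
        return self._forest.predict_proba(np.asarray(fps))[:, 1]

    def __call__(self, mol: Molecule) -> float:
        return self.score(mol)


def qsar_fit(
    fps: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[int],
    seed: int = 0,
    n_trees: int = 500,
    radius: int = 2,
    nbits: int = 2048,
) -> QsarSurrogate:
    """Fit the random-forest activity classifier; deterministic given seed."""
    fps = np.asarray(fps)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(
            f"both classes must be present, got labels {classes.tolist()}"
        )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(fps, labels)
    surrogate = QsarSurrogate(
        radius=radius,
        nbits=nbits,
        n_trees=n_trees,
        seed=seed,
        n_active=int((labels == 1).sum()),
        n_inactive=int((labels == 0).sum()),
    )
    surrogate._forest = forest
    return surrogate


def sa_score(mol: Molecule) -> float:
    """Fragment-contribution synthetic-accessibility score, 1 (easy) to
    10 (hard)."""
    return float(_load_sascorer().calculateScore(mol.rdkit))


def sa_reward(mol: Molecule) -> float:
    """Affine map of the SA score onto [0, 1]: (10 - SA) / 9, so 1 means
    maximally synthesizable."""
    return (10.0 - sa_score(mol)) / 9.0


@dataclass
class RewardConfig:
    """Reward assembly: R(x) = clamp(R_QSAR(x) + λ·R_SA(x), floor)."""

    qsar: Callable[[Molecule], float]
    beta: float = 1.0
    sa_weight: float = 0.0  # λ
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.sa_weight < 0:
            raise ValueError("sa_weight must be >= 0")
        if not 0.0 < self.floor < 1.0:
            raise ValueError("floor must be in (0, 1)")

    def __call__(self, mol: Molecule) -> float:
        return combined_reward(self, mol)


def combined_reward(cfg: RewardConfig, mol: Molecule) -> float:
    """Multiobjective reward, clamped below at ``cfg.floor`` so that the
    sampler's log R is always finite."""
    r = float(cfg.qsar(mol))
    if cfg.sa_weight > 0.0:
        r = r + cfg.sa_weight * sa_reward(mol)
    return max(r, cfg.floor)


def temper(r: float, beta: float) -> float:
    """R^β.  Training consumes this in log space (β·log R); this helper
    exists for reporting and tests."""
    if r <= 0:
        raise ValueError("reward must be > 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return float(r**beta)
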