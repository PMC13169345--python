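"""Evaluation of generated compound pools.

Two diversity readings are reported because both appear in practice:
``diversity_mean_pairwise`` is 1 minus the mean Tanimoto similarity
over unordered distinct pairs, and ``intdiv`` is the internal-diversity
measure 1 - (1/|G|^2) Σ T(m1, m2)^2 over ordered pairs including
self-pairs.  All similarities use ECFP4 (radius 2, 2048 bits).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .chem import Molecule, ecfp

__all__ = [
    "MetricsReport",
    "diversity_mean_pairwise",
    "intdiv",
    "uniqueness",
    "novelty",
    "summarize",
]

_FP_RADIUS = 2
_FP_BITS = 2048


def _fp_matrix(mols: Sequence[Molecule]) -> np.ndarray:
    return np.stack([ecfp(m, _FP_RADIUS, _FP_BITS) for m in mols]).astype(np.float64)


def _pairwise_tanimoto(mols: Sequence[Molecule]) -> np.ndarray:
    """Dense pairwise Tanimoto matrix (all-zero pairs give 1)."""
    fp = _fp_matrix(mols)
    inter = fp @ fp.T
    counts = fp.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


def diversity_mean_pairwise(mols: Sequence[Molecule]) -> float:
    """1 - mean Tanimoto over unordered distinct pairs."""
    if len(mols) < 2:
        raise ValueError("mean pairwise diversity needs at least 2 molecules")
    sim = _pairwise_tanimoto(mols)
    n = len(mols)
    iu = np.triu_indices(n, k=1)
    return float(1.0 - sim[iu].mean())


def intdiv(mols: Sequence[Molecule]) -> float:
    """Internal diversity: 1 - (1/|G|^2) Σ over ordered pairs (self-pairs
    included) of squared Tanimoto similarity."""
    if len(mols) < 1:
        raise ValueError("intdiv needs at least 1 molecule")
    sim = _pairwise_tanimoto(mols)
    return float(1.0 - (sim**2).mean())


def uniqueness(mols: Sequence[Molecule]) -> float:
    """Fraction of distinct canonical structures in the pool."""
    if not mols:
        raise ValueError("uniqueness needs a nonempty pool")
    return len({m.smiles for m in mols}) / len(mols)


def novelty(mols: Sequence[Molecule], reference: set[str]) -> float:
    """Fraction of the distinct generated structures absent from the
    reference set of canonical SMILES."""
    if not mols:
        raise ValueError("novelty needs a nonempty pool")
    distinct = {m.smiles for m in mols}
    return len(distinct - reference) / len(distinct)


@dataclass
class MetricsReport:
    total: int
    reward_mean: float
    reward_std: float
    diversity_mean_pairwise: float
    intdiv: float
    uniqueness: float
    novelty_vs_reference: float
    n_above_threshold: int
    frac_above_threshold: float
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)

    def __post_init__(self) -> None:
        for name in ("uniqueness", "novelty_vs_reference", "frac_above_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def summarize(
    pool: Sequence[tuple[Molecule, float]],
    reference: set[str] | None = None,
    qsar_threshold: float = 0.5,
    max_pairwise: int = 2000,
    seed: int = 0,
) -> MetricsReport:
    """Full metrics report for a (molecule, reward) pool.

    Diversity metrics are computed over the pool as generated (a
    multiset: duplicated structures lower diversity, as they lower it
    in the sampler's output distribution); pools larger than
    ``max_pairwise`` entries are subsampled (seeded) before the O(n^2)
    similarity computation.
    """
    if not pool:
        raise ValueError("cannot summarize an empty pool")
    mols = [m for m, _ in pool]
    rewards = np.array([r for _, r in pool], dtype=np.float64)
    reference = reference or set()
    dmols = mols
    if len(dmols) > max_pairwise:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(dmols), size=max_pairwise, replace=False)
        dmols = [dmols[i] for i in idx]
    n_above = int((rewards >= qsar_threshold).sum())
    return MetricsReport(
        total=len(pool),
        reward_mean=float(rewards.mean()),
        reward_std=float(rewards.std()),
        diversity_mean_pairwise=(
            diversity_mean_pairwise(dmols) if len(dmols) >= 2 else 0.0
        ),
        intdiv=intdiv(dmols),
        uniqueness=uniqueness(mols),
        novelty_vs_reference=novelty(mols, reference),
        n_above_threshold=n_above,
        frac_above_threshold=n_above / len(pool),
        threshold=qsar_threshold,
    )
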