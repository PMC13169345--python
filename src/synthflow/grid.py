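"""Exactly enumerable hypergrid environment.

States are lattice points in {0..H-1}^D; actions increment one
coordinate or stop.  The terminal distribution targeted by a sampler
trained with trajectory balance is R(x)^β / Z(β), and on the grid both
Z(β) and every parent count are brute-forceable, so this environment
is the package's exact verification surface for the sampler: the
proportionality property can be checked to numerical precision rather
than by eyeballing chemistry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["GridDAG", "build_grid", "register_reward", "REWARD_REGISTRY"]

REWARD_REGISTRY: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {}


def register_reward(name: str):
    def deco(fn):
        REWARD_REGISTRY[name] = fn
        return fn

    return deco


@register_reward("constant")
def _constant(x: np.ndarray, side: int) -> np.ndarray:
    return np.ones(x.shape[0])


@register_reward("corners")
def _corners(x: np.ndarray, side: int) -> np.ndarray:
    """Multimodal reward with peaks near the corners: a small base plus
    ridge and peak terms on |x/(H-1) - 0.5| (the usual hypergrid test
    function for samplers of unnormalized densities)."""
    t = np.abs(x / (side - 1) - 0.5)
    ridge = np.all((t > 0.25) & (t <= 0.5), axis=1)
    peak = np.all((t > 0.3) & (t < 0.4), axis=1)
    return 0.1 + 0.5 * ridge + 2.0 * peak


@register_reward("cosine")
def _cosine(x: np.ndarray, side: int) -> np.ndarray:
    """Smooth multimodal positive reward."""
    u = x / (side - 1)
    return 0.1 + np.prod(np.cos(2.0 * np.pi * u) ** 2, axis=1)


@dataclass
class GridDAG:
    """H^D lattice with increment actions and an explicit stop action."""

    side: int
    dims: int
    reward_name: str
    reward_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def n_actions(self) -> int:
        # D increments + stop
        return self.dims + 1

    @property
    def stop_action(self) -> int:
        return self.dims

    def root(self) -> np.ndarray:
        return np.zeros(self.dims, dtype=np.int64)

    def valid_actions(self, state: np.ndarray) -> np.ndarray:
        """Boolean mask over actions; increments past the boundary are
        invalid, stop is always allowed."""
        mask = np.ones(self.n_actions, dtype=bool)
        mask[: self.dims] = state < self.side - 1
        return mask

    def step(self, state: np.ndarray, action: int) -> np.ndarray:
        if action == self.stop_action:
            return state.copy()
        if state[action] >= self.side - 1:
            raise ValueError(f"action {action} off the grid at state {state}")
        nxt = state.copy()
        nxt[action] += 1
        return nxt

    def parent_count(self, state: np.ndarray) -> int:
        """Number of incoming increment edges; the root has 1 by the
        virtual-root convention."""
        n = int(np.count_nonzero(state))
        return max(n, 1)

    # -- exhaustive quantities ----------------------------------------
    def all_states(self) -> np.ndarray:
        return np.array(
            list(itertools.product(range(self.side), repeat=self.dims)),
            dtype=np.int64,
        )

    def rewards(self, states: np.ndarray) -> np.ndarray:
        r = self.reward_fn(states)
        if np.any(r <= 0):
            raise ValueError("grid rewards must be strictly positive")
        return r

    def partition(self, beta: float) -> float:
        """Brute-force Z(β) = Σ_x R(x)^β over all terminal states."""
        return float(np.sum(self.rewards(self.all_states()) ** beta))

    def target_distribution(self, beta: float) -> np.ndarray:
        """Exact tempered target R(x)^β / Z(β), indexed like all_states()."""
        w = self.rewards(self.all_states()) ** beta
        return w / w.sum()

    def state_index(self, states: np.ndarray) -> np.ndarray:
        """Row index of each state in all_states() ordering."""
        states = np.atleast_2d(states)
        powers = self.side ** np.arange(self.dims - 1, -1, -1)
        return states @ powers


def build_grid(side: int, dims: int = 2, reward_name: str = "corners") -> GridDAG:
    if side < 2:
        raise ValueError("side must be >= 2")
    if reward_name not in REWARD_REGISTRY:
        raise KeyError(
            f"unknown reward {reward_name!r}; registered: "
            f"{sorted(REWARD_REGISTRY)}"
        )
    fn = REWARD_REGISTRY[reward_name]
    return GridDAG(side, dims, reward_name, lambda x: fn(np.atleast_2d(x), side))
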