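"""Trajectory sampling and trajectory-balance training.

The sampler draws complete trajectories τ = (s_0 → … → s_T) through an
environment (the chemical reaction MDP or the enumerable grid) and the
trainer minimizes the tempered trajectory-balance objective

    L(τ) = ( log Z(β) + Σ_t log P_F(s_{t+1}|s_t)
             − β·log R(s_T) − Σ_t log P_B(s_{t-1}|s_t) )²,

which at optimum makes the terminal distribution proportional to
R(x)^β.  The forward policy factorizes into a template policy π(a|s)
and a transition distribution T(s'|s, a); the backward policy is
uniform over parents (exact counts where the DAG is enumerable, the
single-parent tree assumption otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import Molecule
from .grid import GridDAG
from .mdp import ReactionMDP
from .models.partition import PartitionMLP
from .models.policy import GCNPolicy
from .nn import (
    Adam,
    MLP,
    Module,
    Tensor,
    log_softmax,
    no_grad,
    scatter_rows,
    stack,
)

__all__ = [
    "Trajectory",
    "TBLossInputs",
    "tb_loss",
    "GridPolicy",
    "sample_trajectory",
    "train_grid",
    "GridTrainResult",
    "train_chem",
    "ChemTrainResult",
    "forward_marginal",
    "sample_compounds",
]


# ----------------------------------------------------------------------
# trajectory container and loss
# ----------------------------------------------------------------------


@dataclass
class Trajectory:
    """One complete sampled trajectory."""

    states: list
    actions: list[int]
    step_logprobs: list[float]
    reward: float

    def __post_init__(self) -> None:
        if not (len(self.actions) == len(self.states) - 1 == len(self.step_logprobs)):
            raise ValueError(
                "trajectory shape mismatch: "
                f"{len(self.states)} states, {len(self.actions)} actions, "
                f"{len(self.step_logprobs)} step log-probs"
            )
        if self.reward <= 0:
            raise ValueError("trajectory reward must be > 0")

    @property
    def terminal(self):
        return self.states[-1]

    @property
    def length(self) -> int:
        return len(self.actions)

    @property
    def log_forward(self) -> float:
        return float(sum(self.step_logprobs))


@dataclass
class TBLossInputs:
    log_forward: float
    log_backward: float
    log_partition: float
    log_reward: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("log_forward", "log_backward", "log_partition", "log_reward", "beta"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite TB loss input: {name} = {v}")


def tb_loss(inputs: TBLossInputs) -> float:
    """Squared log-ratio trajectory-balance loss (floats; the training
    loops build the same expression on tensors)."""
    delta = (
        inputs.log_partition
        + inputs.log_forward
        - inputs.beta * inputs.log_reward
        - inputs.log_backward
    )
    return float(delta * delta)


# ----------------------------------------------------------------------
# grid sampler / trainer
# ----------------------------------------------------------------------


class GridPolicy(Module):
    """MLP forward policy over one-hot grid coordinates."""

    def __init__(self, grid: GridDAG, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.grid = grid
        self.mlp = MLP(rng, grid.side * grid.dims, [hidden, hidden], grid.n_actions)

    def encode(self, states: np.ndarray) -> np.ndarray:
        B = states.shape[0]
        x = np.zeros((B, self.grid.dims, self.grid.side))
        idx = np.arange(B)[:, None], np.arange(self.grid.dims)[None, :], states
        x[idx] = 1.0
        return x.reshape(B, -1)

    def log_probs(self, states: np.ndarray, valid: np.ndarray) -> Tensor:
        logits = self.mlp(Tensor(self.encode(states)))
        return log_softmax(logits, axis=-1, mask=valid)


def _sample_grid_batch(
    grid: GridDAG,
    policy: GridPolicy,
    batch: int,
    rng: np.random.Generator,
    collect_grad: bool = True,
):
    """Roll out a batch of grid trajectories in lock step.

    Returns (terminal states, log_forward tensor (B,), log_backward (B,)).
    """
    states = np.zeros((batch, grid.dims), dtype=np.int64)
    log_f = Tensor(np.zeros(batch))
    log_b = np.zeros(batch)
    active = np.arange(batch)
    max_steps = (grid.side - 1) * grid.dims + 1
    for _ in range(max_steps):
        if len(active) == 0:
            break
        cur = states[active]
        valid = np.stack([grid.valid_actions(s) for s in cur])
        logp = policy.log_probs(cur, valid)
        p = np.exp(logp.data)
        p /= p.sum(axis=1, keepdims=True)
        acts = np.array([rng.choice(grid.n_actions, p=pi) for pi in p])
        chosen = logp[np.arange(len(active)), acts]
        log_f = log_f + scatter_rows(chosen, active, batch)
        nxt_active = []
        for i, (gi, a) in enumerate(zip(active, acts)):
            if a == grid.stop_action:
                continue  # stop edge: terminal has a single parent
            states[gi, a] += 1
            log_b[gi] -= np.log(grid.parent_count(states[gi]))
            nxt_active.append(gi)
        active = np.array(nxt_active, dtype=np.int64)
    return states, log_f, log_b


@dataclass
class GridTrainResult:
    policy: GridPolicy
    partition: PartitionMLP
    loss_history: list[float]
    beta: float


def train_grid(
    grid: GridDAG,
    beta: float = 1.0,
    n_updates: int = 4000,
    batch: int = 64,
    lr: float = 5e-3,
    partition_lr: float = 5e-2,
    hidden: int = 64,
    seed: int = 0,
) -> GridTrainResult:
    """Trajectory-balance training on the grid at a fixed temperature.

    The partition estimator gets its own (larger) learning rate: log Z
    is a single scalar that must move much farther than the policy
    weights."""
    rng = np.random.default_rng(seed)
    policy = GridPolicy(grid, hidden=hidden, seed=seed)
    partition = PartitionMLP(seed=seed + 1)
    opt_p = Adam(policy.parameters(), lr=lr, clip_norm=10.0)
    opt_z = Adam(partition.parameters(), lr=partition_lr, clip_norm=10.0)
    log_rewards_all = np.log(grid.rewards(grid.all_states()))
    history: list[float] = []
    for _ in range(n_updates):
        terminals, log_f, log_b = _sample_grid_batch(grid, policy, batch, rng)
        idx = grid.state_index(terminals)
        log_r = log_rewards_all[idx]
        log_z = partition(beta).reshape(1)
        delta = log_z + log_f - Tensor(beta * log_r) - Tensor(log_b)
        loss = (delta * delta).mean()
        opt_p.zero_grad()
        opt_z.zero_grad()
        loss.backward()
        opt_p.step()
        opt_z.step()
        history.append(loss.item())
    return GridTrainResult(policy, partition, history, beta)


def sample_grid_terminals(
    grid: GridDAG, policy: GridPolicy, n: int, seed: int = 0, chunk: int = 2048
) -> np.ndarray:
    """Draw terminal states from the trained sampler (no gradients)."""
    rng = np.random.default_rng(seed)
    out = []
    with no_grad():
        remaining = n
        while remaining > 0:
            b = min(chunk, remaining)
            terminals, _, _ = _sample_grid_batch(grid, policy, b, rng, collect_grad=False)
            out.append(terminals)
            remaining -= b
    return np.concatenate(out, axis=0)


def empirical_distribution(grid: GridDAG, terminals: np.ndarray) -> np.ndarray:
    counts = np.bincount(grid.state_index(terminals), minlength=grid.side**grid.dims)
    return counts / counts.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return float(0.5 * np.abs(p - q).sum())


# ----------------------------------------------------------------------
# chemical sampler / trainer
# ----------------------------------------------------------------------


def sample_trajectory(
    mdp: ReactionMDP,
    policy: GCNPolicy,
    start: Molecule,
    reward_fn,
    max_len: int | None = None,
    rng: np.random.Generator | None = None,
    explore_eps: float = 0.0,
) -> Trajectory:
    """Sample one trajectory: mask the policy to applicable templates,
    sample a template, sample a product from the transition candidates,
    repeat until ``max_len`` or a dead end (early stop terminates at the
    current state).

    ``explore_eps`` mixes a uniform distribution over applicable
    templates into the sampling policy.  The recorded step log-probs are
    always the policy's own (the balance condition holds for any
    full-support sampler, so exploration steps are off-policy training
    data, not a change of objective).
    """
    rng = rng or np.random.default_rng()
    max_len = max_len if max_len is not None else mdp.max_depth
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    states = [start]
    actions: list[int] = []
    logps: list[float] = []
    cur = start
    for _ in range(max_len):
        applicable = mdp.applicable(cur)
        if not applicable:
            break
        mask = np.zeros(mdp.library.size, dtype=bool)
        mask[applicable] = True
        with no_grad():
            logp = policy.log_probs([cur], mask=mask[None, :]).data[0]
        p = np.exp(logp[applicable])
        p /= p.sum()
        if explore_eps > 0.0:
            p = (1.0 - explore_eps) * p + explore_eps / len(applicable)
            p /= p.sum()
        a = int(rng.choice(applicable, p=p))
        cands = mdp.candidates(cur, a)
        if not cands:
            break
        probs = np.array([q for _, q in cands])
        probs /= probs.sum()
        j = int(rng.choice(len(cands), p=probs))
        nxt = cands[j][0]
        logps.append(float(logp[a] + np.log(probs[j])))
        states.append(nxt)
        actions.append(a)
        cur = nxt
    return Trajectory(states, actions, logps, reward=float(reward_fn(cur)))


def forward_marginal(
    mdp: ReactionMDP, policy: GCNPolicy, state: Molecule, successor: Molecule
) -> float:
    """Action-marginalized one-step forward probability
    P_F(s'|s) = Σ_a π(a|s)·T(s'|s, a).

    Diagnostic only: the training loss uses the state–action
    factorization (the probability of the action actually taken), not
    this marginal."""
    applicable = mdp.applicable(state)
    if not applicable:
        return 0.0
    mask = np.zeros(mdp.library.size, dtype=bool)
    mask[applicable] = True
    with no_grad():
        logp = policy.log_probs([state], mask=mask[None, :]).data[0]
    total = 0.0
    for a in applicable:
        for cand, prob in mdp.candidates(state, a):
            if cand.smiles == successor.smiles:
                total += float(np.exp(logp[a])) * prob
    return total


@dataclass
class ChemTrainResult:
    policy: GCNPolicy
    partition: PartitionMLP
    history: list[dict]
    pool: list[tuple[Molecule, float, int, int]]  # (mol, reward, traj id, step)
    beta: float


def train_chem(
    mdp: ReactionMDP,
    policy: GCNPolicy,
    partition: PartitionMLP,
    reward_fn,
    start: Molecule,
    beta: float = 1.0,
    rounds: int = 60,
    batch: int = 32,
    max_len: int = 4,
    lr: float = 2e-3,
    partition_lr: float = 5e-2,
    seed: int = 0,
    transition_model=None,
    transition_lr: float | None = None,
    explore_eps: float = 0.1,
) -> ChemTrainResult:
    """Joint trajectory-balance training on the chemical MDP.

    Per round: sample a batch of trajectories from ``start``, rebuild
    their forward log-probabilities differentiably, and take one Adam
    step on the mean TB loss for the policy, the partition estimator,
    and (in learned-transition mode) the transition model.  Every state
    visited on every trajectory joins the compound pool.
    """
    rng = np.random.default_rng(seed)
    opt_p = Adam(policy.parameters(), lr=lr, clip_norm=10.0)
    opt_z = Adam(partition.parameters(), lr=partition_lr, clip_norm=10.0)
    opt_t = None
    if transition_model is not None and mdp.transition_source == "learned":
        opt_t = Adam(
            transition_model.parameters(),
            lr=transition_lr if transition_lr is not None else lr,
            clip_norm=10.0,
        )
    reward_cache: dict[str, float] = {}

    def reward(mol: Molecule) -> float:
        if mol.smiles not in reward_cache:
            reward_cache[mol.smiles] = float(reward_fn(mol))
        return reward_cache[mol.smiles]

    history: list[dict] = []
    pool: list[tuple[Molecule, float, int, int]] = []
    traj_counter = 0
    # batch-norm statistics stay frozen at their pretrained values so the
    # differentiable pass reproduces exactly the probabilities sampled from
    policy.eval()
    for _ in range(rounds):
        trajs = [
            sample_trajectory(
                mdp, policy, start, reward, max_len, rng, explore_eps=explore_eps
            )
            for _ in range(batch)
        ]
        # differentiable forward log-probabilities, batched per step
        log_fs = []
        for traj in trajs:
            terms = []
            for t, a in enumerate(traj.actions):
                s = traj.states[t]
                applicable = mdp.applicable(s)
                mask = np.zeros(mdp.library.size, dtype=bool)
                mask[applicable] = True
                logp = policy.log_probs([s], mask=mask[None, :])[0, a]
                cands = mdp.candidates(s, a)
                probs = np.array([q for _, q in cands])
                probs /= probs.sum()
                j = next(
                    i for i, (m, _) in enumerate(cands)
                    if m.smiles == traj.states[t + 1].smiles
                )
                terms.append(logp + float(np.log(probs[j])))
            if terms:
                log_fs.append(stack(terms).sum())
            else:
                log_fs.append(Tensor(0.0))
        log_b = np.array(
            [
                sum(
                    -np.log(mdp.parent_count(s, start))
                    for s in traj.states[1:]
                )
                for traj in trajs
            ]
        )
        log_r = np.array([np.log(t.reward) for t in trajs])
        log_z = partition(beta).reshape(1)
        losses = [
            (log_z + lf - Tensor(beta * r) - Tensor(b)) ** 2.0
            for lf, r, b in zip(log_fs, log_r, log_b)
        ]
        loss = stack([l.reshape(()) for l in losses]).mean()
        opt_p.zero_grad()
        opt_z.zero_grad()
        if opt_t is not None:
            opt_t.zero_grad()
        loss.backward()
        opt_p.step()
        opt_z.step()
        if opt_t is not None:
            opt_t.step()
        for traj in trajs:
            for step, s in enumerate(traj.states[1:], start=1):
                pool.append((s, reward(s), traj_counter, step))
            traj_counter += 1
        if not np.isfinite(loss.item()):
            raise FloatingPointError("trajectory-balance loss diverged")
        history.append(
            {
                "loss": loss.item(),
                "mean_reward": float(np.mean([t.reward for t in trajs])),
                "mean_length": float(np.mean([t.length for t in trajs])),
            }
        )
    return ChemTrainResult(policy, partition, history, pool, beta)


def sample_compounds(
    mdp: ReactionMDP,
    policy: GCNPolicy,
    reward_fn,
    starts: Sequence[Molecule],
    n_trajectories: int,
    max_len: int = 4,
    seed: int = 0,
) -> list[tuple[Molecule, float, int, int]]:
    """Pool every non-start state of ``n_trajectories`` trajectories per
    start compound, with rewards and provenance (trajectory id, step)."""
    rng = np.random.default_rng(seed)
    policy.eval()
    cache: dict[str, float] = {}

    def reward(mol: Molecule) -> float:
        if mol.smiles not in cache:
            cache[mol.smiles] = float(reward_fn(mol))
        return cache[mol.smiles]

    pool = []
    tid = 0
    for start in starts:
        for _ in range(n_trajectories):
            traj = sample_trajectory(mdp, policy, start, reward, max_len, rng)
            for step, s in enumerate(traj.states[1:], start=1):
                pool.append((s, reward(s), tid, step))
            tid += 1
    return pool
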