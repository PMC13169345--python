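"""Self-contained verification experiments at the default study scale.

Each function runs one experiment end to end from a single root seed
and returns plain numbers.  They are the package's evidence that the
sampler does what it claims:

* the grid experiments verify sampling proportionality and partition
  recovery exactly (brute-forced targets);
* the temperature sweep reproduces the reward/diversity trade-off
  direction on the chemical fixture environment;
* the pretraining and surrogate experiments check that each learned
  component recovers its planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Molecule, ecfp
from .config import RunConfig, stage_seed
from .gflownet import (
    empirical_distribution,
    sample_compounds,
    sample_grid_terminals,
    total_variation,
    train_chem,
    train_grid,
)
from .grid import build_grid
from .mdp import ReactionMDP
from .metrics import diversity_mean_pairwise
from .models.partition import PartitionMLP, log_partition
from .models.policy import GCNPolicy, PolicyConfig, pretrain_policy
from .models.transition import TransitionConfig, TransitionTransformer, pretrain_transition
from .pipeline import build_fixtures, fit_reward_surrogate, pretrain_models
from .reward import RewardConfig, qsar_fit

__all__ = [
    "grid_proportionality",
    "partition_recovery_2x2",
    "temperature_sweep",
    "pretraining_accuracy",
    "qsar_recovery",
    "environment_validity",
]


def _config(seed: int) -> RunConfig:
    return RunConfig(seed=seed)


def grid_proportionality(seed: int, betas: tuple[float, ...] = (1.0, 2.0)) -> dict:
    """Train on the 8x8 multimodal grid and measure, per temperature,
    the total-variation distance between 50,000 sampled terminals and
    the brute-forced tempered target, plus the log-partition error."""
    cfg = _config(seed)
    out = {}
    for beta in betas:
        grid = build_grid(cfg.grid.side, cfg.grid.dims, cfg.grid.reward_name)
        res = train_grid(
            grid,
            beta=beta,
            n_updates=cfg.grid.n_updates,
            batch=cfg.grid.batch,
            seed=stage_seed(seed, "grid-train"),
        )
        terminals = sample_grid_terminals(
            grid, res.policy, cfg.grid.n_samples, seed=stage_seed(seed, "grid-sample")
        )
        tv = total_variation(
            empirical_distribution(grid, terminals), grid.target_distribution(beta)
        )
        logz_err = abs(
            log_partition(res.partition, beta) - np.log(grid.partition(beta))
        )
        out[beta] = {
            "tv_distance": float(tv),
            "logz_error": float(logz_err),
            "n_samples": int(cfg.grid.n_samples),
            "n_updates": int(cfg.grid.n_updates),
        }
    return out


def partition_recovery_2x2(seed: int) -> dict:
    """Constant-reward 2x2 grid: the partition estimator must land
    within 0.1 of log 4."""
    grid = build_grid(2, 2, "constant")
    res = train_grid(
        grid, beta=1.0, n_updates=700, batch=32, seed=stage_seed(seed, "grid2-train")
    )
    lz = log_partition(res.partition, 1.0)
    return {
        "logz_learned": float(lz),
        "logz_true": float(np.log(4.0)),
        "logz_error": float(abs(lz - np.log(4.0))),
    }


def temperature_sweep(
    seed: int, betas: tuple[float, ...] = (2.0, 8.0, 32.0)
) -> dict:
    """The reward/diversity trade-off on the chemical fixture
    environment: identical budgets and seeds at every temperature."""
    import copy

    cfg = _config(seed)
    bundle = build_fixtures(cfg)
    qsar = fit_reward_surrogate(cfg, bundle)
    policy0, _, _, _ = pretrain_models(cfg, bundle, with_transition=False)
    start = Molecule.from_smiles(cfg.training.start_smiles)
    out = {}
    for beta in betas:
        policy = copy.deepcopy(policy0)
        mdp = ReactionMDP(bundle.library, max_depth=cfg.training.max_len)
        partition = PartitionMLP(seed=stage_seed(seed, "partition-init"))
        reward = RewardConfig(qsar=qsar, beta=beta, floor=cfg.reward.floor)
        train_chem(
            mdp,
            policy,
            partition,
            reward,
            start,
            beta=beta,
            rounds=cfg.training.rounds,
            batch=cfg.training.batch,
            max_len=cfg.training.max_len,
            lr=cfg.training.lr,
            partition_lr=cfg.training.partition_lr,
            explore_eps=cfg.training.explore_eps,
            seed=stage_seed(seed, "tb-train"),
        )
        pool = sample_compounds(
            mdp,
            policy,
            reward,
            [start],
            cfg.sampling.n_trajectories,
            max_len=cfg.training.max_len,
            seed=stage_seed(seed, "sample"),
        )
        mols = [m for m, _, _, _ in pool]
        rewards = np.array([r for _, r, _, _ in pool])
        rng = np.random.default_rng(stage_seed(seed, "metrics"))
        idx = rng.choice(
            len(mols), min(cfg.metrics.max_pairwise, len(mols)), replace=False
        )
        out[beta] = {
            "mean_reward": float(rewards.mean()),
            "diversity": float(diversity_mean_pairwise([mols[i] for i in idx])),
            "pool_size": len(pool),
            "pool": pool,
        }
    return out


def pretraining_accuracy(seed: int) -> dict:
    """Held-out accuracy of both pretrained components on the
    2000-triple fixture corpus."""
    cfg = _config(seed)
    bundle = build_fixtures(cfg)
    policy, policy_report, transition, transition_report = pretrain_models(
        cfg, bundle, with_transition=True
    )
    return {
        "policy_top1": policy_report.topk_accuracy[1],
        "policy_top5": policy_report.topk_accuracy[5],
        "policy_top10": policy_report.topk_accuracy[10],
        "policy_majority_baseline": policy_report.majority_baseline,
        "transition_exact_match": transition_report.exact_match_holdout,
        "n_triples": len(bundle.triples),
    }


def qsar_recovery(seed: int, holdout_frac: float = 0.2) -> dict:
    """Train the surrogate on noisy planted labels and score its
    recovery of the noise-free planted rule on a held-out split."""
    from sklearn.metrics import roc_auc_score

    from .fixtures import planted_activity_labels

    cfg = _config(seed)
    bundle = build_fixtures(cfg)
    clean = planted_activity_labels(bundle.corpus, flip_prob=0.0)
    fps = np.stack([ecfp(m) for m in bundle.corpus])
    noisy = np.array(bundle.labels)
    rng = np.random.default_rng(stage_seed(seed, "qsar-split"))
    order = rng.permutation(len(bundle.corpus))
    n_hold = int(round(len(order) * holdout_frac))
    test_idx, train_idx = order[:n_hold], order[n_hold:]
    model = qsar_fit(
        fps[train_idx],
        noisy[train_idx],
        seed=stage_seed(seed, "qsar"),
        n_trees=cfg.reward.n_trees,
    )
    scores = model.score_fingerprints(fps[test_idx])
    clean_test = np.array(clean)[test_idx]
    return {
        "auroc_vs_planted_truth": float(roc_auc_score(clean_test, scores)),
        "n_train": len(train_idx),
        "n_holdout": len(test_idx),
        "flip_prob": cfg.fixtures.flip_prob,
        "active_fraction": float(np.mean(clean)),
    }


def environment_validity(seed: int, pool=None) -> dict:
    """Structural validity of everything the environment produces:
    sampled compounds re-canonicalize, and every fixture reaction triple
    re-validates through the template engine."""
    from .chem import canonicalize
    from .templates import apply_template

    cfg = _config(seed)
    bundle = build_fixtures(cfg)
    if pool is None:
        policy = GCNPolicy(
            PolicyConfig(hidden=cfg.policy.hidden, epochs=1),
            bundle.library.size,
            seed=stage_seed(seed, "policy-init"),
        )
        policy.eval()
        mdp = ReactionMDP(bundle.library, max_depth=cfg.training.max_len)
        pool = sample_compounds(
            mdp,
            policy,
            lambda m: 0.5,
            [Molecule.from_smiles(cfg.training.start_smiles)],
            100,
            max_len=cfg.training.max_len,
            seed=stage_seed(seed, "validity-sample"),
        )
    n_valid = 0
    for entry in pool:
        mol = entry[0]
        if canonicalize(mol.smiles) == mol.smiles:
            n_valid += 1
    n_revalidated = sum(
        t.product in apply_template(bundle.library[t.template_index], t.reactant)
        for t in bundle.triples
    )
    return {
        "pool_valid_fraction": n_valid / max(len(pool), 1),
        "pool_size": len(pool),
        "triples_revalidated_fraction": n_revalidated / len(bundle.triples),
        "n_triples": len(bundle.triples),
    }
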