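"""End-to-end orchestration: fixtures → pretraining → reward fitting →
trajectory-balance training → sampling → metrics.

Every stage is a plain function taking a :class:`RunConfig`; the CLI
wraps these, and the acceptance machinery calls them directly.  Stage
randomness derives from the root seed via :func:`stage_seed`.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import Molecule, Vocabulary, ecfp
from .config import RunConfig, stage_seed
from .fixtures import (
    ReactionTriple,
    default_template_library,
    generate_activity_corpus,
    generate_building_blocks,
    generate_reaction_dataset,
    planted_activity_labels,
    save_smiles,
    save_triples,
)
from .gflownet import (
    ChemTrainResult,
    sample_compounds,
    total_variation,
    train_chem,
    train_grid,
    sample_grid_terminals,
    empirical_distribution,
)
from .grid import build_grid
from .mdp import ReactionMDP
from .metrics import MetricsReport, summarize
from .models.partition import PartitionMLP, log_partition
from .models.policy import GCNPolicy, PolicyConfig, PolicyReport, pretrain_policy
from .models.transition import (
    TransitionConfig,
    TransitionReport,
    TransitionTransformer,
    pretrain_transition,
)
from .reward import RewardConfig, qsar_fit

log = logging.getLogger(__name__)

__all__ = [
    "FixtureBundle",
    "build_fixtures",
    "fit_reward_surrogate",
    "pretrain_models",
    "run_temperature_sweep",
    "verify_grid",
    "GridVerification",
]


@dataclass
class FixtureBundle:
    library: object
    blocks: list[Molecule]
    triples: list[ReactionTriple]
    corpus: list[Molecule]
    labels: list[int]
    vocab: Vocabulary


def build_fixtures(cfg: RunConfig) -> FixtureBundle:
    """Generate the full synthetic study input from the config seed."""
    lib = default_template_library()
    blocks = generate_building_blocks(
        stage_seed(cfg.seed, "blocks"), cfg.fixtures.n_blocks
    )
    triples = generate_reaction_dataset(
        lib, blocks, cfg.fixtures.n_triples, stage_seed(cfg.seed, "triples")
    )
    corpus = generate_activity_corpus(
        lib,
        blocks,
        cfg.fixtures.n_corpus,
        stage_seed(cfg.seed, "corpus"),
        max_steps=cfg.fixtures.corpus_max_steps,
    )
    labels = planted_activity_labels(
        corpus,
        flip_prob=cfg.fixtures.flip_prob,
        seed=stage_seed(cfg.seed, "labels"),
    )
    smiles = [t.reactant.smiles for t in triples] + [t.product.smiles for t in triples]
    smiles += [m.smiles for m in corpus]
    vocab = Vocabulary.build(smiles, lib.size)
    log.info(
        "fixtures: %d blocks, %d triples, %d corpus molecules (%.0f%% active)",
        len(blocks),
        len(triples),
        len(corpus),
        100.0 * np.mean(labels),
    )
    return FixtureBundle(lib, blocks, triples, corpus, labels, vocab)


def write_fixtures(bundle: FixtureBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.library.save(outdir / "templates.tsv")
    save_smiles(bundle.blocks, outdir / "building_blocks.smi")
    save_triples(bundle.triples, outdir / "reactions.tsv")
    lines = ["smiles\tlabel"] + [
        f"{m.smiles}\t{y}" for m, y in zip(bundle.corpus, bundle.labels)
    ]
    (outdir / "activity_labels.tsv").write_text("\n".join(lines) + "\n")
    bundle.vocab.save(outdir / "vocab.txt")


def fit_reward_surrogate(cfg: RunConfig, bundle: FixtureBundle):
    fps = np.stack([ecfp(m) for m in bundle.corpus])
    return qsar_fit(
        fps,
        bundle.labels,
        seed=stage_seed(cfg.seed, "qsar"),
        n_trees=cfg.reward.n_trees,
    )


def pretrain_models(
    cfg: RunConfig, bundle: FixtureBundle, with_transition: bool = True
) -> tuple[GCNPolicy, PolicyReport, TransitionTransformer | None, TransitionReport | None]:
    pcfg = PolicyConfig(
        hidden=cfg.policy.hidden,
        conv_layers=cfg.policy.conv_layers,
        dense_layers=cfg.policy.dense_layers,
        lr=cfg.policy.lr,
        epochs=cfg.policy.epochs,
        batch_size=cfg.policy.batch_size,
        holdout_frac=cfg.policy.holdout_frac,
    )
    policy = GCNPolicy(pcfg, bundle.library.size, seed=stage_seed(cfg.seed, "policy-init"))
    data = [(t.reactant, t.template_index) for t in bundle.triples]
    policy_report = pretrain_policy(
        policy, data, pcfg, seed=stage_seed(cfg.seed, "policy-train")
    )
    log.info("policy pretraining: top-k %s", policy_report.topk_accuracy)
    transition = None
    transition_report = None
    if with_transition:
        tcfg = TransitionConfig(
            dim=cfg.transition.dim,
            heads=cfg.transition.heads,
            enc_layers=cfg.transition.enc_layers,
            dec_layers=cfg.transition.dec_layers,
            ff_dim=cfg.transition.ff_dim,
            dropout=cfg.transition.dropout,
            max_len=cfg.transition.max_len,
            lr=cfg.transition.lr,
            epochs=cfg.transition.epochs,
            batch_size=cfg.transition.batch_size,
            holdout_frac=cfg.transition.holdout_frac,
        )
        transition = TransitionTransformer(
            tcfg, bundle.vocab, seed=stage_seed(cfg.seed, "transition-init")
        )
        transition_report = pretrain_transition(
            transition,
            bundle.triples,
            tcfg,
            seed=stage_seed(cfg.seed, "transition-train"),
        )
        log.info(
            "transition pretraining: held-out exact match %.3f",
            transition_report.exact_match_holdout,
        )
    return policy, policy_report, transition, transition_report


@dataclass
class SweepEntry:
    beta: float
    report: MetricsReport
    result: ChemTrainResult = field(repr=False)
    pool: list = field(repr=False)


def run_temperature_sweep(
    cfg: RunConfig,
    bundle: FixtureBundle,
    qsar,
    policy: GCNPolicy,
    transition: TransitionTransformer | None = None,
    betas: list[float] | None = None,
) -> list[SweepEntry]:
    """Train one sampler per temperature under identical budgets and
    seeds, then sample and summarize each."""
    betas = betas if betas is not None else cfg.training.betas
    start = Molecule.from_smiles(cfg.training.start_smiles)
    reference = {t.product.smiles for t in bundle.triples}
    entries: list[SweepEntry] = []
    for beta in betas:
        pol = copy.deepcopy(policy)
        mdp = ReactionMDP(
            bundle.library,
            max_depth=cfg.training.max_len,
            transition_source=cfg.training.transition_source,
            transition_model=transition
            if cfg.training.transition_source == "learned"
            else None,
            beam=cfg.training.beam,
        )
        partition = PartitionMLP(seed=stage_seed(cfg.seed, "partition-init"))
        reward = RewardConfig(
            qsar=qsar,
            beta=beta,
            sa_weight=cfg.reward.sa_weight,
            floor=cfg.reward.floor,
        )
        result = train_chem(
            mdp,
            pol,
            partition,
            reward,
            start,
            beta=beta,
            rounds=cfg.training.rounds,
            batch=cfg.training.batch,
            max_len=cfg.training.max_len,
            lr=cfg.training.lr,
            partition_lr=cfg.training.partition_lr,
            seed=stage_seed(cfg.seed, "tb-train"),
            explore_eps=cfg.training.explore_eps,
        )
        pool = sample_compounds(
            mdp,
            pol,
            reward,
            [start],
            cfg.sampling.n_trajectories,
            max_len=cfg.training.max_len,
            seed=stage_seed(cfg.seed, "sample"),
        )
        report = summarize(
            [(m, r) for m, r, _, _ in pool],
            reference=reference,
            qsar_threshold=cfg.metrics.qsar_threshold,
            max_pairwise=cfg.metrics.max_pairwise,
            seed=stage_seed(cfg.seed, "metrics"),
        )
        log.info(
            "beta=%g: pool=%d mean reward %.3f diversity %.3f",
            beta,
            report.total,
            report.reward_mean,
            report.diversity_mean_pairwise,
        )
        entries.append(SweepEntry(beta, report, result, pool))
    return entries


@dataclass
class GridVerification:
    beta: float
    tv_distance: float
    logz_error: float
    logz_learned: float
    logz_true: float
    passed: bool


def verify_grid(cfg: RunConfig, betas: list[float] | None = None) -> list[GridVerification]:
    """Train on the enumerable grid and compare against brute force."""
    betas = betas if betas is not None else cfg.grid.betas
    out = []
    for beta in betas:
        grid = build_grid(cfg.grid.side, cfg.grid.dims, cfg.grid.reward_name)
        res = train_grid(
            grid,
            beta=beta,
            n_updates=cfg.grid.n_updates,
            batch=cfg.grid.batch,
            seed=stage_seed(cfg.seed, "grid-train"),
        )
        terminals = sample_grid_terminals(
            grid, res.policy, cfg.grid.n_samples, seed=stage_seed(cfg.seed, "grid-sample")
        )
        tv = total_variation(
            empirical_distribution(grid, terminals), grid.target_distribution(beta)
        )
        lz = log_partition(res.partition, beta)
        lz_true = float(np.log(grid.partition(beta)))
        err = abs(lz - lz_true)
        passed = tv <= cfg.grid.tv_threshold and err <= cfg.grid.logz_threshold
        log.info(
            "grid beta=%g: TV=%.4f logZ err=%.4f (%s)",
            beta,
            tv,
            err,
            "pass" if passed else "FAIL",
        )
        out.append(GridVerification(beta, tv, err, lz, lz_true, passed))
    return out


def write_report(report: MetricsReport, path: Path) -> None:
    path.write_text(json.dumps(report.as_dict(), indent=2) + "\n")
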