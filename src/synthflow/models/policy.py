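"""Graph-convolutional template policy π(a|s).

Stacked graph-convolution → batch-normalization → ReLU blocks over the
molecular graph, sum pooling over atoms, then dense layers and a
softmax over template indices.  Sum pooling makes the output invariant
to atom ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ..chem import Molecule
from ..nn import (
    Adam,
    Linear,
    MaskedBatchNorm,
    Module,
    Tensor,
    cross_entropy_logits,
    log_softmax,
    no_grad,
)

__all__ = ["PolicyConfig", "GCNPolicy", "pretrain_policy", "featurize"]

_ELEMENTS = ["C", "N", "O", "F", "S", "Cl", "Br", "I"]
_N_FEATURES = len(_ELEMENTS) + 1 + 6 + 3 + 5 + 2  # element, other, degree, charge, numH, arom+ring


def featurize(mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
    """Atom feature matrix (n_atoms, F) and symmetric-normalized
    adjacency with self-loops (n_atoms, n_atoms)."""
    rd = mol.rdkit
    n = rd.GetNumAtoms()
    if n == 0:
        raise ValueError(f"cannot featurize a molecule with zero atoms: {mol.smiles!r}")
    x = np.zeros((n, _N_FEATURES))
    for i, atom in enumerate(rd.GetAtoms()):
        sym = atom.GetSymbol()
        x[i, _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
        x[i, len(_ELEMENTS) + 1 + min(atom.GetDegree(), 5)] = 1.0
        charge = int(np.clip(atom.GetFormalCharge(), -1, 1))
        x[i, len(_ELEMENTS) + 7 + charge + 1] = 1.0
        x[i, len(_ELEMENTS) + 10 + min(atom.GetTotalNumHs(), 4)] = 1.0
        x[i, -2] = float(atom.GetIsAromatic())
        x[i, -1] = float(atom.IsInRing())
    adj = np.eye(n)
    for bond in rd.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[a, b] = adj[b, a] = 1.0
    deg = adj.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    return x, adj * dinv[:, None] * dinv[None, :]


@dataclass
class PolicyConfig:
    """GCN hyperparameters; hidden width 256, one convolution block and
    three dense layers with learning rate 4e-4 are the defaults."""

    hidden: int = 256
    conv_layers: int = 1
    dense_layers: int = 3
    lr: float = 4e-4
    batch_size: int = 64
    epochs: int = 20
    holdout_frac: float = 0.1
    topk: tuple[int, ...] = (1, 5, 10)


class GCNPolicy(Module):
    def __init__(self, config: PolicyConfig, n_templates: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_templates = n_templates
        h = config.hidden
        self.conv_w = [
            Linear(rng, _N_FEATURES if i == 0 else h, h, bias=False)
            for i in range(config.conv_layers)
        ]
        self.conv_bn = [MaskedBatchNorm(h) for _ in range(config.conv_layers)]
        dims = [h] * config.dense_layers + [n_templates]
        self.dense = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _features(self, mol: Molecule) -> tuple[np.ndarray, np.ndarray]:
        if mol.smiles not in self._cache:
            self._cache[mol.smiles] = featurize(mol)
        return self._cache[mol.smiles]

    def logits(self, mols: list[Molecule]) -> Tensor:
        """Batched forward pass -> (B, n_templates) unnormalized scores."""
        feats = [self._features(m) for m in mols]
        n_max = max(f[0].shape[0] for f in feats)
        B = len(mols)
        x = np.zeros((B, n_max, _N_FEATURES))
        adj = np.zeros((B, n_max, n_max))
        mask = np.zeros((B, n_max), dtype=bool)
        for i, (xf, af) in enumerate(feats):
            k = xf.shape[0]
            x[i, :k] = xf
            adj[i, :k, :k] = af
            mask[i, :k] = True
        h = Tensor(x)
        adj_t = Tensor(adj)
        mask_f = Tensor(mask[:, :, None].astype(np.float64))
        for w, bn in zip(self.conv_w, self.conv_bn):
            h = adj_t @ w(h)
            h = bn(h, mask).relu() * mask_f  # zero out padded atoms
        pooled = h.sum(axis=1)  # sum pooling over atoms
        for i, layer in enumerate(self.dense):
            pooled = layer(pooled)
            if i < len(self.dense) - 1:
                pooled = pooled.relu()
        return pooled

    def log_probs(
        self, mols: list[Molecule], mask: np.ndarray | None = None
    ) -> Tensor:
        """Log probability vectors over templates, optionally masked to
        the applicable set and renormalized."""
        return log_softmax(self.logits(mols), axis=-1, mask=mask)

    def forward_probs(self, mol: Molecule) -> np.ndarray:
        """Probability vector over all templates for a single molecule."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                p = np.exp(self.log_probs([mol]).data[0])
        finally:
            if was_training:
                self.train()
        return p / p.sum()


@dataclass
class PolicyReport:
    n_train: int
    n_holdout: int
    topk_accuracy: dict[int, float]
    majority_baseline: float
    loss_history: list[float] = field(default_factory=list)


def pretrain_policy(
    model: GCNPolicy,
    data: list[tuple[Molecule, int]],
    config: PolicyConfig | None = None,
    seed: int = 0,
) -> PolicyReport:
    """Cross-entropy training on (molecule, template index) pairs with a
    held-out split; reports top-k accuracies and the majority-class
    baseline computed from the held-out label frequencies."""
    if not data:
        raise ValueError("training data is empty")
    cfg = config or model.config
    for _, label in data:
        if not 0 <= label < model.n_templates:
            raise ValueError(
                f"label {label} outside template range [0, {model.n_templates})"
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_hold = int(round(len(data) * cfg.holdout_frac))
    hold = [data[i] for i in order[:n_hold]]
    train = [data[i] for i in order[n_hold:]]
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=5.0)
    history: list[float] = []
    model.train()
    for _ in range(cfg.epochs):
        perm = rng.permutation(len(train))
        total, nb = 0.0, 0
        for start in range(0, len(train), cfg.batch_size):
            batch = [train[i] for i in perm[start : start + cfg.batch_size]]
            mols = [m for m, _ in batch]
            labels = np.array([y for _, y in batch])
            loss = cross_entropy_logits(model.logits(mols), labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1
        history.append(total / max(nb, 1))
    model.eval()
    eval_set = hold if hold else train
    with no_grad():
        logits = model.logits([m for m, _ in eval_set]).data
    labels = np.array([y for _, y in eval_set])
    ranks = np.argsort(-logits, axis=1)
    topk = {}
    for k in cfg.topk:
        hits = (ranks[:, :k] == labels[:, None]).any(axis=1)
        topk[k] = float(hits.mean())
    counts = np.bincount(labels, minlength=model.n_templates)
    majority = float(counts.max() / counts.sum())
    return PolicyReport(
        n_train=len(train),
        n_holdout=len(hold),
        topk_accuracy=topk,
        majority_baseline=majority,
        loss_history=history,
    )


def save_policy(model: GCNPolicy, path) -> None:
    """Self-describing checkpoint: architecture spec + parameters +
    batch-norm running statistics."""
    import json

    meta = {
        "kind": "gcn_policy",
        "n_templates": model.n_templates,
        "hidden": model.config.hidden,
        "conv_layers": model.config.conv_layers,
        "dense_layers": model.config.dense_layers,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    for i, bn in enumerate(model.conv_bn):
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_policy(path) -> GCNPolicy:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("kind") != "gcn_policy":
            raise ValueError(f"{path} is not a policy checkpoint")
        cfg = PolicyConfig(
            hidden=meta["hidden"],
            conv_layers=meta["conv_layers"],
            dense_layers=meta["dense_layers"],
        )
        model = GCNPolicy(cfg, meta["n_templates"])
        n_params = len(model.parameters())
        model.load_state_arrays([archive[f"p{i}"] for i in range(n_params)])
        for i, bn in enumerate(model.conv_bn):
            bn.running_mean = archive[f"bn{i}_mean"]
            bn.running_var = archive[f"bn{i}_var"]
    model.eval()
    return model
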