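"""Conditional sequence-to-sequence transition model.

A small encoder–decoder transformer maps ``<RXN_a>`` + reactant SMILES
tokens to product SMILES tokens, defining the learned transition
T(s'|s, a) of the synthesis MDP.  Beam-search candidates are
canonicalized, deduplicated, and their sequence likelihoods are
renormalized over the surviving valid candidates, which is what makes
the transition a proper probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chem import Molecule, SmilesParseError, Vocabulary, canonicalize, detokenize, tokenize
from ..fixtures import ReactionTriple
from ..nn import (
    Adam,
    Dropout,
    Embedding,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    cross_entropy_logits,
    log_softmax,
    no_grad,
    softmax,
)

__all__ = [
    "TransitionConfig",
    "TransitionTransformer",
    "pretrain_transition",
    "transition_candidates",
]


@dataclass
class TransitionConfig:
    """Architecture and training knobs (desk-scale defaults)."""

    dim: int = 64
    heads: int = 4
    enc_layers: int = 2
    dec_layers: int = 2
    ff_dim: int = 128
    dropout: float = 0.1
    max_len: int = 72
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    holdout_frac: float = 0.1


class _MultiHeadAttention(Module):
    def __init__(self, rng, dim: int, heads: int):
        assert dim % heads == 0
        self.heads = heads
        self.dh = dim // heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def __call__(self, q: Tensor, kv: Tensor, penalty: np.ndarray) -> Tensor:
        # q: (B, Lq, D); kv: (B, Lk, D); penalty additive (B, 1, Lq, Lk)
        B, Lq, D = q.shape
        Lk = kv.shape[1]

        def split(x: Tensor, L: int) -> Tensor:
            return x.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

        qh = split(self.wq(q), Lq)
        kh = split(self.wk(kv), Lk)
        vh = split(self.wv(kv), Lk)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        scores = scores + Tensor(penalty)
        attn = softmax(scores, axis=-1)
        out = attn @ vh  # (B, h, Lq, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.wo(out)


class _FeedForward(Module):
    def __init__(self, rng, dim: int, ff_dim: int):
        self.l1 = Linear(rng, dim, ff_dim)
        self.l2 = Linear(rng, ff_dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())


class _EncoderBlock(Module):
    def __init__(self, rng, dim, heads, ff_dim, dropout_p, drop_rng):
        self.ln1 = LayerNorm(dim)
        self.attn = _MultiHeadAttention(rng, dim, heads)
        self.ln2 = LayerNorm(dim)
        self.ff = _FeedForward(rng, dim, ff_dim)
        self.drop = Dropout(dropout_p, drop_rng)

    def __call__(self, x: Tensor, penalty: np.ndarray) -> Tensor:
        h = self.ln1(x)
        x = x + self.drop(self.attn(h, h, penalty))
        x = x + self.drop(self.ff(self.ln2(x)))
        return x


class _DecoderBlock(Module):
    def __init__(self, rng, dim, heads, ff_dim, dropout_p, drop_rng):
        self.ln1 = LayerNorm(dim)
        self.self_attn = _MultiHeadAttention(rng, dim, heads)
        self.ln2 = LayerNorm(dim)
        self.cross_attn = _MultiHeadAttention(rng, dim, heads)
        self.ln3 = LayerNorm(dim)
        self.ff = _FeedForward(rng, dim, ff_dim)
        self.drop = Dropout(dropout_p, drop_rng)

    def __call__(self, x, memory, self_penalty, cross_penalty) -> Tensor:
        h = self.ln1(x)
        x = x + self.drop(self.self_attn(h, h, self_penalty))
        x = x + self.drop(self.cross_attn(self.ln2(x), memory, cross_penalty))
        x = x + self.drop(self.ff(self.ln3(x)))
        return x


def _pad_penalty(valid: np.ndarray) -> np.ndarray:
    """(B, Lk) boolean -> additive penalty (B, 1, 1, Lk)."""
    return np.where(valid, 0.0, -1e9)[:, None, None, :]


def _causal_penalty(L: int) -> np.ndarray:
    return np.where(np.tril(np.ones((L, L), bool)), 0.0, -1e9)[None, None]


class TransitionTransformer(Module):
    """Encoder–decoder over SMILES token sequences with condition tokens."""

    def __init__(self, config: TransitionConfig, vocab: Vocabulary, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        dim = config.dim
        self.drop_rng = np.random.default_rng(seed + 1)
        self.tok_emb = Embedding(rng, len(vocab), dim)
        self.pos_emb = Embedding(rng, config.max_len, dim)
        self.encoder = [
            _EncoderBlock(rng, dim, config.heads, config.ff_dim, config.dropout, self.drop_rng)
            for _ in range(config.enc_layers)
        ]
        self.decoder = [
            _DecoderBlock(rng, dim, config.heads, config.ff_dim, config.dropout, self.drop_rng)
            for _ in range(config.dec_layers)
        ]
        self.enc_ln = LayerNorm(dim)
        self.dec_ln = LayerNorm(dim)
        self.out = Linear(rng, dim, len(vocab))

    # -- encoding ------------------------------------------------------
    def _embed(self, ids: np.ndarray) -> Tensor:
        L = ids.shape[1]
        if L > self.config.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.config.max_len}")
        return self.tok_emb(ids) + self.pos_emb(np.arange(L))

    def encode(self, src: np.ndarray, src_valid: np.ndarray) -> Tensor:
        x = self._embed(src)
        penalty = _pad_penalty(src_valid)
        for block in self.encoder:
            x = block(x, penalty)
        return self.enc_ln(x)

    def decode_logits(
        self,
        memory: Tensor,
        src_valid: np.ndarray,
        tgt_in: np.ndarray,
    ) -> Tensor:
        x = self._embed(tgt_in)
        self_pen = _causal_penalty(tgt_in.shape[1])
        cross_pen = _pad_penalty(src_valid)
        for block in self.decoder:
            x = block(x, memory, self_pen, cross_pen)
        return self.out(self.dec_ln(x))

    # -- data preparation ----------------------------------------------
    def encode_pair(self, reactant: str, template_index: int, product: str):
        src = self.vocab.encode(tokenize(reactant, condition=template_index))
        tgt = self.vocab.encode(tokenize(product))
        return src, [self.vocab.bos_id] + tgt + [self.vocab.eos_id]

    def _batch(self, seqs: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
        L = max(len(s) for s in seqs)
        pad = self.vocab.pad_id
        ids = np.full((len(seqs), L), pad, dtype=np.int64)
        valid = np.zeros((len(seqs), L), dtype=bool)
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            valid[i, : len(s)] = True
        return ids, valid

    def step_loss(self, pairs: list[tuple[list[int], list[int]]]) -> Tensor:
        """Teacher-forced mean cross-entropy over a batch of (src, tgt)."""
        src, src_valid = self._batch([p[0] for p in pairs])
        tgt, tgt_valid = self._batch([p[1] for p in pairs])
        memory = self.encode(src, src_valid)
        logits = self.decode_logits(memory, src_valid, tgt[:, :-1])
        return cross_entropy_logits(logits, tgt[:, 1:], tgt_valid[:, 1:])

    # -- decoding ------------------------------------------------------
    def beam_decode(
        self, reactant: str, template_index: int, beam: int
    ) -> list[tuple[list[int], float]]:
        """Deterministic beam search; returns (token ids, log-likelihood)
        for each finished hypothesis, best first."""
        if beam < 1:
            raise ValueError("beam must be >= 1")
        with no_grad():
            src_ids = self.vocab.encode(tokenize(reactant, condition=template_index))
            src = np.asarray([src_ids], dtype=np.int64)
            src_valid = np.ones_like(src, dtype=bool)
            memory = self.encode(src, src_valid)
            mem_data = memory.data
            live: list[tuple[list[int], float]] = [([self.vocab.bos_id], 0.0)]
            done: list[tuple[list[int], float]] = []
            max_steps = self.config.max_len - 1
            for _ in range(max_steps):
                if not live:
                    break
                tgt, _ = self._batch([seq for seq, _ in live])
                mem = Tensor(np.repeat(mem_data, len(live), axis=0))
                sv = np.repeat(src_valid, len(live), axis=0)
                logits = self.decode_logits(mem, sv, tgt)
                logp = log_softmax(logits, axis=-1).data
                expansions: list[tuple[float, list[int]]] = []
                for i, (seq, score) in enumerate(live):
                    step_lp = logp[i, len(seq) - 1]
                    # top candidates suffice; ties broken by token id
                    order = np.argsort(-step_lp, kind="stable")[: beam + 1]
                    for tok in order:
                        expansions.append((score + float(step_lp[tok]), seq + [int(tok)]))
                expansions.sort(key=lambda e: (-e[0], e[1]))
                live = []
                for score, seq in expansions:
                    if seq[-1] == self.vocab.eos_id:
                        done.append((seq[1:-1], score))
                    elif len(live) < beam:
                        live.append((seq, score))
                # keep only the best `beam` finished hypotheses, and stop
                # once no live hypothesis can still improve on them
                done.sort(key=lambda e: (-e[1], e[0]))
                done = done[:beam]
                if not live:
                    break
                best_live = live[0][1]
                if len(done) >= beam and best_live <= done[-1][1]:
                    break
            done.sort(key=lambda e: (-e[1], e[0]))
            return done[:beam]

    def greedy_decode(self, reactant: str, template_index: int) -> str | None:
        """Greedy product prediction; None when decoding fails to produce
        a parseable SMILES."""
        hyps = self.beam_decode(reactant, template_index, beam=1)
        if not hyps:
            return None
        smiles = detokenize(self.vocab.decode(hyps[0][0]))
        try:
            return canonicalize(smiles)
        except SmilesParseError:
            return None


def transition_candidates(
    model: TransitionTransformer,
    mol: Molecule,
    template_index: int,
    beam: int,
) -> list[tuple[Molecule, float]]:
    """Valid, deduplicated beam candidates with renormalized likelihoods.

    The probability attached to each candidate molecule is its sequence
    likelihood renormalized over the surviving candidates; this defines
    the learned transition probability used in the trajectory-balance
    product.  Empty when no candidate parses.
    """
    n_rxn_tokens = sum(1 for t in model.vocab.tokens if t.startswith("<RXN_"))
    if not 0 <= template_index < n_rxn_tokens:
        raise IndexError(
            f"template index {template_index} outside library range "
            f"[0, {n_rxn_tokens})"
        )
    hyps = model.beam_decode(mol.smiles, template_index, beam)
    scored: dict[str, float] = {}
    for ids, loglik in hyps:
        smiles = detokenize(model.vocab.decode(ids))
        try:
            can = canonicalize(smiles)
        except SmilesParseError:
            continue
        # keep the highest-likelihood sequence realizing each molecule
        if can not in scored or loglik > scored[can]:
            scored[can] = loglik
    if not scored:
        return []
    items = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    logs = np.array([v for _, v in items])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return [(Molecule(s), float(p)) for (s, _), p in zip(items, probs)]


@dataclass
class TransitionReport:
    n_train: int
    n_holdout: int
    exact_match_holdout: float
    loss_history: list[float] = field(default_factory=list)


def pretrain_transition(
    model: TransitionTransformer,
    triples: list[ReactionTriple],
    config: TransitionConfig | None = None,
    seed: int = 0,
) -> TransitionReport:
    """Teacher-forced cross-entropy training on condition-token pairs;
    reports greedy-decode exact-match accuracy on a held-out split."""
    if not triples:
        raise ValueError("training data is empty")
    cfg = config or model.config
    for tok in {f"<RXN_{t.template_index}>" for t in triples}:
        if tok not in model.vocab.index:
            raise ValueError(f"vocabulary missing condition token {tok}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(triples))
    n_hold = int(round(len(triples) * cfg.holdout_frac))
    hold_idx = order[:n_hold]
    train_idx = order[n_hold:]
    pairs = [
        model.encode_pair(t.reactant.smiles, t.template_index, t.product.smiles)
        for t in triples
    ]
    train_pairs = [pairs[i] for i in train_idx]
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=5.0)
    history: list[float] = []
    model.train()
    for _ in range(cfg.epochs):
        perm = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(train_pairs), cfg.batch_size):
            batch = [train_pairs[i] for i in perm[start : start + cfg.batch_size]]
            loss = model.step_loss(batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    model.eval()
    n_match = 0
    for i in hold_idx:
        t = triples[i]
        pred = model.greedy_decode(t.reactant.smiles, t.template_index)
        if pred == t.product.smiles:
            n_match += 1
    em = n_match / max(len(hold_idx), 1)
    return TransitionReport(
        n_train=len(train_idx),
        n_holdout=len(hold_idx),
        exact_match_holdout=em,
        loss_history=history,
    )


def save_transition(model: TransitionTransformer, path) -> None:
    """Checkpoint with architecture spec, vocabulary, and its hash."""
    import json
    from dataclasses import asdict

    meta = {
        "kind": "transition_transformer",
        "config": asdict(model.config),
        "vocab_hash": model.vocab.content_hash(),
        "vocab_tokens": model.vocab.tokens,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_transition(path, vocab: Vocabulary | None = None) -> TransitionTransformer:
    """Restore a checkpoint; if ``vocab`` is given its hash must match
    the stored one."""
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("kind") != "transition_transformer":
            raise ValueError(f"{path} is not a transition checkpoint")
        stored = Vocabulary(meta["vocab_tokens"])
        if vocab is not None and vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError(
                "vocabulary mismatch: checkpoint hash "
                f"{meta['vocab_hash']} != {vocab.content_hash()}"
            )
        cfg = TransitionConfig(**meta["config"])
        model = TransitionTransformer(cfg, stored)
        n_params = len(model.parameters())
        model.load_state_arrays([archive[f"p{i}"] for i in range(n_params)])
    model.eval()
    return model
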