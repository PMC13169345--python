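"""Policy, transition, and partition models."""

import numpy as np
import pytest
from rdkit import Chem

from synthflow.chem import Molecule, Vocabulary
from synthflow.models.partition import (
    PartitionMLP,
    load_partition,
    log_partition,
    save_partition,
)
from synthflow.models.policy import (
    GCNPolicy,
    PolicyConfig,
    load_policy,
    pretrain_policy,
    save_policy,
)
from synthflow.models.transition import (
    TransitionConfig,
    TransitionTransformer,
    load_transition,
    pretrain_transition,
    save_transition,
    transition_candidates,
)


@pytest.fixture(scope="module")
def tiny_policy(library):
    return GCNPolicy(PolicyConfig(hidden=32, epochs=5), library.size, seed=0)


@pytest.fixture(scope="module")
def trained_transition(library, triples_small, vocab):
    cfg = TransitionConfig(dim=32, ff_dim=64, epochs=12, batch_size=32)
    model = TransitionTransformer(cfg, vocab, seed=0)
    report = pretrain_transition(model, triples_small, cfg, seed=0)
    return model, report


class TestPolicy:
    def test_output_is_probability_vector(self, tiny_policy, blocks):
        p = tiny_policy.forward_probs(blocks[0])
        assert p.shape == (10,)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-6

    def test_permutation_invariance_via_sum_pooling(self, tiny_policy):
        m = Molecule.from_smiles("COc1ccc(CN(C)C)cc1")
        rd = m.rdkit
        perm = [int(i) for i in np.random.default_rng(3).permutation(rd.GetNumAtoms())]
        renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(rd, perm), canonical=False)
        p1 = tiny_policy.forward_probs(m)
        p2 = tiny_policy.forward_probs(Molecule(renumbered))
        assert np.abs(p1 - p2).max() < 1e-5

    def test_zero_atom_molecule_rejected(self, tiny_policy):
        with pytest.raises(ValueError, match="zero atoms"):
            tiny_policy.forward_probs(Molecule(""))

    def test_memorizes_twenty_pairs(self, library, blocks):
        data = []
        seen = set()
        for b in blocks:
            from synthflow.templates import enumerate_applicable

            app = enumerate_applicable(library, b)
            if app and b.smiles not in seen:
                data.append((b, app[0]))
                seen.add(b.smiles)
            if len(data) == 20:
                break
        cfg = PolicyConfig(hidden=64, epochs=150, lr=3e-3, holdout_frac=0.0)
        model = GCNPolicy(cfg, library.size, seed=1)
        pretrain_policy(model, data, cfg, seed=1)
        for mol, label in data:
            assert int(np.argmax(model.forward_probs(mol))) == label

    def test_topk_accuracies_are_nested(self, library, triples_small):
        cfg = PolicyConfig(hidden=32, epochs=3)
        model = GCNPolicy(cfg, library.size, seed=0)
        report = pretrain_policy(
            model, [(t.reactant, t.template_index) for t in triples_small], cfg, seed=0
        )
        acc = report.topk_accuracy
        assert acc[1] <= acc[5] <= acc[10] <= 1.0

    def test_single_class_dataset_reaches_full_accuracy(self, library, blocks):
        data = [(b, 3) for b in blocks[:30]]
        cfg = PolicyConfig(hidden=32, epochs=60, lr=3e-3)
        model = GCNPolicy(cfg, library.size, seed=0)
        report = pretrain_policy(model, data, cfg, seed=0)
        assert report.topk_accuracy[1] == 1.0

    def test_label_out_of_range_rejected(self, library, blocks):
        model = GCNPolicy(PolicyConfig(hidden=16, epochs=1), library.size)
        with pytest.raises(ValueError, match="outside template range"):
            pretrain_policy(model, [(blocks[0], 99)])

    def test_checkpoint_round_trip(self, tiny_policy, blocks, tmp_path):
        save_policy(tiny_policy, tmp_path / "p.npz")
        loaded = load_policy(tmp_path / "p.npz")
        assert np.allclose(
            tiny_policy.forward_probs(blocks[0]), loaded.forward_probs(blocks[0])
        )


class TestTransition:
    def test_loss_decreases_over_training(self, trained_transition):
        _, report = trained_transition
        assert report.loss_history[-1] < report.loss_history[0]

    def test_candidates_renormalize(self, trained_transition, triples_small):
        model, _ = trained_transition
        t = triples_small[0]
        cands = transition_candidates(model, t.reactant, t.template_index, beam=5)
        if cands:
            assert abs(sum(p for _, p in cands) - 1.0) < 1e-6
            for m, p in cands:
                assert 0.0 <= p <= 1.0
                assert Molecule.from_smiles(m.smiles) == m

    def test_beam_one_gives_at_most_one_candidate(self, trained_transition, triples_small):
        model, _ = trained_transition
        t = triples_small[1]
        cands = transition_candidates(model, t.reactant, t.template_index, beam=1)
        assert len(cands) <= 1
        if cands:
            assert cands[0][1] == 1.0

    def test_decoding_is_deterministic(self, trained_transition, triples_small):
        model, _ = trained_transition
        t = triples_small[2]
        a = transition_candidates(model, t.reactant, t.template_index, beam=6)
        b = transition_candidates(model, t.reactant, t.template_index, beam=6)
        assert [(m.smiles, p) for m, p in a] == [(m.smiles, p) for m, p in b]

    def test_template_index_out_of_range(self, trained_transition, triples_small):
        model, _ = trained_transition
        with pytest.raises(IndexError, match="outside library range"):
            transition_candidates(model, triples_small[0].reactant, 99, beam=2)

    def test_duplicate_only_dataset_memorized(self, library, vocab, triples_small):
        cfg = TransitionConfig(dim=32, ff_dim=64, epochs=40, batch_size=8, holdout_frac=0.2)
        model = TransitionTransformer(cfg, vocab, seed=0)
        data = [triples_small[0]] * 20
        report = pretrain_transition(model, data, cfg, seed=0)
        assert report.exact_match_holdout == 1.0

    def test_checkpoint_round_trip_and_vocab_guard(
        self, trained_transition, vocab, triples_small, tmp_path
    ):
        model, _ = trained_transition
        save_transition(model, tmp_path / "t.npz")
        loaded = load_transition(tmp_path / "t.npz", vocab=vocab)
        t = triples_small[3]
        assert loaded.greedy_decode(t.reactant.smiles, t.template_index) == (
            model.greedy_decode(t.reactant.smiles, t.template_index)
        )
        other = Vocabulary.build(["CCOBr"], 2)
        with pytest.raises(ValueError, match="vocabulary mismatch"):
            load_transition(tmp_path / "t.npz", vocab=other)


class TestPartition:
    def test_finite_over_the_temperature_range(self):
        z = PartitionMLP(hidden=16, seed=0)
        for beta in (1.0, 8.0, 16.0, 32.0):
            assert np.isfinite(log_partition(z, beta))

    def test_gradient_nonzero_at_initialization(self):
        z = PartitionMLP(hidden=16, seed=0)
        out = z(4.0).reshape(())
        out.backward()
        total = sum(float(np.abs(p.grad).sum()) for p in z.parameters())
        assert total > 0

    def test_invalid_beta_rejected(self):
        z = PartitionMLP(hidden=16)
        with pytest.raises(ValueError):
            z(-1.0)

    def test_unknown_encoding_rejected(self):
        with pytest.raises(ValueError, match="encoding"):
            PartitionMLP(encoding="fourier")

    def test_checkpoint_round_trip(self, tmp_path):
        z = PartitionMLP(hidden=16, seed=5)
        save_partition(z, tmp_path / "z.npz")
        loaded = load_partition(tmp_path / "z.npz")
        assert log_partition(z, 3.0) == log_partition(loaded, 3.0)
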