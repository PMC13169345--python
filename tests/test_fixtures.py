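"""Synthetic-data generators and the enumerable grid environment."""

import numpy as np
import pytest
from rdkit import Chem

from synthflow.chem import Molecule, canonicalize
from synthflow.fixtures import (
    PLANTED_PHARMACOPHORE,
    default_template_library,
    generate_activity_corpus,
    generate_building_blocks,
    generate_reaction_dataset,
    load_smiles,
    load_triples,
    planted_activity_labels,
    save_smiles,
    save_triples,
)
from synthflow.grid import build_grid, REWARD_REGISTRY
from synthflow.templates import (
    ReactionTemplate,
    TemplateLibrary,
    apply_template,
    enumerate_applicable,
)


class TestBuildingBlocks:
    def test_deterministic_given_seed(self):
        assert [m.smiles for m in generate_building_blocks(1, 50)] == [
            m.smiles for m in generate_building_blocks(1, 50)
        ]

    def test_different_seeds_differ(self):
        a = [m.smiles for m in generate_building_blocks(1, 100)]
        b = [m.smiles for m in generate_building_blocks(2, 100)]
        assert a != b

    def test_all_blocks_canonicalize_and_are_distinct(self, blocks):
        smiles = [m.smiles for m in blocks]
        assert len(set(smiles)) == len(smiles)
        for s in smiles:
            assert canonicalize(s) == s

    def test_every_template_covered(self, library, blocks):
        covered = set()
        for b in blocks:
            covered.update(enumerate_applicable(library, b))
        assert covered == set(range(library.size))

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="combinatorial space"):
            generate_building_blocks(1, 10_000)

    def test_no_block_contains_the_pharmacophore(self):
        pattern = Chem.MolFromSmarts(PLANTED_PHARMACOPHORE)
        for m in generate_building_blocks(1, 250):
            assert not m.rdkit.HasSubstructMatch(pattern)


class TestReactionDataset:
    def test_every_triple_revalidates_through_the_engine(
        self, library, triples_small
    ):
        for t in triples_small:
            products = apply_template(library[t.template_index], t.reactant)
            assert t.product in products

    def test_deterministic_file_output(self, library, blocks, tmp_path):
        a = generate_reaction_dataset(library, blocks, 50, seed=9)
        b = generate_reaction_dataset(library, blocks, 50, seed=9)
        save_triples(a, tmp_path / "a.tsv")
        save_triples(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_degenerate_single_outcome_library(self):
        lib = TemplateLibrary(
            [ReactionTemplate(0, "[NX3+:1](=[OX1:2])[O-]>>[NX3;H2;+0:1]")]
        )
        block = [Molecule.from_smiles("O=[N+]([O-])c1ccccc1")]
        triples = generate_reaction_dataset(lib, block, 10, seed=0)
        assert len({(t.reactant, t.template_index, t.product) for t in triples}) == 1

    def test_round_trip_files(self, triples_small, tmp_path):
        save_triples(triples_small[:20], tmp_path / "t.tsv")
        loaded = load_triples(tmp_path / "t.tsv")
        assert loaded == triples_small[:20]

    def test_smiles_file_round_trip(self, blocks, tmp_path):
        save_smiles(blocks[:10], tmp_path / "b.smi")
        assert load_smiles(tmp_path / "b.smi") == blocks[:10]


class TestPlantedLabels:
    def test_noiseless_labels_equal_substructure_matches(self, blocks):
        pattern = Chem.MolFromSmarts(PLANTED_PHARMACOPHORE)
        labels = planted_activity_labels(blocks, flip_prob=0.0)
        for m, y in zip(blocks, labels):
            assert y == int(m.rdkit.HasSubstructMatch(pattern))

    def test_empty_input(self):
        assert planted_activity_labels([]) == []

    def test_flip_fraction_within_three_standard_errors(self, library):
        blocks = generate_building_blocks(3, 150)
        corpus = generate_activity_corpus(library, blocks, 1000, seed=5)
        clean = planted_activity_labels(corpus, flip_prob=0.0)
        noisy = planted_activity_labels(corpus, flip_prob=0.1, seed=6)
        flipped = np.mean(np.array(clean) != np.array(noisy))
        se = np.sqrt(0.1 * 0.9 / len(corpus))
        assert abs(flipped - 0.1) < 3 * se

    def test_invalid_pattern_and_flip_prob(self, blocks):
        with pytest.raises(ValueError, match="SMARTS"):
            planted_activity_labels(blocks[:2], pharmacophore="][")
        with pytest.raises(ValueError, match="flip_prob"):
            planted_activity_labels(blocks[:2], flip_prob=0.7)

    def test_corpus_is_distinct_valid_and_reproducible(self, library, blocks):
        corpus = generate_activity_corpus(library, blocks, 300, seed=5)
        again = generate_activity_corpus(library, blocks, 300, seed=5)
        assert corpus == again
        smiles = [m.smiles for m in corpus]
        assert len(set(smiles)) == len(smiles)


class TestGrid:
    def test_unknown_reward_rejected(self):
        with pytest.raises(KeyError, match="unknown reward"):
            build_grid(4, 2, "no-such-reward")

    def test_side_minimum(self):
        with pytest.raises(ValueError):
            build_grid(1, 2, "constant")

    def test_constant_reward_target_is_uniform(self):
        grid = build_grid(2, 2, "constant")
        target = grid.target_distribution(beta=1.0)
        assert np.allclose(target, 0.25)
        assert grid.partition(1.0) == 4.0

    def test_interior_parent_count(self):
        grid = build_grid(8, 2, "corners")
        assert grid.parent_count(np.array([3, 4])) == 2
        assert grid.parent_count(np.array([0, 4])) == 1
        assert grid.parent_count(np.array([0, 0])) == 1  # root convention

    def test_partition_matches_exhaustive_double_loop(self):
        grid = build_grid(8, 2, "corners")
        z = 0.0
        for i in range(8):
            for j in range(8):
                z += float(grid.reward_fn(np.array([[i, j]]))[0]) ** 2
        assert np.isclose(grid.partition(2.0), z, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("name", sorted(REWARD_REGISTRY))
    @pytest.mark.parametrize("beta", [1.0, 2.0, 8.0])
    def test_target_distribution_normalizes(self, name, beta):
        grid = build_grid(8, 2, name)
        target = grid.target_distribution(beta)
        assert np.isclose(target.sum(), 1.0)
        assert (target > 0).all()

    def test_valid_actions_and_step(self):
        grid = build_grid(3, 2, "constant")
        edge = np.array([2, 1])
        mask = grid.valid_actions(edge)
        assert not mask[0] and mask[1] and mask[2]  # x at boundary, stop allowed
        assert tuple(grid.step(edge, 1)) == (2, 2)
        with pytest.raises(ValueError):
            grid.step(edge, 0)
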