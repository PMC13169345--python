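"""Trajectory sampling, the trajectory-balance loss, and training loops."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synthflow.chem import Molecule
from synthflow.fixtures import default_template_library
from synthflow.gflownet import (
    TBLossInputs,
    Trajectory,
    empirical_distribution,
    sample_compounds,
    sample_grid_terminals,
    sample_trajectory,
    tb_loss,
    total_variation,
    train_chem,
    train_grid,
)
from synthflow.grid import build_grid
from synthflow.mdp import ReactionMDP
from synthflow.models.partition import PartitionMLP, log_partition
from synthflow.models.policy import GCNPolicy, PolicyConfig
from synthflow.templates import ReactionTemplate, TemplateLibrary


class TestTBLoss:
    def test_balanced_assignment_is_exactly_zero(self):
        inputs = TBLossInputs(
            log_forward=-1.7,
            log_backward=-0.4,
            log_partition=3.0 * np.log(0.6) + (-0.4) - (-1.7),
            log_reward=np.log(0.6),
            beta=3.0,
        )
        # analytically balanced; the only residual is one rounding ulp
        assert tb_loss(inputs) <= 1e-30

    def test_worked_single_step_case(self):
        # P_F = P_B = 1, R = 0.5, beta = 2, Z = 0.25: log 0.25 = 2 log 0.5
        inputs = TBLossInputs(
            log_forward=0.0,
            log_backward=0.0,
            log_partition=np.log(0.25),
            log_reward=np.log(0.5),
            beta=2.0,
        )
        assert tb_loss(inputs) == 0.0

    @given(
        st.floats(-10, 0),
        st.floats(-10, 0),
        st.floats(-20, 20),
        st.floats(-10, -0.01),
        st.floats(0.1, 32),
    )
    def test_nonnegative(self, lf, lb, lz, lr, beta):
        assert tb_loss(TBLossInputs(lf, lb, lz, lr, beta)) >= 0.0

    def test_nonfinite_input_named(self):
        with pytest.raises(ValueError, match="log_forward"):
            TBLossInputs(np.inf, 0.0, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError, match="log_reward"):
            TBLossInputs(0.0, 0.0, 0.0, np.nan, 1.0)


class TestTrajectoryContainer:
    def test_shape_mismatch_rejected(self):
        m = Molecule.from_smiles("CCO")
        with pytest.raises(ValueError, match="shape mismatch"):
            Trajectory([m, m], [0, 1], [-0.5], reward=1.0)

    def test_nonpositive_reward_rejected(self):
        m = Molecule.from_smiles("CCO")
        with pytest.raises(ValueError, match="reward"):
            Trajectory([m], [], [], reward=0.0)

    def test_log_forward_sums_step_logprobs(self):
        m = Molecule.from_smiles("CCO")
        t = Trajectory([m, m, m], [0, 0], [-0.5, -0.25], reward=0.5)
        assert t.log_forward == -0.75
        assert t.length == 2
        assert t.terminal == m


@pytest.fixture(scope="module")
def untrained_chem_env():
    lib = default_template_library()
    mdp = ReactionMDP(lib, max_depth=4)
    policy = GCNPolicy(PolicyConfig(hidden=32, epochs=1), lib.size, seed=0)
    policy.eval()
    return mdp, policy


class TestSampleTrajectory:

    def test_length_bounded_and_logprobs_nonpositive(self, untrained_chem_env, rng):
        mdp, policy = untrained_chem_env
        start = Molecule.from_smiles("NCc1ccc(C=O)cc1")
        for _ in range(10):
            t = sample_trajectory(mdp, policy, start, lambda m: 0.5, max_len=3, rng=rng)
            assert t.length <= 3
            assert all(lp <= 0 for lp in t.step_logprobs)
            assert t.states[0] == start

    def test_deterministic_single_template_chain_has_zero_logprobs(self, rng):
        lib = TemplateLibrary(
            [ReactionTemplate(0, "[NX3+:1](=[OX1:2])[O-]>>[NX3;H2;+0:1]")]
        )
        mdp = ReactionMDP(lib, max_depth=3)
        policy = GCNPolicy(PolicyConfig(hidden=16, epochs=1), lib.size, seed=0)
        policy.eval()
        # single nitro group -> one applicable template with one product
        start = Molecule.from_smiles("O=[N+]([O-])c1ccccc1")
        t = sample_trajectory(mdp, policy, start, lambda m: 1.0, max_len=3, rng=rng)
        assert t.length >= 1
        assert all(lp == 0.0 for lp in t.step_logprobs)

    def test_start_without_applicable_templates_gives_degenerate(self, untrained_chem_env, rng):
        mdp, policy = untrained_chem_env
        t = sample_trajectory(
            mdp, policy, Molecule.from_smiles("C"), lambda m: 0.3, max_len=3, rng=rng
        )
        assert t.length == 0
        assert t.reward == 0.3


class TestGridTraining:
    def test_two_by_two_constant_grid_recovers_uniform_and_log4(self):
        """The smallest verification: uniform target and Z = 4."""
        grid = build_grid(2, 2, "constant")
        res = train_grid(grid, beta=1.0, n_updates=700, batch=32, seed=0)
        terms = sample_grid_terminals(grid, res.policy, 4000, seed=1)
        tv = total_variation(
            empirical_distribution(grid, terms), grid.target_distribution(1.0)
        )
        assert tv <= 0.02
        assert abs(log_partition(res.partition, 1.0) - np.log(4.0)) <= 0.1

    def test_loss_decreases_and_history_has_one_entry_per_update(self):
        grid = build_grid(8, 2, "corners")
        res = train_grid(grid, beta=1.0, n_updates=300, batch=16, seed=0)
        assert len(res.loss_history) == 300
        first = np.mean(res.loss_history[:30])
        last = np.mean(res.loss_history[-30:])
        assert last < first

    def test_reproducible_given_seed(self):
        grid = build_grid(4, 2, "cosine")
        a = train_grid(grid, beta=1.0, n_updates=50, batch=8, seed=5)
        b = train_grid(grid, beta=1.0, n_updates=50, batch=8, seed=5)
        assert a.loss_history == b.loss_history


@pytest.fixture(scope="module")
def chem_train_setup(library):
    mdp = ReactionMDP(library, max_depth=3)
    policy = GCNPolicy(PolicyConfig(hidden=32, epochs=1), library.size, seed=0)
    partition = PartitionMLP(hidden=16, seed=1)
    reward = lambda m: 0.2 + 0.6 * ("N" in m.smiles)
    start = Molecule.from_smiles("O=Cc1ccc(C(=O)O)cc1")
    return mdp, policy, partition, reward, start


class TestChemTraining:

    def test_history_and_pool_bookkeeping(self, chem_train_setup):
        mdp, policy, partition, reward, start = chem_train_setup
        res = train_chem(
            mdp, policy, partition, reward, start,
            beta=1.0, rounds=5, batch=4, max_len=3, seed=0,
        )
        assert len(res.history) == 5
        for h in res.history:
            assert np.isfinite(h["loss"])
            assert 0 < h["mean_reward"] <= 1.0
            assert 0 <= h["mean_length"] <= 3
        assert len(res.pool) <= 5 * 4 * 3
        for mol, r, tid, step in res.pool:
            assert r > 0 and step >= 1

    def test_identical_seeds_reproduce_history_and_pool(self, library):
        def run():
            mdp = ReactionMDP(library, max_depth=3)
            policy = GCNPolicy(PolicyConfig(hidden=16, epochs=1), library.size, seed=2)
            partition = PartitionMLP(hidden=16, seed=3)
            return train_chem(
                mdp, policy, partition, lambda m: 0.5,
                Molecule.from_smiles("NCc1ccccc1"),
                beta=2.0, rounds=4, batch=4, max_len=3, seed=9,
            )

        a, b = run(), run()
        assert [h["loss"] for h in a.history] == [h["loss"] for h in b.history]
        assert [(m.smiles, r) for m, r, _, _ in a.pool] == [
            (m.smiles, r) for m, r, _, _ in b.pool
        ]

    def test_sample_compounds_pool_bounds_and_rewards(self, chem_train_setup, library):
        mdp, policy, partition, reward, start = chem_train_setup
        pool = sample_compounds(mdp, policy, reward, [start], 10, max_len=3, seed=4)
        assert len(pool) <= 10 * 3
        for mol, r, tid, step in pool:
            assert r > 0
            assert mol != start  # start material itself is excluded


class TestForwardMarginal:
    def test_marginal_sums_to_one_over_successors(self, untrained_chem_env):
        """Summing P_F(s'|s) over every reachable successor gives 1 when
        all actions lead somewhere."""
        from synthflow.gflownet import forward_marginal

        mdp, policy = untrained_chem_env
        state = Molecule.from_smiles("NCc1ccc(C=O)cc1")
        successors = set()
        for a in mdp.applicable(state):
            successors.update(m.smiles for m, _ in mdp.candidates(state, a))
        total = sum(
            forward_marginal(mdp, policy, state, Molecule(s)) for s in successors
        )
        assert total == pytest.approx(1.0)

    def test_zero_for_unreachable_successor(self, untrained_chem_env):
        from synthflow.gflownet import forward_marginal

        mdp, policy = untrained_chem_env
        state = Molecule.from_smiles("NCc1ccc(C=O)cc1")
        assert forward_marginal(mdp, policy, state, Molecule.from_smiles("CC")) == 0.0
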