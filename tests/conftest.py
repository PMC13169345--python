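"""Shared fixtures: a small fixture chemistry bundle reused across tests.

The full study-scale bundle (200 blocks / 2000 triples / 1000-molecule
corpus) lives in test_acceptance.py; unit tests use the smaller objects
here to stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from synthflow.chem import Molecule, Vocabulary
from synthflow.fixtures import (
    default_template_library,
    generate_building_blocks,
    generate_reaction_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return default_template_library()


@pytest.fixture(scope="session")
def blocks(library):
    return generate_building_blocks(seed=1, n=60)


@pytest.fixture(scope="session")
def triples_small(library, blocks):
    return generate_reaction_dataset(library, blocks, n=300, seed=2)


@pytest.fixture(scope="session")
def vocab(library, triples_small):
    smiles = [t.reactant.smiles for t in triples_small]
    smiles += [t.product.smiles for t in triples_small]
    return Vocabulary.build(smiles, library.size)


@pytest.fixture(scope="session")
def sample_molecules(blocks):
    return blocks[:30]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
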