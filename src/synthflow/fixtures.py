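"""Synthetic desk-scale fixtures: template library, building blocks,
template-labeled reaction triples, and planted activity labels.

The fixtures emulate the shape of a patent-derived, template-labeled
single-product reaction corpus at a scale where every component of the
package can be trained and exhaustively verified on one CPU: ten
hand-written reaction templates over common medicinal-chemistry
transformations, a few hundred building blocks from a scaffold ×
substituent grid, and a planted structure–activity rule (a benzylic
tertiary amine) that is reachable from amine- or aldehyde-bearing
blocks only through multi-step reaction sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule, canonicalize
from .templates import ReactionTemplate, TemplateLibrary, apply_template

__all__ = [
    "default_template_library",
    "generate_building_blocks",
    "ReactionTriple",
    "generate_reaction_dataset",
    "planted_activity_labels",
    "generate_activity_corpus",
    "PLANTED_PHARMACOPHORE",
    "save_triples",
    "load_triples",
    "save_smiles",
    "load_smiles",
]

# Benzylic tertiary amine: the planted "active" motif.  Building blocks
# never contain a tertiary amine, so the motif only appears after
# N-functionalization steps.
PLANTED_PHARMACOPHORE = "[c][CX4;H2][NX3;H0;!$(NC=O)]([CX4])[CX4]"

# template definitions: (smarts, arity, partner smiles, name)
_TEMPLATE_DEFS = [
    ("[NX3;H2:1].[CX4;H3:2][I]>>[NX3;H1:1][CX4;H3:2]", 2, "CI",
     "N-methylation of primary amine"),
    ("[NX3;H1;!$(NC=O):1].[CX4;H3:2][I]>>[NX3;H0:1][CX4;H3:2]", 2, "CI",
     "N-methylation of secondary amine"),
    ("[CX3:1](=[OX1:2])[OX2H1].[NX3;H2:3][CX4;H2:4]>>"
     "[CX3:1](=[OX1:2])[NX3;H1:3][CX4;H2:4]", 2, "NCCO",
     "amide coupling with ethanolamine"),
    ("[CX3:1](=[OX1:2])[OX2H1].[OX2H1:3][CX4;H3:4]>>"
     "[CX3:1](=[OX1:2])[OX2:3][CX4;H3:4]", 2, "CO",
     "Fischer esterification with methanol"),
    ("[CX4:1][OX2H1:2].[CX4;H3:3][I]>>[CX4:1][OX2:2][CX4;H3:3]", 2, "CI",
     "Williamson ether synthesis"),
    ("[NX3;H2:1].[CH2:2]([c:3])[Cl]>>[NX3;H1:1][CH2:2][c:3]", 2,
     "ClCc1ccc([N+](=O)[O-])cc1", "N-benzylation of primary amine"),
    ("[NX3;H1;!$(NC=O):1].[CH2:2]([c:3])[Cl]>>[NX3;H0:1][CH2:2][c:3]", 2,
     "ClCc1ccc([N+](=O)[O-])cc1", "N-benzylation of secondary amine"),
    ("[NX3+:1](=[OX1:2])[O-]>>[NX3;H2;+0:1]", 1, None, "nitro reduction"),
    ("[CX3:1](=[OX1:2])([#6:3])[#6:4]>>[CX4;H1:1]([OX2H1:2])([#6:3])[#6:4]",
     1, None, "ketone reduction"),
    ("[CX3;H1:1]=[OX1].[NX3;H2:2][CX4;H3:3]>>[CX4;H2:1][NX3;H1:2][CX4;H3:3]",
     2, "CN", "reductive amination with methylamine"),
]


def default_template_library() -> TemplateLibrary:
    """The ten-template fixture library."""
    templates = []
    for i, (smarts, arity, partner, name) in enumerate(_TEMPLATE_DEFS):
        pool = [Molecule.from_smiles(partner)] if partner else []
        templates.append(ReactionTemplate(i, smarts, arity, pool, name))
    return TemplateLibrary(templates)


# scaffold x substituent grid ------------------------------------------

_AROMATIC_CORES = [
    "c1ccc({X})cc1", "Cc1ccc({X})cc1", "Fc1ccc({X})cc1", "Clc1ccc({X})cc1",
    "COc1ccc({X})cc1", "c1ccc({X})cc1C", "Cc1cccc({X})c1", "Fc1cccc({X})c1",
    "Clc1cccc({X})c1", "COc1cccc({X})c1", "Cc1ccc({X})cc1C",
    "Fc1ccc({X})cc1F", "CC(C)c1ccc({X})cc1", "FC(F)(F)c1ccc({X})cc1",
    "c1ccc2c(c1)CCC2{X}", "c1ccsc1{X}", "c1ccoc1{X}", "Cc1ccccc1{X}",
    "c1ccncc1C{X}", "Cc1ccc(C{X})cc1", "c1ccc(C{X})cc1", "c1ccc(CC{X})cc1",
    "Fc1ccc(C{X})cc1", "COc1ccc(C{X})cc1",
]
_AROMATIC_HEADS = [
    "CN", "N", "NC", "C(=O)O", "CO", "O", "[N+](=O)[O-]", "C(C)=O", "C=O",
]
_ALIPHATIC_CORES = [
    "C1CCC({X})CC1", "C1CCCC1{X}", "CC(C)({X})C", "CC(C){X}", "CC{X}",
    "CCC{X}", "CCCC{X}", "CC(C)C{X}", "C1CC1C{X}", "C1CCC1{X}",
]
_ALIPHATIC_HEADS = ["N", "C(=O)O", "CO", "O", "C(C)=O", "C=O"]

# Guaranteed per-template representatives (in block-capacity order these
# are emitted first so that small n still covers every template).
_COVERAGE_BLOCKS = [
    "NCc1ccccc1",        # primary amine: t0, t5
    "CNc1ccccc1",        # secondary (aryl) amine: t1, t6
    "OC(=O)c1ccccc1",    # carboxylic acid: t2, t3
    "OCc1ccccc1",        # primary alcohol: t4
    "O=[N+]([O-])c1ccccc1",  # nitroarene: t7
    "CC(=O)c1ccccc1",    # ketone: t8
    "O=Cc1ccccc1",       # aldehyde: t9
]


def _block_space() -> list[str]:
    """The full, ordered combinatorial block space (canonical, distinct)."""
    seen: set[str] = set()
    ordered: list[str] = []
    raw = list(_COVERAGE_BLOCKS)
    raw += [c.format(X=h) for c, h in itertools.product(_AROMATIC_CORES, _AROMATIC_HEADS)]
    raw += [c.format(X=h) for c, h in itertools.product(_ALIPHATIC_CORES, _ALIPHATIC_HEADS)]
    for s in raw:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            ordered.append(can)
    return ordered


def generate_building_blocks(seed: int, n: int) -> list[Molecule]:
    """Draw ``n`` distinct building blocks from the scaffold grid.

    The first blocks emitted are fixed per-template representatives, so
    every fixture template has at least one applicable block for any
    ``n >= 7``; the remainder is a seeded shuffle of the grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    space = _block_space()
    if n > len(space):
        raise ValueError(
            f"requested {n} blocks but the combinatorial space has only "
            f"{len(space)}"
        )
    head = space[: len(_COVERAGE_BLOCKS)]
    tail = space[len(_COVERAGE_BLOCKS) :]
    rng = np.random.default_rng(seed)
    rng.shuffle(tail)
    chosen = (head + tail)[:n]
    return [Molecule(s) for s in chosen]


# reaction triples ------------------------------------------------------


@dataclass(frozen=True)
class ReactionTriple:
    """One template-labeled single-product reaction record."""

    reactant: Molecule
    template_index: int
    product: Molecule


def generate_reaction_dataset(
    library: TemplateLibrary,
    blocks: Sequence[Molecule],
    n: int,
    seed: int,
) -> list[ReactionTriple]:
    """Sample ``n`` reaction triples: a random block, a uniformly random
    applicable template, a uniformly random product of that template."""
    if not blocks:
        raise ValueError("blocks must be nonempty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    products_cache: dict[tuple[str, int], list[Molecule]] = {}

    def products(mol: Molecule, t: int) -> list[Molecule]:
        key = (mol.smiles, t)
        if key not in products_cache:
            products_cache[key] = apply_template(library[t], mol)
        return products_cache[key]

    usable = [
        b for b in blocks if any(products(b, t.index) for t in library)
    ]
    if not usable:
        raise ValueError("no building block matches any template")
    triples: list[ReactionTriple] = []
    for _ in range(n):
        block = usable[rng.integers(len(usable))]
        applicable = [t.index for t in library if products(block, t.index)]
        t = applicable[rng.integers(len(applicable))]
        outs = products(block, t)
        product = outs[rng.integers(len(outs))]
        triples.append(ReactionTriple(block, t, product))
    return triples


# planted activity ------------------------------------------------------


def planted_activity_labels(
    mols: Sequence[Molecule],
    pharmacophore: str = PLANTED_PHARMACOPHORE,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> list[int]:
    """Binary labels: 1 iff the molecule contains the pharmacophore as a
    substructure, each label then flipped independently with probability
    ``flip_prob``."""
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must be in [0, 0.5)")
    pattern = Chem.MolFromSmarts(pharmacophore)
    if pattern is None:
        raise ValueError(f"unparseable SMARTS pattern: {pharmacophore!r}")
    rng = np.random.default_rng(seed)
    labels = []
    for m in mols:
        y = int(m.rdkit.HasSubstructMatch(pattern))
        if flip_prob > 0.0 and rng.random() < flip_prob:
            y = 1 - y
        labels.append(y)
    return labels


def generate_activity_corpus(
    library: TemplateLibrary,
    blocks: Sequence[Molecule],
    n: int,
    seed: int,
    max_steps: int = 3,
    max_mw: float = 450.0,
) -> list[Molecule]:
    """Distinct molecules for activity modeling: building blocks plus
    products of random reaction walks of up to ``max_steps`` steps,
    capped at ``max_mw`` daltons to keep the corpus desk-scale."""
    from rdkit.Chem import Descriptors

    rng = np.random.default_rng(seed)
    cache: dict[tuple[str, int], list[Molecule]] = {}

    def products(mol: Molecule, t: int) -> list[Molecule]:
        key = (mol.smiles, t)
        if key not in cache:
            cache[key] = apply_template(library[t], mol)
        return cache[key]

    pool: list[Molecule] = []
    seen: set[str] = set()

    def add(m: Molecule) -> None:
        if m.smiles not in seen:
            seen.add(m.smiles)
            pool.append(m)

    for b in blocks:
        add(b)
    attempts = 0
    while len(pool) < n and attempts < 50 * n:
        attempts += 1
        # walks may start from earlier products, so the reachable set
        # grows combinatorially with n
        state = pool[rng.integers(len(pool))]
        n_steps = int(rng.integers(1, max_steps + 1))
        for _ in range(n_steps):
            applicable = [t.index for t in library if products(state, t.index)]
            if not applicable:
                break
            t = applicable[rng.integers(len(applicable))]
            outs = products(state, t)
            state = outs[rng.integers(len(outs))]
            if Descriptors.MolWt(state.rdkit) > max_mw:
                break
            add(state)
    if len(pool) < n:
        raise ValueError(
            f"could only generate {len(pool)} distinct molecules "
            f"(requested {n})"
        )
    return pool[:n]


# plain-text I/O --------------------------------------------------------


def save_smiles(mols: Sequence[Molecule], path: str | Path) -> None:
    Path(path).write_text("\n".join(m.smiles for m in mols) + "\n")


def load_smiles(path: str | Path) -> list[Molecule]:
    out = []
    for line in Path(path).read_text().splitlines():
        smiles = line.split("\t")[0].strip()
        if smiles:
            out.append(Molecule.from_smiles(smiles))
    return out


def save_triples(triples: Sequence[ReactionTriple], path: str | Path) -> None:
    lines = ["reactant_smiles\ttemplate_index\tproduct_smiles"]
    for t in triples:
        lines.append(f"{t.reactant.smiles}\t{t.template_index}\t{t.product.smiles}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_triples(path: str | Path) -> list[ReactionTriple]:
    rows = Path(path).read_text().splitlines()
    out = []
    for line in rows[1:]:
        if not line.strip():
            continue
        r, t, p = line.split("\t")
        out.append(ReactionTriple(Molecule(r), int(t), Molecule(p)))
    return out
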