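"""Reaction templates and their application to molecules.

A :class:`ReactionTemplate` is an indexed reaction-SMARTS rule — the
action alphabet of the synthesis MDP.  Unimolecular templates transform
the state molecule alone; bimolecular templates carry an explicit
partner pool for the second reactant slot so that product enumeration
is reproducible.  Products that fail sanitization (reaction SMARTS can
produce impossible valences) are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .chem import Molecule, canonicalize, mol_from_smiles

__all__ = [
    "ReactionTemplate",
    "TemplateLibrary",
    "TemplateError",
    "apply_template",
    "enumerate_applicable",
    "filter_starting_materials",
    "passes_structure_filters",
]

log = logging.getLogger(__name__)


class TemplateError(ValueError):
    pass


@dataclass
class ReactionTemplate:
    """An indexed structural transformation rule.

    ``arity`` is the number of reactant slots (1 or 2); bimolecular
    templates enumerate ``partner_pool`` in the second slot.
    """

    index: int
    rxn_smarts: str
    arity: int = 1
    partner_pool: list[Molecule] = field(default_factory=list)
    name: str = ""
    _rxn: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.index < 0:
            raise TemplateError(f"template index must be >= 0, got {self.index}")
        if self.arity not in (1, 2):
            raise TemplateError(f"template {self.index}: arity must be 1 or 2")
        if self.arity == 2 and not self.partner_pool:
            raise TemplateError(
                f"template {self.index}: bimolecular template needs a partner pool"
            )

    @property
    def rxn(self):
        if self._rxn is None:
            rxn = AllChem.ReactionFromSmarts(self.rxn_smarts)
            if rxn is None:
                raise TemplateError(
                    f"template {self.index}: cannot parse reaction SMARTS "
                    f"{self.rxn_smarts!r}"
                )
            n_expected = 1 if self.arity == 1 else 2
            if rxn.GetNumReactantTemplates() != n_expected:
                raise TemplateError(
                    f"template {self.index}: SMARTS has "
                    f"{rxn.GetNumReactantTemplates()} reactant slots, "
                    f"arity says {n_expected}"
                )
            object.__setattr__(self, "_rxn", rxn)
        return self._rxn


def apply_template(template: ReactionTemplate, reactant: Molecule) -> list[Molecule]:
    """All distinct sanitized single-product outcomes of ``template`` on
    ``reactant`` (enumerating the partner pool for bimolecular rules).

    Returns an empty list when the template does not match.  Output
    SMILES are canonical and sorted for determinism.
    """
    rxn = template.rxn
    rd_reactant = reactant.rdkit
    partner_sets: Sequence[tuple]
    if template.arity == 1:
        partner_sets = [(rd_reactant,)]
    else:
        partner_sets = [(rd_reactant, p.rdkit) for p in template.partner_pool]

    out: set[str] = set()
    n_dropped = 0
    for reactants in partner_sets:
        try:
            products = rxn.RunReactants(reactants)
        except Exception:  # pragma: no cover - defensive, RDKit rarely raises
            continue
        for prod_tuple in products:
            if len(prod_tuple) != 1:
                continue
            mol = prod_tuple[0]
            try:
                Chem.SanitizeMol(mol)
                out.add(Chem.MolToSmiles(mol))
            except Exception:
                n_dropped += 1
    if n_dropped:
        log.debug(
            "template %d on %s: dropped %d unsanitizable products",
            template.index,
            reactant.smiles,
            n_dropped,
        )
    return [Molecule(s) for s in sorted(out)]


@dataclass
class TemplateLibrary:
    """Ordered template collection; indices run 0..size-1 without gaps."""

    templates: list[ReactionTemplate]

    def __post_init__(self) -> None:
        for i, t in enumerate(self.templates):
            if t.index != i:
                raise TemplateError(
                    f"template at position {i} has index {t.index}; "
                    "indices must be 0..size-1 with no gaps"
                )

    @property
    def size(self) -> int:
        return len(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, i: int) -> ReactionTemplate:
        return self.templates[i]

    def __iter__(self):
        return iter(self.templates)

    # -- serialization: index <tab> smarts <tab> arity <tab> partners ---
    def save(self, path: str | Path) -> None:
        lines = ["index\trxn_smarts\tarity\tpartners\tname"]
        for t in self.templates:
            partners = ".".join(p.smiles for p in t.partner_pool)
            lines.append(f"{t.index}\t{t.rxn_smarts}\t{t.arity}\t{partners}\t{t.name}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TemplateLibrary":
        rows = Path(path).read_text().splitlines()
        templates = []
        for line in rows[1:]:
            if not line.strip():
                continue
            idx, smarts, arity, partners, name = line.split("\t")
            pool = [Molecule.from_smiles(s) for s in partners.split(".") if s]
            templates.append(
                ReactionTemplate(int(idx), smarts, int(arity), pool, name)
            )
        return cls(templates)


def enumerate_applicable(library: TemplateLibrary, mol: Molecule) -> list[int]:
    """Indices of templates with at least one product on ``mol``
    (sorted ascending, duplicate-free by construction)."""
    return [t.index for t in library if apply_template(t, mol)]


# ----------------------------------------------------------------------
# starting-material selection
# ----------------------------------------------------------------------

# Reactive-group queries: halogen, carbonyl, unsaturated bond, and
# nucleophilic substituent (operationalized as N-H / O-H / S-H).
_REACTIVE_SMARTS = {
    "halogen": "[F,Cl,Br,I]",
    "carbonyl": "[CX3]=[OX1]",
    "unsaturated": "[*]=,#[*]",
    "nucleophile": "[$([#7;!H0]),$([OX2H1]),$([SX2H1])]",
}
_REACTIVE_PATTERNS = None


def _reactive_patterns():
    global _REACTIVE_PATTERNS
    if _REACTIVE_PATTERNS is None:
        _REACTIVE_PATTERNS = {
            k: Chem.MolFromSmarts(v) for k, v in _REACTIVE_SMARTS.items()
        }
    return _REACTIVE_PATTERNS


def passes_structure_filters(
    mol: Molecule, max_ring: int = 8, max_mw: float = 300.0
) -> bool:
    """Structural eligibility rules for starting materials: no ring with
    ``max_ring`` or more members, molecular weight at most ``max_mw``,
    and at least one reactive functional group (halogen, carbonyl,
    unsaturated bond, or nucleophilic N-H/O-H/S-H)."""
    rd = mol.rdkit
    for ring in rd.GetRingInfo().AtomRings():
        if len(ring) >= max_ring:
            return False
    if Descriptors.MolWt(rd) > max_mw:
        return False
    return any(rd.HasSubstructMatch(p) for p in _reactive_patterns().values())


def filter_starting_materials(
    mols: Iterable[Molecule],
    qsar_score,
    bins: Sequence[tuple[float, float]],
    seed: int,
) -> dict[tuple[float, float], tuple[Molecule, float]]:
    """Select one random starting material per activity bin.

    Removes structurally ineligible molecules (see
    :func:`passes_structure_filters`), scores survivors with
    ``qsar_score`` (a callable ``Molecule -> [0, 1]``), then draws one
    survivor uniformly at random per ``(lo, hi]``-style bin.  Bins with
    no survivor are absent from the result.
    """
    import numpy as np

    bins = list(bins)
    for i, (lo, hi) in enumerate(bins):
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bin {(lo, hi)} not within [0, 1]")
        for lo2, hi2 in bins[i + 1 :]:
            if lo < hi2 and lo2 < hi:
                raise ValueError(f"bins {(lo, hi)} and {(lo2, hi2)} overlap")
    survivors = [m for m in mols if passes_structure_filters(m)]
    scored = [(m, float(qsar_score(m))) for m in survivors]
    rng = np.random.default_rng(seed)
    out: dict[tuple[float, float], tuple[Molecule, float]] = {}
    for lo, hi in bins:
        members = [(m, s) for m, s in scored if lo <= s < hi]
        if members:
            out[(lo, hi)] = members[rng.integers(len(members))]
    return out
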