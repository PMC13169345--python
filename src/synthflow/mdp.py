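"""The chemical Markov decision process over reaction templates.

States are molecules, actions are template indices, and transitions are
chemical reactions.  Two transition sources are supported:

* **oracle** — the template engine enumerates products directly and the
  transition distribution is uniform over them.  On fixture-sized
  problems the full reachable DAG can be enumerated, so backward-policy
  parent counts are exact.
* **learned** — a :class:`TransitionTransformer` proposes products by
  beam search with renormalized sequence likelihoods.  Parent
  enumeration is intractable here, so the backward policy uses the
  tree assumption (every state has one parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .chem import Molecule
from .models.transition import TransitionTransformer, transition_candidates
from .templates import TemplateLibrary, apply_template

__all__ = ["ReactionMDP", "ReachabilityError"]


class ReachabilityError(ValueError):
    pass


@dataclass
class ReactionMDP:
    library: TemplateLibrary
    max_depth: int = 5
    transition_source: Literal["oracle", "learned"] = "oracle"
    transition_model: TransitionTransformer | None = None
    beam: int = 10
    _products: dict[tuple[str, int], list[Molecule]] = field(
        default_factory=dict, repr=False
    )
    _applicable: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _dags: dict[tuple[str, int], dict] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.transition_source == "learned" and self.transition_model is None:
            raise ValueError("learned transition source needs a transition model")

    # -- oracle engine (cached) ----------------------------------------
    def oracle_products(self, mol: Molecule, action: int) -> list[Molecule]:
        key = (mol.smiles, action)
        if key not in self._products:
            self._products[key] = apply_template(self.library[action], mol)
        return self._products[key]

    def applicable(self, mol: Molecule) -> list[int]:
        """Template indices with at least one oracle product."""
        if mol.smiles not in self._applicable:
            self._applicable[mol.smiles] = [
                t.index for t in self.library if self.oracle_products(mol, t.index)
            ]
        return self._applicable[mol.smiles]

    # -- transitions ---------------------------------------------------
    def candidates(self, mol: Molecule, action: int) -> list[tuple[Molecule, float]]:
        """Successor distribution for (state, action): uniform over the
        oracle products, or beam-renormalized under the learned model."""
        if self.transition_source == "oracle":
            prods = self.oracle_products(mol, action)
            if not prods:
                return []
            p = 1.0 / len(prods)
            return [(m, p) for m in prods]
        return transition_candidates(self.transition_model, mol, action, self.beam)

    # -- parent sets ---------------------------------------------------
    def _dag(self, start: Molecule) -> dict[str, set[tuple[str, int]]]:
        """Exhaustive forward expansion from ``start`` to ``max_depth``:
        maps each reachable state to its set of (parent, action) edges."""
        key = (start.smiles, self.max_depth)
        if key not in self._dags:
            parents: dict[str, set[tuple[str, int]]] = {start.smiles: set()}
            frontier = [start]
            for _ in range(self.max_depth):
                nxt: list[Molecule] = []
                for mol in frontier:
                    for a in self.applicable(mol):
                        for child in self.oracle_products(mol, a):
                            if child.smiles not in parents:
                                parents[child.smiles] = set()
                                nxt.append(child)
                            parents[child.smiles].add((mol.smiles, a))
                frontier = nxt
            self._dags[key] = parents
        return self._dags[key]

    def parent_count(self, state: Molecule, start: Molecule | None = None) -> int:
        """Number of (parent, action) edges leading into ``state``.

        Oracle mode enumerates the DAG below ``start`` exhaustively; the
        start state itself counts 1 by the virtual-root convention.
        Learned mode returns 1 (tree assumption).
        """
        if self.transition_source == "learned":
            return 1
        if start is None:
            raise ValueError("oracle parent_count needs the start molecule")
        dag = self._dag(start)
        if state.smiles not in dag:
            raise ReachabilityError(
                f"state {state.smiles!r} is not reachable from "
                f"{start.smiles!r} within depth {self.max_depth}"
            )
        return max(len(dag[state.smiles]), 1)

    def reachable_size(self, start: Molecule) -> int:
        """Number of states reachable from ``start`` within max_depth."""
        return len(self._dag(start))
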