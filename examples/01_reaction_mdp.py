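"""Explore the reaction-template MDP: states are molecules, actions are
templates, transitions are reactions.

Builds the fixture template library, applies templates to a starting
material, and enumerates the full reachable DAG with exact parent
counts — the quantities the uniform backward policy needs.
"""

from synthflow import Molecule, ReactionMDP, default_template_library

library = default_template_library()
mdp = ReactionMDP(library, max_depth=3)
start = Molecule.from_smiles("NCc1ccc(C=O)cc1")  # 4-(aminomethyl)benzaldehyde

print(f"start: {start.smiles}")
print("applicable templates:")
for idx in mdp.applicable(start):
    products = mdp.oracle_products(start, idx)
    print(f"  [{idx}] {library[idx].name}: {len(products)} product(s)")
    for p in products:
        print(f"        -> {p.smiles}")

n_states = mdp.reachable_size(start)
print(f"\nreachable states within depth 3: {n_states}")
multi = [
    s
    for s in mdp._dag(start)
    if mdp.parent_count(Molecule(s), start) >= 2
]
print(f"states with >= 2 (parent, action) edges: {len(multi)}")
print(
    "Each count is the denominator of the uniform backward policy for "
    "that state; on this fixture DAG the counts are exact."
)
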