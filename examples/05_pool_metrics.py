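"""Evaluate a generated compound pool: reward statistics, two diversity
readings, uniqueness, and novelty against a reference corpus.
"""

import numpy as np

from synthflow import (
    GCNPolicy,
    Molecule,
    PolicyConfig,
    ReactionMDP,
    default_template_library,
    generate_building_blocks,
    generate_reaction_dataset,
    sample_compounds,
    summarize,
)

library = default_template_library()
blocks = generate_building_blocks(seed=1, n=100)
triples = generate_reaction_dataset(library, blocks, n=300, seed=2)
reference = {t.product.smiles for t in triples}

policy = GCNPolicy(PolicyConfig(hidden=32, epochs=1), library.size, seed=0)
policy.eval()  # untrained: uniform-ish exploration of the reaction space
mdp = ReactionMDP(library, max_depth=3)
start = Molecule.from_smiles("NCc1ccc(C=O)cc1")
pool = sample_compounds(
    mdp, policy, lambda m: 0.3 + 0.4 * ("N" in m.smiles), [start], 150, max_len=3, seed=4
)

report = summarize(
    [(m, r) for m, r, _, _ in pool], reference=reference, qsar_threshold=0.5
)
for key, value in report.as_dict().items():
    print(f"{key:>24}: {value:.4f}" if isinstance(value, float) else f"{key:>24}: {value}")
print(
    "\nuniqueness is the distinct fraction of the pool; novelty is the "
    "fraction of distinct compounds absent from the reference products; "
    "the two diversity lines are 1 - mean Tanimoto (unordered pairs) and "
    "the internal-diversity variant with squared similarities."
)
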