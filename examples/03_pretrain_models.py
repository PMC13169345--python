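"""Pretrain the two forward-prediction components on synthetic reactions.

The template policy (a graph-convolutional network) learns which
reactions apply to a molecule; the conditional transformer learns to
write the product SMILES given the reactant prefixed with a
reaction-condition token.  Both are scored on held-out reactions.
"""

from synthflow import (
    PolicyConfig,
    GCNPolicy,
    TransitionConfig,
    TransitionTransformer,
    Vocabulary,
    default_template_library,
    generate_building_blocks,
    generate_reaction_dataset,
    pretrain_policy,
    pretrain_transition,
    transition_candidates,
)

library = default_template_library()
blocks = generate_building_blocks(seed=1, n=120)
triples = generate_reaction_dataset(library, blocks, n=600, seed=2)
smiles = [t.reactant.smiles for t in triples] + [t.product.smiles for t in triples]
vocab = Vocabulary.build(smiles, library.size)

pcfg = PolicyConfig(hidden=64, epochs=8)
policy = GCNPolicy(pcfg, library.size, seed=0)
policy_report = pretrain_policy(policy, [(t.reactant, t.template_index) for t in triples], pcfg, seed=0)
print(f"policy held-out top-k accuracy: {policy_report.topk_accuracy}")
print(f"majority-class baseline:        {policy_report.majority_baseline:.3f}")

tcfg = TransitionConfig(dim=48, ff_dim=96, epochs=14, batch_size=32)
transition = TransitionTransformer(tcfg, vocab, seed=0)
transition_report = pretrain_transition(transition, triples, tcfg, seed=0)
print(f"transition held-out exact match: {transition_report.exact_match_holdout:.3f}")

t = triples[0]
candidates = transition_candidates(transition, t.reactant, t.template_index, beam=5)
print(f"\nbeam-5 candidates for {t.reactant.smiles} under template {t.template_index}:")
for mol, prob in candidates:
    marker = "  <- oracle product" if mol == t.product else ""
    print(f"  {prob:.3f}  {mol.smiles}{marker}")
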