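# Methods

## The generative model

Molecular generation is formulated as sampling trajectories through a
synthesis MDP.  A state s is a molecule (canonical SMILES); an action a
is a reaction-template index; taking a in s yields a product s′ with
transition probability T(s′|s, a).  Trajectories start at a designated
starting material s₀ and run until either a configured maximum length
(default 4 reaction steps; configurable up to the conventional 5) or a
dead end — a state where no template applies or no decoded product is
valid — which is treated as reaching the terminal at the current state
so that every trajectory is rewardable.

The forward policy factorizes into the template policy and the
transition model, P_F(s′|s) over a chosen action being
π_θ(a|s)·T_φ(s′|s, a).  A diagnostic utility also exposes the
action-marginalized form Σ_a π_θ(a|s)·T_φ(s′|s, a); the training loss
uses the state–action factorization, i.e. the probabilities of the
choices actually sampled.

**Template policy.**  A graph-convolutional network: atom features
(element one-hot over {C, N, O, F, S, Cl, Br, I, other}, degree, formal
charge, total H count, aromaticity, ring membership), symmetric-
normalized adjacency with self-loops, then stacked blocks of graph
convolution → batch normalization → ReLU, sum pooling over atoms, and
dense layers ending in a softmax over template indices.  Sum pooling
makes the output invariant to atom ordering (tested to 1e-5).  Defaults
follow the reference configuration — hidden width 256, one convolution
block, three dense layers, learning rate 4e-4 — while the fixture
pipeline runs width 128 for speed; both are plain config values.

**Transition model.**  A small encoder–decoder transformer over SMILES
tokens with a leading condition token `<RXN_a>` selecting the reaction
type.  The fixture-scale architecture is width 64, 2+2 layers, 4 heads,
feed-forward 128, dropout 0.1 (the full-scale 512/6/8 configuration is
reachable through the same config).  Decoding is deterministic beam
search; finished hypotheses are kept until no live hypothesis can beat
the worst kept score.  Candidates are canonicalized, deduplicated
(keeping each molecule's best-scoring sequence), invalid strings
dropped, and the surviving sequence likelihoods renormalized — this
renormalized distribution *is* T_φ(s′|s, a), which keeps the
trajectory-balance product well-defined.  How beam scores become a
transition probability is not fixed by the problem statement; beam
renormalization is this package's documented choice.

**Partition estimator.**  log Z_ψ(β) is a perceptron with three hidden
layers (width 64) on the scalar encoding log β.  The encoding is a
configurable choice; log β spans the useful temperature range {2…32}
smoothly.  The estimator's parameters are separate from the policy's.

**Reward.**  A random-forest classifier (500 trees, fixed
hyperparameters) over ECFP4 fingerprints (radius 2, 2048 bits) supplies
R_QSAR(x) ∈ [0, 1] as the positive-class probability.  Optionally
R(x) = R_QSAR(x) + λ·R_SA(x) with R_SA = (10 − SA)/9, an affine map of
the fragment-contribution synthetic-accessibility score onto [0, 1]
(the SA-to-reward map is a package choice and configurable).  Rewards
are clamped below at a floor (default 1e-6) because forest
probabilities can be exactly zero and the loss consumes log R.
Tempering R^β is computed in log space as β·log R.

## Training

The tempered trajectory-balance loss for a complete trajectory is the
squared log-ratio

    (log Z_ψ(β) + Σ log π_θ + Σ log T_φ − β log R(x) − Σ log P_B)²

minimized jointly over θ, φ, ψ with Adam (global gradient-norm
clipping; the partition estimator gets a larger learning rate because
a single scalar must travel much farther than the network weights).

Choices the loss leaves open, with the defaults used here:

* **Template masking.**  The policy distribution is masked to the
  applicable templates and renormalized before sampling, and the masked
  probability is what enters the forward product — the product must use
  the distribution actually sampled from.
* **Backward policy.**  Uniform over parents.  On grids and on
  fixture-scale chemical DAGs, parent counts are exact (exhaustive
  forward expansion from the start, cached); with learned transitions
  parent enumeration is intractable and the tree assumption |Pa(s)| = 1
  is used.  The start state counts 1 by a virtual-root convention.
* **Terminal semantics.**  One TB term per trajectory with the reward
  at the endpoint.  All intermediate molecules still enter the
  generated-compound pool for evaluation (every visited state is a
  valid molecule by construction).  An `all_prefixes`-style per-prefix
  loss was considered and rejected as the default because the printed
  objective is a single-endpoint loss.
* **Exploration.**  Pure on-policy TB training collapses: once the
  policy is near-deterministic the loss is only evaluated on the single
  visited trajectory and nothing constrains the rest of the DAG.
  Trajectories are therefore sampled from an ε-mixture of the policy
  with the uniform distribution over applicable templates (ε = 0.1
  during training, 0 during final sampling).  The recorded step
  log-probabilities are always the policy's own, so the balance
  residual is unchanged — exploration only changes *where* it is
  evaluated, which is valid because trajectory balance holds for
  trajectories from any full-support sampler.
* **Product choice within a beam.**  During trajectory generation a
  product is sampled from the renormalized candidate distribution
  (likelihood-proportional), not taken greedily.
* **Pretraining.**  The policy and transformer are pretrained on the
  fixture reaction corpus (cross-entropy / teacher forcing) and those
  parameters initialize TB training.

## The synthetic study system

The fixtures emulate, at desk scale, a template-labeled single-product
reaction corpus and an activity-labeled compound set, so that every
component is trainable and every claim checkable without external data.

* **Template library.**  Ten reaction-SMARTS rules covering common
  medicinal-chemistry steps: N-methylation (1° and 2° amines), amide
  coupling, Fischer esterification, Williamson ether synthesis,
  N-benzylation (1° and 2° amines), nitro reduction, ketone reduction,
  and reductive amination.  Bimolecular templates carry an explicit
  single-molecule partner pool (e.g. methyl iodide, ethanolamine,
  4-nitrobenzyl chloride), which keeps (reactant, template) → product
  deterministic — what the transformer's exact-match evaluation needs —
  while the nitrobenzyl and ethanolamine partners introduce fresh
  reactive handles so the reachable chemistry grows multiplicatively
  with depth.  Products that fail sanitization are dropped and counted.
* **Building blocks.**  A scaffold × substituent grid (24 aromatic and
  10 aliphatic cores × amine/acid/alcohol/nitro/carbonyl heads,
  ~280 distinct molecules).  The first seven blocks emitted are fixed
  representatives guaranteeing every template at least one applicable
  block at any n ≥ 7; the rest is a seeded shuffle.  Defaults: 200
  blocks, 2,000 reaction triples, 1,000 activity-labeled molecules.
* **Planted activity.**  A molecule is "active" iff it contains a
  benzylic tertiary amine (`[c][CX4;H2][NX3;H0;!$(NC=O)]([CX4])[CX4]`).
  No building block contains the motif; reaching it requires reaction
  sequences (two N-alkylations, or benzylation followed by methylation
  — at least two steps from the starting materials used in the study),
  so reward pressure is genuinely multi-step.  Labels are flipped
  independently with probability 0.05 to emulate assay noise.  The
  label corpus is generated by random reaction walks (≤3 steps, MW cap
  450 Da) and is ~27% active.
* **What the fixtures do not emulate.**  Real reaction corpora have
  thousands of templates, reagent/solvent noise, atom-mapping errors,
  multi-product reactions and heavy class imbalance; real QSAR training
  sets are larger, noisier and chemically broader.  Passing at fixture
  scale shows the machinery is correct and the trade-offs behave as
  designed; it does not certify performance on patent-scale data.

**Starting-material selection** follows structural rules: molecules
with any ring of ≥8 members or molecular weight over 300 Da are
removed, as are molecules lacking every reactive handle (halogen,
carbonyl, non-aromatic unsaturation, or a nucleophilic N–H/O–H/S–H).
"Nucleophilic substituent" and "unsaturated bond" are operationalized
as those SMARTS — plain arenes do not count as reactive unsaturation,
otherwise the rule would exclude nothing.  Survivors are scored by the
surrogate and one is drawn uniformly (seeded) per activity bin.

## Exact verification on grids

The chemical DAG cannot be enumerated at scale, so the sampler's
correctness claim — terminals drawn ∝ R(x)^β — is verified on a
hypergrid environment where everything is brute-forceable: states are
lattice points in {0…H−1}^D, actions increment one coordinate or stop
(the explicit stop gives a well-defined terminal set), parent counts
equal the number of nonzero coordinates, and Z(β) = Σ_x R(x)^β is an
exhaustive sum.  Registered rewards: `constant`, `corners` (multimodal
peaks near the corners), `cosine`.  At the default study scale (8×8
`corners`, 3,000 updates, batch 64), the trained sampler's 50,000
terminal draws land within total-variation ≈ 0.01 of the exact target
and the partition estimator within ≈ 0.003 of the true log Z for
β ∈ {1, 2} — against a pass band of 0.05 / 0.1.  Sampling noise alone
contributes TV ≈ 0.028 at n = 50,000 over 64 cells.

## The temperature study

One sampler is trained per β ∈ {2, 8, 32} under identical budgets and
seeds (start: 4-formylbenzoic acid, surrogate score ≈ 0.04; 200 rounds
× batch 32, max 4 steps, oracle transitions with exact parent counts),
then 400 trajectories are sampled per temperature and every visited
compound pooled.  The study start and budget were fixed by computing
the *exact* tempered target on the enumerable fixture DAG (trajectory
enumeration with exact parent counts): under perfect sampling the
pooled mean reward rises 0.536 → 0.587 → 0.641 and pooled diversity
falls 0.504 → 0.463 → 0.388 across β = 2/8/32, so the measured trend
tests whether training reaches the target, not whether the environment
happens to cooperate.  Diversity is reported over the pool as a
multiset — duplicated compounds lower diversity exactly as sampler
concentration should — with seeded subsampling (≤1,500 entries) ahead
of the O(n²) similarity computation.

## Evaluation metrics

Mean pairwise diversity is 1 − mean Tanimoto over unordered distinct
pairs; internal diversity is 1 − (1/|G|²) Σ T(m₁,m₂)² over ordered
pairs including self-pairs (so a singleton set scores 0 and two
disjoint-fingerprint molecules 0.5).  Both appear in reports because
both conventions are in circulation.  Uniqueness is the distinct
fraction of the pool; novelty is the fraction of *distinct* generated
structures absent from the reference corpus (denominator: the distinct
set — configurable).  All similarities use ECFP4 (radius 2, 2048 bits).
Fréchet ChemNet distance is listed as not-computed: it requires
pretrained ChemNet weights, which are out of scope here.

## The surrogate-recovery protocol

The QSAR experiment trains the forest on labels carrying 5% flip noise
and evaluates AUROC on a held-out 20% split **against the noise-free
planted labels**.  Scoring against the flipped labels instead would cap
the expected AUROC at ~0.95 at a 50% base rate — and strictly below
that at the fixture's 27% active rate — for *any* scorer, since the
flips are independent of structure; recovery of the planted rule is the
quantity of interest and is what is reported (measured ≈ 0.999).

## Numerical core

PyTorch-free by design: `synthflow.nn` is a compact reverse-mode
automatic-differentiation engine over NumPy arrays (float64) with the
operations the models need — broadcasted arithmetic, batched matmul,
gather/scatter, reductions, stable masked log-softmax (masking via a
−1e9 additive penalty held out of the tape), layer norm, masked batch
norm with running statistics, dropout, Adam with global-norm clipping.
Every operation's gradient is validated against central differences in
the test suite.  Batch-norm statistics are frozen (evaluation mode)
throughout TB training so the differentiable pass reproduces exactly
the probabilities that were sampled from.

Degenerate inputs: zero-atom molecules are rejected at featurization;
a start with no applicable template yields a zero-length trajectory
rewarded at the start itself; two all-zero fingerprints have Tanimoto
similarity 1 by convention (identical objects, avoids 0/0); reward
floors keep every log finite; non-finite TB inputs raise with the
offending term named.

## Known limitations

The learned-transition mode trains the transformer jointly through the
renormalized beam likelihoods, but at desk scale the temperature study
uses oracle (template-engine) transitions — beam decoding inside the
training loop is the dominant cost, exactly as transformer-based
trajectory sampling dominates at full scale.  The depth-capped MDP
conflates a molecule reached at different depths into one state, so
trajectory balance over molecule-level states is an approximation near
the depth cap.  Protecting-group logic, reaction selectivity and
applicability-domain estimation for the surrogate are out of scope;
surrogate scores prioritize compounds, they do not certify activity.
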