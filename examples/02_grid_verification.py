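"""Verify sampling proportionality exactly on an enumerable grid.

Trains the sampler with the trajectory-balance objective on a 6x6
multimodal grid, then compares 20,000 sampled terminal states against
the brute-forced target R(x)^beta / Z(beta).  Small total-variation
distance and log-partition error show the sampler matches the tempered
target, which is the method's central claim.
"""

import numpy as np

from synthflow import build_grid, log_partition, train_grid
from synthflow.gflownet import (
    empirical_distribution,
    sample_grid_terminals,
    total_variation,
)

beta = 2.0
grid = build_grid(side=6, dims=2, reward_name="corners")
result = train_grid(grid, beta=beta, n_updates=1500, batch=64, seed=0)

terminals = sample_grid_terminals(grid, result.policy, n=20000, seed=1)
tv = total_variation(
    empirical_distribution(grid, terminals), grid.target_distribution(beta)
)
logz = log_partition(result.partition, beta)
logz_true = float(np.log(grid.partition(beta)))

print(f"beta = {beta}")
print(f"total-variation distance to exact target: {tv:.4f}")
print(f"learned log Z = {logz:.4f}, brute-forced log Z = {logz_true:.4f}")
print(
    "TV near zero means terminals are sampled proportionally to "
    "R(x)^beta; the log Z agreement shows the partition estimator "
    "recovered the true normalizing constant."
)
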