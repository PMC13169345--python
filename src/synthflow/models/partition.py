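"""Temperature-conditioned partition-function estimator log Z(β).

A perceptron with three hidden layers maps an encoding of the
temperature β to the log partition function of the tempered target
R(x)^β.  β is fed as log β, which spans the usual temperature range
smoothly; the encoding is configurable.
"""

from __future__ import annotations

import numpy as np

from ..nn import MLP, Module, Tensor

__all__ = ["PartitionMLP", "log_partition"]


class PartitionMLP(Module):
    def __init__(self, hidden: int = 64, seed: int = 0, encoding: str = "log"):
        if encoding not in ("log", "linear"):
            raise ValueError(f"unknown beta encoding {encoding!r}")
        rng = np.random.default_rng(seed)
        self.encoding = encoding
        self.mlp = MLP(rng, 1, [hidden, hidden, hidden], 1)

    def _encode(self, beta: float) -> np.ndarray:
        if beta <= 0:
            raise ValueError("beta must be > 0")
        v = np.log(beta) if self.encoding == "log" else beta
        return np.array([[v]])

    def __call__(self, beta: float) -> Tensor:
        """Differentiable scalar log Z(β) (shape (1, 1) tensor)."""
        return self.mlp(Tensor(self._encode(beta)))


def log_partition(model: PartitionMLP, beta: float) -> float:
    """Point estimate of log Z(β)."""
    out = float(model(beta).data.reshape(()))
    if not np.isfinite(out):  # pragma: no cover - parameters are finite by construction
        raise FloatingPointError(f"log Z({beta}) is not finite")
    return out


def save_partition(model: PartitionMLP, path) -> None:
    import json

    hidden = model.mlp.layers[0].w.data.shape[1]
    meta = {"kind": "partition_mlp", "hidden": int(hidden), "encoding": model.encoding}
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_partition(path) -> PartitionMLP:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("kind") != "partition_mlp":
            raise ValueError(f"{path} is not a partition checkpoint")
        model = PartitionMLP(hidden=meta["hidden"], encoding=meta["encoding"])
        n_params = len(model.parameters())
        model.load_state_arrays([archive[f"p{i}"] for i in range(n_params)])
    return model
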