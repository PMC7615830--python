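"""Generic minibatch training loop for either learning rule.

One iteration updates the weights once from a minibatch: for prospective
configuration each example in the batch is relaxed (the relaxation is
vectorized over the batch, each example's activities evolving
independently) and the Hebbian updates are averaged before application; for
backpropagation the per-example gradients are averaged.  Test error is the
fraction of argmax-misclassified test examples, recorded once per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import backprop, pcn
from .fixtures import SyntheticDataset
from .network import LayeredNetwork, forward_prediction

__all__ = ["TrainTrace", "train_loop", "test_error"]


@dataclass
class TrainTrace:
    """Per-epoch test error with the two summary statistics used throughout:
    the mean of the test error during training (how fast the model learns)
    and the minimum (how well it can learn)."""

    test_errors: list[float] = field(default_factory=list)
    net: LayeredNetwork | None = None

    @property
    def mean_test_error(self) -> float:
        return float(np.mean(self.test_errors))

    @property
    def min_test_error(self) -> float:
        return float(np.min(self.test_errors))


def test_error(net: LayeredNetwork, dataset: SyntheticDataset) -> float:
    """Fraction of incorrectly classified test samples (argmax decoding)."""
    pred = forward_prediction(net, dataset.test_x.T)
    return float(np.mean(np.argmax(pred, axis=0) != dataset.test_y))


def train_loop(
    net: LayeredNetwork,
    rule: str,
    dataset: SyntheticDataset,
    alpha: float,
    batch_size: int = 32,
    epochs: int = 10,
    seed: int | None = None,
    config: pcn.RelaxationConfig | None = None,
) -> TrainTrace:
    """Train a copy of ``net`` on ``dataset`` and record per-epoch test error.

    ``batch_size=1`` is the online-learning regime (one weight update per
    example); larger batches average the per-example updates.
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    rng = np.random.default_rng(seed)
    net = net.copy()
    n = len(dataset.train_y)
    targets = dataset.one_hot(dataset.train_y)
    trace = TrainTrace()
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = dataset.train_x[idx].T  # (dim, b)
            tb = targets[idx].T  # (classes, b)
            if rule == "pc":
                net = pcn.learn(net, xb, tb, alpha, config)
            else:
                net = backprop.backprop_update(net, xb, tb, alpha)
        trace.test_errors.append(test_error(net, dataset))
    trace.net = net
    return trace
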