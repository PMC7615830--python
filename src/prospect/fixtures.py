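"""Synthetic fixtures: the bear network, random nets/patterns, blob data.

The 1-1-2 "bear" network is the minimal interference example: one stimulus
(seeing the river) predicts two outcomes (hearing water, smelling salmon).
When one prediction turns out wrong, backpropagation's correction also
degrades the correct prediction, while prospective configuration first
infers the activity pattern consistent with the observed outcome and spares
it.  The random fixtures support the depth-sweep interference protocol and
the generic batched training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ACTIVATIONS, LayeredNetwork, init_network

__all__ = [
    "PatternPair",
    "SyntheticDataset",
    "bear_fixture",
    "BearFixture",
    "random_pattern_pair",
    "deep_linear_fixture",
    "synthetic_classification",
]


@dataclass
class PatternPair:
    """An input pattern and the target pattern it should predict."""

    s_in: np.ndarray
    s_target: np.ndarray


@dataclass
class BearFixture:
    net: LayeredNetwork
    pattern: PatternPair
    alpha: float
    iterations: int


def bear_fixture(activation: str = "linear") -> BearFixture:
    """1 input, 1 hidden, 2 outputs; all weights 1; input [1], target [0, 1].

    Output neuron 0 is the *incorrect* prediction (target 0) and neuron 1
    the *correct* one (target 1, already predicted before learning).
    Training uses learning rate 0.2 for 24 iterations for both rules.
    """
    net = LayeredNetwork(
        [1, 1, 2],
        [np.ones((1, 1)), np.ones((2, 1))],
        ACTIVATIONS[activation],
    )
    return BearFixture(
        net=net,
        pattern=PatternPair(np.array([1.0]), np.array([0.0, 1.0])),
        alpha=0.2,
        iterations=24,
    )


def random_pattern_pair(in_size: int, out_size: int, seed: int | None = None) -> PatternPair:
    """I.i.d. standard-normal input/target pair (mean 0, s.d. 1)."""
    if in_size <= 0 or out_size <= 0:
        raise ValueError("pattern sizes must be positive")
    rng = np.random.default_rng(seed)
    return PatternPair(rng.normal(0.0, 1.0, in_size), rng.normal(0.0, 1.0, out_size))


def deep_linear_fixture(depth: int, seed: int | None = None, width: int = 64) -> LayeredNetwork:
    """Linear network with ``depth`` weight layers of equal width.

    Xavier-uniform initialized, identity activation; used by the
    interference depth sweep (depths 1..25 at width 64).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return init_network([width] * (depth + 1), activation="linear", seed=seed, init="xavier_uniform")


@dataclass
class SyntheticDataset:
    """Gaussian class blobs with one-hot targets, split train/test.

    A desk-scale classification stand-in for image benchmarks: ``class_count``
    isotropic Gaussian clusters in ``dim`` dimensions whose centers are drawn
    on a sphere of radius ``separation``.  Classes are balanced to within one
    example.
    """

    train_x: np.ndarray  # (n_train, dim)
    train_y: np.ndarray  # (n_train,) integer labels
    test_x: np.ndarray
    test_y: np.ndarray
    class_count: int

    @property
    def dim(self) -> int:
        return self.train_x.shape[1]

    def one_hot(self, labels: np.ndarray) -> np.ndarray:
        out = np.zeros((len(labels), self.class_count))
        out[np.arange(len(labels)), labels] = 1.0
        return out


def synthetic_classification(
    n_train: int = 200,
    n_test: int = 100,
    class_count: int = 2,
    dim: int = 8,
    separation: float = 4.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """Balanced Gaussian-blob classification data with one-hot targets."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, (class_count, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation / 2.0

    def make(n: int) -> tuple[np.ndarray, np.ndarray]:
        # balanced to within one example
        labels = np.array([i % class_count for i in range(n)])
        rng.shuffle(labels)
        x = centers[labels] + rng.normal(0.0, noise_sd, (n, dim))
        return x, labels

    train_x, train_y = make(n_train)
    test_x, test_y = make(n_test)
    return SyntheticDataset(train_x, train_y, test_x, test_y, class_count)
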