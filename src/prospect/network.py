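"""Layered networks shared by both learning rules.

A :class:`LayeredNetwork` is a plain multilayer perceptron skeleton: ``L``
weight matrices ``w^1 .. w^L`` connecting ``L+1`` layers of neurons, with a
single elementwise activation ``f`` applied presynaptically (the input to
layer ``l+1`` is ``w^l f(x^l)``).  There are no bias terms.  The same object
is trained either by prospective configuration (relaxation of a predictive
coding network, :mod:`prospect.pcn`) or by backpropagation
(:mod:`prospect.backprop`), so both rules start from identical weights and
produce identical feedforward predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Activation",
    "ACTIVATIONS",
    "LayeredNetwork",
    "init_network",
    "forward_prediction",
    "DimensionError",
    "InvalidSpecificationError",
]


class DimensionError(ValueError):
    """An array does not match the network geometry."""


class InvalidSpecificationError(ValueError):
    """A network specification is malformed (e.g. non-positive layer size)."""


@dataclass(frozen=True)
class Activation:
    """Named elementwise activation with its derivative."""

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    fprime: Callable[[np.ndarray], np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sigmoid_prime(x: np.ndarray) -> np.ndarray:
    s = _sigmoid(x)
    return s * (1.0 - s)


_LEAKY_SLOPE = 0.01

ACTIVATIONS: dict[str, Activation] = {
    "linear": Activation("linear", lambda x: np.asarray(x, dtype=float), lambda x: np.ones_like(x, dtype=float)),
    "sigmoid": Activation("sigmoid", _sigmoid, _sigmoid_prime),
    "leaky_relu": Activation(
        "leaky_relu",
        lambda x: np.where(x > 0, x, _LEAKY_SLOPE * x),
        lambda x: np.where(x > 0, 1.0, _LEAKY_SLOPE),
    ),
}
# alias used in some configs
ACTIVATIONS["identity"] = ACTIVATIONS["linear"]


def get_activation(name: str) -> Activation:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise InvalidSpecificationError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


@dataclass
class LayeredNetwork:
    """Weights and geometry of a layered network.

    Parameters
    ----------
    layer_sizes
        Number of neurons per layer, ``n^1 .. n^{L+1}``.
    weights
        ``L`` matrices; ``weights[l]`` has shape ``(n^{l+2}, n^{l+1})`` in
        0-based indexing, i.e. it maps layer ``l`` to layer ``l+1``.
    activation
        Elementwise activation shared by all layers.
    weight_masks
        Optional per-layer boolean arrays marking trainable entries; masked
        (False) entries never change.  Used for structurally constrained
        networks such as the diagonal input-to-hidden map in the motor task.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    activation: Activation
    weight_masks: list[np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        sizes = list(self.layer_sizes)
        if len(sizes) < 2:
            raise InvalidSpecificationError("a network needs at least 2 layers")
        if any(int(n) <= 0 for n in sizes):
            raise InvalidSpecificationError(f"layer sizes must be positive, got {sizes}")
        if len(self.weights) != len(sizes) - 1:
            raise InvalidSpecificationError(
                f"expected {len(sizes) - 1} weight matrices, got {len(self.weights)}"
            )
        for l, w in enumerate(self.weights):
            if w.shape != (sizes[l + 1], sizes[l]):
                raise DimensionError(
                    f"weight {l} has shape {w.shape}, expected {(sizes[l + 1], sizes[l])}"
                )
            if not np.all(np.isfinite(w)):
                raise InvalidSpecificationError(f"weight {l} contains non-finite entries")

    @property
    def n_weight_layers(self) -> int:
        return len(self.weights)

    @property
    def in_size(self) -> int:
        return self.layer_sizes[0]

    @property
    def out_size(self) -> int:
        return self.layer_sizes[-1]

    def copy(self) -> "LayeredNetwork":
        masks = None
        if self.weight_masks is not None:
            masks = [m.copy() for m in self.weight_masks]
        return LayeredNetwork(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            self.activation,
            masks,
        )

    def with_weights(self, weights: list[np.ndarray]) -> "LayeredNetwork":
        """A new network sharing geometry/activation but with fresh weights."""
        masks = None
        if self.weight_masks is not None:
            masks = [m.copy() for m in self.weight_masks]
        return LayeredNetwork(list(self.layer_sizes), weights, self.activation, masks)


def init_network(
    layer_sizes: Sequence[int],
    activation: str = "linear",
    init_sd: float | None = None,
    seed: int | None = None,
    init: str = "xavier_normal",
) -> LayeredNetwork:
    """Create a network with randomly initialized weights.

    By default weights are drawn from the Xavier normal distribution,
    ``Normal(0, sd)`` with ``sd = sqrt(2 / (n^l + n^{l+1}))``.  Passing
    ``init_sd`` overrides the per-layer scale with a fixed standard
    deviation, as used by the minimal behavioral networks.
    ``init="xavier_uniform"`` draws from ``Uniform(-b, b)`` with
    ``b = sqrt(6 / (n^l + n^{l+1}))`` instead.
    """
    sizes = [int(n) for n in layer_sizes]
    if any(n <= 0 for n in sizes):
        raise InvalidSpecificationError(f"layer sizes must be positive, got {sizes}")
    if init not in ("xavier_normal", "xavier_uniform"):
        raise InvalidSpecificationError(f"unknown init {init!r}")
    rng = np.random.default_rng(seed)
    weights = []
    for l in range(len(sizes) - 1):
        fan_in, fan_out = sizes[l], sizes[l + 1]
        if init_sd is not None:
            w = rng.normal(0.0, init_sd, size=(fan_out, fan_in)) if init_sd > 0 else np.zeros((fan_out, fan_in))
        elif init == "xavier_uniform":
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        else:
            sd = np.sqrt(2.0 / (fan_in + fan_out))
            w = rng.normal(0.0, sd, size=(fan_out, fan_in))
        weights.append(w)
    return LayeredNetwork(sizes, weights, get_activation(activation))


def _as_columns(x: np.ndarray, expected: int, what: str) -> tuple[np.ndarray, bool]:
    """Promote a 1-D pattern to a single-column matrix; validate the width."""
    arr = np.asarray(x, dtype=float)
    was_1d = arr.ndim == 1
    if was_1d:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[0] != expected:
        raise DimensionError(f"{what} has shape {np.shape(x)}, expected length {expected}")
    return arr, was_1d


def forward_prediction(net: LayeredNetwork, s_in: np.ndarray) -> np.ndarray:
    """Feedforward output ``x^{L+1}`` from ``x^l = w^{l-1} f(x^{l-1})``.

    This is the exact energy minimum of the predictive coding network when
    only the input is clamped: all prediction errors vanish along the chain.
    Accepts a single pattern (1-D) or a batch as columns of a 2-D array.
    """
    x, was_1d = _as_columns(s_in, net.in_size, "input")
    f = net.activation.f
    for w in net.weights:
        x = w @ f(x)
    return x[:, 0] if was_1d else x


def forward_activities(net: LayeredNetwork, s_in: np.ndarray) -> list[np.ndarray]:
    """All layer activities of the feedforward pass (as column matrices)."""
    x, _ = _as_columns(s_in, net.in_size, "input")
    f = net.activation.f
    acts = [x]
    for w in net.weights:
        acts.append(w @ f(acts[-1]))
    return acts
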