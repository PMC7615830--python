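"""Weight-matched backpropagation baseline.

Trains the same :class:`~prospect.network.LayeredNetwork` by plain gradient
descent on the loss ``L = 1/2 ||s_target - x^{L+1}||^2`` of the feedforward
pass, with the error backpropagated layer by layer through the chain rule.
Because prediction is shared code, both learning rules produce identical
outputs from identical weights; they differ only in how they assign credit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DimensionError, LayeredNetwork, _as_columns, forward_activities

__all__ = ["LossValue", "backprop_update", "loss"]


@dataclass
class LossValue:
    """Half squared output error over unmasked outputs."""

    value: float


def _output_mask(mask: np.ndarray | None, n_out: int, batch: int) -> np.ndarray:
    if mask is None:
        return np.ones((n_out, batch), dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if m.ndim == 1:
        if m.shape[0] != n_out:
            raise DimensionError(f"output mask has length {m.shape[0]}, expected {n_out}")
        m = np.broadcast_to(m[:, None], (n_out, batch))
    elif m.shape != (n_out, batch):
        raise DimensionError(f"output mask has shape {m.shape}, expected {(n_out, batch)}")
    return m


def _full_target(target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n_out, batch = mask.shape
    tgt = np.asarray(target, dtype=float)
    if tgt.ndim == 1:
        if tgt.shape[0] == n_out:
            return np.broadcast_to(tgt[:, None], (n_out, batch)).copy()
        counts = mask.sum(axis=0)
        if np.all(counts == counts[0]) and tgt.shape[0] == counts[0] and batch == 1:
            full = np.zeros((n_out, batch))
            full[mask] = tgt
            return full
        raise DimensionError(
            f"target of length {tgt.shape[0]} does not match output width {n_out}"
        )
    if tgt.shape != (n_out, batch):
        raise DimensionError(f"target has shape {tgt.shape}, expected {(n_out, batch)}")
    return tgt.copy()


def backprop_update(
    net: LayeredNetwork,
    s_in: np.ndarray,
    target: np.ndarray,
    alpha: float,
    output_mask: np.ndarray | None = None,
    per_layer_alpha: list[float] | None = None,
) -> LayeredNetwork:
    """One gradient-descent step ``dw^l = -alpha dL/dw^l``.

    Masked-out output neurons contribute zero error.  Batched inputs
    (columns) average the gradient over the batch.  Returns a new network.
    """
    x0, _ = _as_columns(s_in, net.in_size, "input")
    acts = forward_activities(net, x0)
    batch = x0.shape[1]
    mask = _output_mask(output_mask, net.out_size, batch)
    tgt = _full_target(target, mask)

    f, fprime = net.activation.f, net.activation.fprime
    delta = np.where(mask, acts[-1] - tgt, 0.0)  # dL/dx^{L+1}
    alphas = per_layer_alpha if per_layer_alpha is not None else [alpha] * net.n_weight_layers
    if len(alphas) != net.n_weight_layers:
        raise DimensionError(f"need {net.n_weight_layers} per-layer rates, got {len(alphas)}")
    grads: list[np.ndarray] = [np.empty(0)] * net.n_weight_layers
    for l in range(net.n_weight_layers - 1, -1, -1):
        grads[l] = (delta @ f(acts[l]).T) / batch
        if l > 0:
            delta = fprime(acts[l]) * (net.weights[l].T @ delta)
    new_weights = []
    for l, w in enumerate(net.weights):
        dw = -alphas[l] * grads[l]
        if net.weight_masks is not None:
            dw = dw * net.weight_masks[l]
        new_weights.append(w + dw)
    return net.with_weights(new_weights)


def loss(
    net: LayeredNetwork,
    s_in: np.ndarray,
    target: np.ndarray,
    output_mask: np.ndarray | None = None,
) -> LossValue:
    """``L = 1/2 sum (s_target - x^{L+1})^2`` over unmasked outputs (batch mean)."""
    x0, _ = _as_columns(s_in, net.in_size, "input")
    acts = forward_activities(net, x0)
    batch = x0.shape[1]
    mask = _output_mask(output_mask, net.out_size, batch)
    tgt = _full_target(target, mask)
    err = np.where(mask, tgt - acts[-1], 0.0)
    return LossValue(0.5 * float(np.sum(err * err)) / batch)
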