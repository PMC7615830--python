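"""Prospective configuration in predictive coding networks.

The network carries value neurons ``x^l`` and prediction-error neurons
``eps^l = x^l - w^{l-1} f(x^{l-1})``, and both its inference and its
learning descend the energy

    E = sum_l E^l,   E^l = 1/2 ||x^l - w^{l-1} f(x^{l-1})||^2 .

Learning a pattern pair proceeds in two phases:

1. *Relaxation* (neural dynamics): the input layer is clamped to the
   stimulus and the (masked) output neurons to the target; the remaining
   activities follow ``dx^l = gamma (-eps^l + f'(x^l) o (w^l)^T eps^{l+1})``
   until the activity settles into the *prospective* state -- the pattern of
   activity the network should produce once learning has succeeded.
2. *Weight consolidation* (weight dynamics): a single Hebbian step
   ``dw^l = alpha eps^{l+1} (f(x^l))^T`` evaluated at the relaxed state.

Both phases are exact gradient flows on E (in x and w respectively), which
the test-suite checks against central-difference gradients.

All operations accept a single pattern (1-D arrays) or a batch of patterns
stored as the columns of 2-D arrays; batched weight updates are averaged
over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    DimensionError,
    LayeredNetwork,
    _as_columns,
    forward_activities,
)

__all__ = [
    "NetworkState",
    "ClampSpec",
    "RelaxationConfig",
    "EnergyReport",
    "RelaxationResult",
    "DivergenceError",
    "compute_errors",
    "energy",
    "relaxation_step",
    "relax",
    "weight_update",
    "learn",
]


class DivergenceError(FloatingPointError):
    """Relaxation produced non-finite activities."""


@dataclass
class NetworkState:
    """Per-layer activities and prediction errors during relaxation.

    ``activities[l]`` is the value-neuron activity of layer ``l`` (0-based;
    shape ``(n^l, batch)``); ``errors[l]`` is the prediction error of layer
    ``l+1``, i.e. ``errors[l] = activities[l+1] - w^l f(activities[l])``.
    """

    activities: list[np.ndarray]
    errors: list[np.ndarray] = field(default_factory=list)

    @property
    def batch_size(self) -> int:
        return self.activities[0].shape[1]

    def output(self) -> np.ndarray:
        return self.activities[-1]

    def copy(self) -> "NetworkState":
        return NetworkState([a.copy() for a in self.activities], [e.copy() for e in self.errors])


@dataclass
class ClampSpec:
    """Which neurons are clamped during relaxation.

    The input layer is always clamped.  ``output_mask`` marks the output
    neurons held at target values: an all-true mask is full clamping, an
    all-false mask leaves the output free (prediction mode).  A 2-D mask
    (``n_out x batch``) gives per-example clamping, as used when training a
    value network on one action's output at a time.  Hidden layers are never
    clamped.
    """

    output_mask: np.ndarray
    input_clamped: bool = True

    @classmethod
    def full(cls, n_out: int) -> "ClampSpec":
        return cls(np.ones(n_out, dtype=bool))

    @classmethod
    def free(cls, n_out: int) -> "ClampSpec":
        return cls(np.zeros(n_out, dtype=bool))


@dataclass
class RelaxationConfig:
    """Numerical schedule of the relaxation.

    gamma0 : initial integration step of the neural dynamics (default 0.1).
    max_steps : maximum number of relaxation sweeps (default 128).
    adaptive : if True, whenever a sweep fails to decrease the total energy
        the step is halved; relaxation stops early at the second halving
        (for gamma0 = 0.1 that is when the step reaches 0.025).  The RL
        configuration instead uses a fixed gamma = 0.05 for 32 sweeps.
    """

    gamma0: float = 0.1
    max_steps: int = 128
    halving_factor: float = 0.5
    max_halvings: int = 2
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be positive")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")

    @classmethod
    def rl_defaults(cls) -> "RelaxationConfig":
        return cls(gamma0=0.05, max_steps=32, adaptive=False)


@dataclass
class EnergyReport:
    """Total energy and its decomposition into local layer terms."""

    per_layer: list[float]
    total: float


@dataclass
class RelaxationResult:
    """Converged state plus the trace of the relaxation.

    ``gamma_trace`` records the step size of each applied sweep;
    ``final_gamma`` is the step size when relaxation ended (after an early
    stop this is the post-halving value at which no further sweep was taken).
    """

    state: NetworkState
    steps: int
    energy_trace: list[float]
    gamma_trace: list[float]
    final_gamma: float


def compute_errors(net: LayeredNetwork, state: NetworkState) -> NetworkState:
    """Set ``eps^{l+1} = x^{l+1} - w^l f(x^l)`` for every weight layer (in place)."""
    f = net.activation.f
    state.errors = [
        state.activities[l + 1] - net.weights[l] @ f(state.activities[l])
        for l in range(net.n_weight_layers)
    ]
    return state


def energy(net: LayeredNetwork, state: NetworkState) -> EnergyReport:
    """Energy ``E^l = 1/2 ||eps^l||^2`` per layer and its sum (summed over a batch)."""
    f = net.activation.f
    per_layer = []
    for l in range(net.n_weight_layers):
        eps = state.activities[l + 1] - net.weights[l] @ f(state.activities[l])
        per_layer.append(0.5 * float(np.sum(eps * eps)))
    return EnergyReport(per_layer, float(sum(per_layer)))


def _total_energy(state: NetworkState) -> float:
    """Total energy from already-computed errors (avoids re-deriving them)."""
    with np.errstate(over="ignore"):  # overflow surfaces as inf -> DivergenceError
        return 0.5 * float(sum(np.sum(e * e) for e in state.errors))


def _broadcast_mask(mask: np.ndarray, n_out: int, batch: int) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.ndim == 1:
        if m.shape[0] != n_out:
            raise DimensionError(f"output mask has length {m.shape[0]}, expected {n_out}")
        m = np.broadcast_to(m[:, None], (n_out, batch))
    elif m.shape != (n_out, batch):
        raise DimensionError(f"output mask has shape {m.shape}, expected {(n_out, batch)}")
    return m


def relaxation_step(
    net: LayeredNetwork,
    state: NetworkState,
    clamp: ClampSpec,
    gamma: float,
) -> NetworkState:
    """One sweep of the neural dynamics (in place).

    For each unclamped layer, ``dx^l = gamma (-eps^l + f'(x^l) o (w^l)^T
    eps^{l+1})``; the feedback term is absent at the top layer, so free
    output neurons move as ``dx^{L+1} = -gamma eps^{L+1}``.  Clamped neurons
    (the input layer and masked outputs) are left untouched.  ``state.errors``
    must have been computed for the current activities.
    """
    fprime = net.activation.fprime
    L = net.n_weight_layers
    for l in range(1, L):
        dx = gamma * (
            -state.errors[l - 1]
            + fprime(state.activities[l]) * (net.weights[l].T @ state.errors[l])
        )
        state.activities[l] = state.activities[l] + dx
    n_out, batch = state.activities[-1].shape
    mask = _broadcast_mask(clamp.output_mask, n_out, batch)
    free = ~mask
    if free.any():
        top = state.activities[-1].copy()
        top[free] += (-gamma * state.errors[L - 1])[free]
        state.activities[-1] = top
    return state


def _init_state(
    net: LayeredNetwork,
    s_in: np.ndarray,
    target: np.ndarray | None,
    mask: np.ndarray,
) -> NetworkState:
    x0, _ = _as_columns(s_in, net.in_size, "input")
    batch = x0.shape[1]
    acts = [x0.copy()]
    for n in net.layer_sizes[1:]:
        acts.append(np.zeros((n, batch)))
    if mask.any():
        if target is None:
            raise DimensionError("target required when any output neuron is clamped")
        tgt = _expand_target(target, mask)
        acts[-1][mask] = tgt[mask]
    return NetworkState(acts)


def _expand_target(target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Return a full-width target matrix matching ``mask``'s shape.

    Accepts a full-width target (1-D of length n_out or n_out x batch), or a
    compact 1-D vector holding one value per masked-true output.
    """
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
            f"target of length {tgt.shape[0]} does not match output width {n_out} "
            f"or the clamped-output count"
        )
    if tgt.shape != (n_out, batch):
        raise DimensionError(f"target has shape {tgt.shape}, expected {(n_out, batch)}")
    return tgt.copy()


def relax(
    net: LayeredNetwork,
    s_in: np.ndarray,
    target: np.ndarray | None = None,
    clamp: ClampSpec | None = None,
    config: RelaxationConfig | None = None,
) -> RelaxationResult:
    """Run relaxation to the prospective state.

    Activities start from the clamped input/target with hidden layers (and
    free outputs) at zero, then follow the neural dynamics for up to
    ``config.max_steps`` sweeps.  In adaptive mode, any sweep that fails to
    decrease the total energy halves the integration step, and relaxation
    terminates early at the second halving.  The returned result carries the
    settled state (with errors consistent with the final activities), the
    number of sweeps applied and the energy/step-size traces.
    """
    if config is None:
        config = RelaxationConfig()
    if clamp is None:
        clamp = ClampSpec.full(net.out_size) if target is not None else ClampSpec.free(net.out_size)
    x0, _ = _as_columns(s_in, net.in_size, "input")
    mask = _broadcast_mask(clamp.output_mask, net.out_size, x0.shape[1])
    state = _init_state(net, x0, target, mask)
    eff_clamp = ClampSpec(mask)

    gamma = config.gamma0
    halvings = 0
    prev_energy = None
    energy_trace: list[float] = []
    gamma_trace: list[float] = []
    steps = 0
    for t in range(config.max_steps):
        compute_errors(net, state)
        e = _total_energy(state)
        if not np.isfinite(e):
            raise DivergenceError(f"relaxation diverged at sweep {t}")
        energy_trace.append(e)
        if config.adaptive and prev_energy is not None and e >= prev_energy:
            gamma *= config.halving_factor
            halvings += 1
            if halvings >= config.max_halvings:
                break
        prev_energy = e
        gamma_trace.append(gamma)
        relaxation_step(net, state, eff_clamp, gamma)
        steps += 1
    compute_errors(net, state)
    final_e = _total_energy(state)
    if not np.isfinite(final_e):
        raise DivergenceError(f"relaxation diverged at sweep {steps}")
    energy_trace.append(final_e)
    return RelaxationResult(state, steps, energy_trace, gamma_trace, gamma)


def weight_update(
    net: LayeredNetwork,
    state: NetworkState,
    alpha: float,
    per_layer_alpha: list[float] | None = None,
) -> LayeredNetwork:
    """Hebbian consolidation ``dw^l = alpha_l eps^{l+1} (f(x^l))^T``.

    The state must be the converged relaxation state; batched updates are
    averaged over the batch.  Returns a new network (the input is untouched);
    structurally masked weight entries stay fixed.
    """
    if len(state.errors) != net.n_weight_layers:
        raise DimensionError("state errors not computed; call compute_errors first")
    alphas = per_layer_alpha if per_layer_alpha is not None else [alpha] * net.n_weight_layers
    if len(alphas) != net.n_weight_layers:
        raise DimensionError(f"need {net.n_weight_layers} per-layer rates, got {len(alphas)}")
    f = net.activation.f
    batch = state.batch_size
    new_weights = []
    for l, w in enumerate(net.weights):
        dw = alphas[l] * (state.errors[l] @ f(state.activities[l]).T) / batch
        if net.weight_masks is not None:
            dw = dw * net.weight_masks[l]
        new_weights.append(w + dw)
    return net.with_weights(new_weights)


def learn(
    net: LayeredNetwork,
    s_in: np.ndarray,
    target: np.ndarray,
    alpha: float,
    config: RelaxationConfig | None = None,
    output_mask: np.ndarray | None = None,
    per_layer_alpha: list[float] | None = None,
) -> LayeredNetwork:
    """One prospective-configuration learning step: relax, then consolidate.

    ``output_mask`` restricts which outputs are clamped to the target; free
    output neurons take part in the relaxation and generate their own
    prediction errors, which is what lets the network reassign credit to
    outputs that were not supervised on this trial.
    """
    clamp = ClampSpec(output_mask) if output_mask is not None else ClampSpec.full(net.out_size)
    result = relax(net, s_in, target, clamp, config)
    return weight_update(net, result.state, alpha, per_layer_alpha)


def free_state(net: LayeredNetwork, s_in: np.ndarray) -> NetworkState:
    """The energy minimum with only the input clamped: the feedforward pass."""
    state = NetworkState(forward_activities(net, s_in))
    return compute_errors(net, state)
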