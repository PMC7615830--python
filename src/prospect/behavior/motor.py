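"""Minimal-network simulation of contextual sensorimotor learning.

The model is a 2-2-2 linear network: the input neurons encode the blue/red
background, the hidden neurons the *belief* of being in the blue or red
context ([B], [R]) -- input to hidden is one-to-one (diagonal) -- and the
output neurons the predicted perturbation in the + and - directions (hidden
to output fully connected).  Each trial is a supervised learning step with
the chosen rule: inputs B -> [1,0], R -> [0,1]; targets + -> [1,0],
- -> [0,1], no perturbation -> [0,0].  Layer learning rates are
independent, reflecting different plasticity from perception to belief and
from belief to prediction.

The predicted perturbation is the difference between the two output
activities, and the adaptation change of a test triplet is the absolute
difference of this (free, measured before that trial's learning step)
prediction between the triplet's two B0 probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import backprop, pcn
from ..network import ACTIVATIONS, LayeredNetwork, forward_prediction
from .schedule import TEST_COMBINATIONS, build_motor_schedule

__all__ = ["motor_network", "run_motor_experiment", "MotorResult"]

_INPUTS = {"B": np.array([1.0, 0.0]), "R": np.array([0.0, 1.0])}
_TARGETS = {"+": np.array([1.0, 0.0]), "-": np.array([0.0, 1.0]), "0": np.array([0.0, 0.0])}


def motor_network(seed: int, init_sd: float, activation: str = "linear") -> LayeredNetwork:
    """2-2-2 network with a diagonal (structurally fixed) input->hidden map.

    Off-diagonal input->hidden entries are zero and never updated; all
    trainable weights are drawn Normal(0, init_sd).
    """
    rng = np.random.default_rng(seed)
    w1 = np.diag(rng.normal(0.0, init_sd, 2)) if init_sd > 0 else np.zeros((2, 2))
    w2 = rng.normal(0.0, init_sd, (2, 2)) if init_sd > 0 else np.zeros((2, 2))
    net = LayeredNetwork([2, 2, 2], [w1, w2], ACTIVATIONS[activation])
    net.weight_masks = [np.eye(2, dtype=bool), np.ones((2, 2), dtype=bool)]
    return net


def _perturbation_prediction(net: LayeredNetwork, background: str) -> float:
    out = forward_prediction(net, _INPUTS[background])
    return float(out[0] - out[1])


@dataclass
class MotorResult:
    """Mean adaptation change per test combination, with per-triplet records."""

    mean_change: dict[str, float]
    records: pd.DataFrame = field(repr=False, default=None)

    def as_vector(self, order=TEST_COMBINATIONS) -> np.ndarray:
        return np.array([self.mean_change[c] for c in order])


def run_motor_experiment(
    rule: str,
    init_sd: float,
    lr_layer1: float,
    lr_layer2: float,
    n_participants: int = 24,
    seed: int = 0,
    config: pcn.RelaxationConfig | None = None,
) -> MotorResult:
    """Run the full schedule for each participant and measure test triplets.

    Every trial (probes and washout included) trains the network on its
    input/target pair with the chosen rule; unperturbed trials use target
    [0, 0].  The free perturbation prediction on each testing-triplet B0
    probe is recorded before that trial's learning step; the absolute
    difference within a triplet, averaged over triplets of the same
    combination and over participants, is the adaptation change.
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    rates = [lr_layer1, lr_layer2]
    rows = []
    root = np.random.SeedSequence(seed)
    for participant, child in enumerate(root.spawn(n_participants)):
        net_seed, sched_seed = (int(s) % (2**31) for s in child.generate_state(2))
        net = motor_network(net_seed, init_sd)
        schedule = build_motor_schedule(sched_seed, participant)
        pre_prediction: float | None = None
        for trial in schedule.trials:
            if trial.session == "testing" and trial.role in ("triplet_pre", "triplet_post"):
                prediction = _perturbation_prediction(net, trial.background)
                if trial.role == "triplet_pre":
                    pre_prediction = prediction
                else:
                    rows.append(
                        {
                            "participant": participant,
                            "combination": trial.combination,
                            "block": trial.block,
                            "change": abs(prediction - pre_prediction),
                        }
                    )
            s_in = _INPUTS[trial.background]
            target = _TARGETS[trial.perturbation]
            if rule == "pc":
                net = pcn.learn(net, s_in, target, alpha=0.0, config=config, per_layer_alpha=rates)
            else:
                net = backprop.backprop_update(net, s_in, target, alpha=0.0, per_layer_alpha=rates)
        if pre_prediction is None:
            raise RuntimeError("schedule contained no testing triplets")
    records = pd.DataFrame(rows)
    mean_change = {c: float(records.loc[records.combination == c, "change"].mean()) for c in TEST_COMBINATIONS}
    return MotorResult(mean_change, records)
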