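"""Interference metrics: target alignment and the learning-step harness.

Interference is quantified by the angle, in output space, between the
direction toward the target and the direction the output actually moves
after one weight update; *target alignment* is the cosine of that angle.
Alignment 1 means the update moves the output straight at the target (no
interference); lower values mean updates aimed at correcting some outputs
degrade others.  Both predictions are measured free (without the target
provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import backprop, pcn
from .network import LayeredNetwork, forward_prediction

__all__ = ["target_alignment", "measure_learning_step", "LearningStepRecord", "depth_sweep"]


def target_alignment(
    y_before: np.ndarray, y_after: np.ndarray, target: np.ndarray
) -> float:
    """Cosine between ``target - y_before`` and ``y_after - y_before``.

    Returns ``nan`` (an explicitly missing value, never 0) when either
    direction vector has zero norm, since the alignment is then undefined.
    """
    y_before = np.asarray(y_before, dtype=float).ravel()
    y_after = np.asarray(y_after, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if not (y_before.shape == y_after.shape == target.shape):
        raise ValueError("alignment arguments must have equal length")
    to_target = target - y_before
    learning = y_after - y_before
    n1 = np.linalg.norm(to_target)
    n2 = np.linalg.norm(learning)
    if n1 == 0.0 or n2 == 0.0:
        return math.nan
    return float(np.dot(to_target, learning) / (n1 * n2))


@dataclass
class LearningStepRecord:
    y_before: np.ndarray
    y_after: np.ndarray
    alignment: float
    loss_before: float
    loss_after: float


def measure_learning_step(
    net: LayeredNetwork,
    rule: str,
    s_in: np.ndarray,
    target: np.ndarray,
    alpha: float,
    config: pcn.RelaxationConfig | None = None,
) -> LearningStepRecord:
    """Free prediction, one weight update by ``rule``, free prediction again.

    The input network is left unmodified; a copy is trained.
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    y_before = forward_prediction(net, s_in)
    if rule == "pc":
        trained = pcn.learn(net.copy(), s_in, target, alpha, config)
    else:
        trained = backprop.backprop_update(net.copy(), s_in, target, alpha)
    y_after = forward_prediction(trained, s_in)
    return LearningStepRecord(
        y_before=y_before,
        y_after=y_after,
        alignment=target_alignment(y_before, y_after, target),
        loss_before=backprop.loss(net, s_in, target).value,
        loss_after=backprop.loss(trained, s_in, target).value,
    )


def depth_sweep(
    depths=range(1, 26),
    n_seeds: int = 27,
    width: int = 64,
    alpha: float = 0.001,
    base_seed: int = 0,
    rules: tuple[str, ...] = ("pc", "bp"),
    config: pcn.RelaxationConfig | None = None,
) -> pd.DataFrame:
    """Target alignment of random deep linear networks, one update per net.

    For each depth and seed, a linear ``width``-wide network is built
    (Xavier uniform init), a random standard-normal pattern pair is drawn,
    and the alignment after one update is recorded for each rule starting
    from identical weights.  Returns a tidy frame (depth, seed, rule,
    alignment).
    """
    from .fixtures import deep_linear_fixture, random_pattern_pair

    rows = []
    for depth in depths:
        for s in range(n_seeds):
            seed = base_seed + 1000 * depth + s
            net = deep_linear_fixture(depth, seed=seed, width=width)
            pair = random_pattern_pair(width, width, seed=seed + 500000)
            for rule in rules:
                rec = measure_learning_step(net, rule, pair.s_in, pair.s_target, alpha, config)
                rows.append(
                    {"depth": depth, "seed": s, "rule": rule, "alignment": rec.alignment}
                )
    return pd.DataFrame(rows)
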