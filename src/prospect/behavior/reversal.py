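"""Minimal-network simulation of probabilistic reversal learning.

Two options pay reward (+1) or punishment (-1); one option has the higher
reward probability and the probabilities are occasionally swapped, so the
values of the options are negatively correlated.  The model is a 1-1-2
linear network: a single input neuron encodes being in the task (always 1),
one hidden neuron the latent state of which option is currently superior,
and the two outputs the predicted value of each option.  Choices are drawn
from a softmax (temperature 1) over the two predicted values; the learning
step clamps the chosen option's output to the outcome (prospective
configuration leaves the other output free; backpropagation masks its
error).

The readout compares the chosen-option value signal on consecutive trial
pairs that start with a punishment: if the next choice repeats the option
("stay") versus takes the other option ("switch").  Prospective
configuration raises the value estimate of the alternative after a
punishment -- it infers a flip of the latent state -- so the switch-trial
signal exceeds the preceding punish-trial signal, while backpropagation
only depresses the punished option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import backprop, pcn
from ..network import LayeredNetwork, forward_prediction, init_network

__all__ = [
    "ReversalEnvironment",
    "reversal_environment",
    "softmax_choice",
    "run_reversal_experiment",
    "ReversalResult",
    "ChoiceTrialRecord",
]

TRIAL_TYPES = ("punish_stay", "stay", "punish_switch", "switch")


class ReversalEnvironment:
    """Two-option reward sampler with periodic probability reversals.

    The chosen option yields +1 with its current probability, else -1.
    When the schedule reverses, the two probabilities are swapped, so they
    always sum to ``p_high + p_low``.
    """

    def __init__(self, p_high: float = 0.8, p_low: float = 0.2, reversal_period: int = 20, seed: int | None = None):
        if not (0.0 <= p_low < p_high <= 1.0):
            raise ValueError("need 0 <= p_low < p_high <= 1")
        if reversal_period <= 0:
            raise ValueError("reversal_period must be positive")
        self.p_high = p_high
        self.p_low = p_low
        self.reversal_period = reversal_period
        self._rng = np.random.default_rng(seed)
        self._probs = np.array([p_high, p_low])
        self._trial = 0

    @property
    def probabilities(self) -> np.ndarray:
        return self._probs.copy()

    def sample(self, choice: int) -> int:
        """Outcome (+1 reward / -1 punishment) of choosing option ``choice``."""
        if choice not in (0, 1):
            raise ValueError("choice must be 0 or 1")
        outcome = 1 if self._rng.random() < self._probs[choice] else -1
        self._trial += 1
        if self._trial % self.reversal_period == 0:
            self._probs = self._probs[::-1].copy()
        return outcome


def reversal_environment(
    p_high: float = 0.8, p_low: float = 0.2, reversal_period: int = 20, seed: int | None = None
) -> ReversalEnvironment:
    return ReversalEnvironment(p_high, p_low, reversal_period, seed)


def softmax_choice(values: np.ndarray, temperature: float = 1.0, rng: np.random.Generator | None = None) -> int:
    """Sample an option index with P(i) proportional to exp(v_i / T)."""
    v = np.asarray(values, dtype=float) / temperature
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax values must be finite")
    v = v - v.max()
    p = np.exp(v)
    p /= p.sum()
    rng = rng if rng is not None else np.random.default_rng()
    return int(rng.choice(len(p), p=p))


@dataclass(frozen=True)
class ChoiceTrialRecord:
    """One trial of the reversal task, with the next-choice relation."""

    trial: int
    choice: int
    outcome: int
    signal: float  # chosen-option output activity at choice time
    relation: str  # "stay", "switch" or "undefined" (final trial)


@dataclass
class ReversalResult:
    """Mean chosen-option value signal for the four trial types."""

    mean_signal: dict[str, float]
    records: pd.DataFrame = field(repr=False, default=None)

    def as_vector(self, order=TRIAL_TYPES) -> np.ndarray:
        return np.array([self.mean_signal[t] for t in order])


def run_reversal_experiment(
    rule: str,
    init_sd: float,
    alpha: float,
    n_participants: int = 16,
    n_trials: int = 128,
    p_high: float = 0.8,
    p_low: float = 0.2,
    reversal_period: int = 20,
    seed: int = 0,
    config: pcn.RelaxationConfig | None = None,
) -> ReversalResult:
    """Simulate all participants and average the four trial-type signals.

    Signals are grouped from consecutive pairs whose first trial was
    punished: the punish trial's signal goes to ``punish_stay`` or
    ``punish_switch`` according to the next choice, and the next trial's
    signal to ``stay`` or ``switch``.
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    s_in = np.array([1.0])
    rows = []
    root = np.random.SeedSequence(seed)
    for participant, child in enumerate(root.spawn(n_participants)):
        net_seed, env_seed, choice_seed = (int(s) % (2**31) for s in child.generate_state(3))
        net = init_network([1, 1, 2], activation="linear", init_sd=init_sd, seed=net_seed)
        env = ReversalEnvironment(p_high, p_low, reversal_period, env_seed)
        rng = np.random.default_rng(choice_seed)
        choices = np.empty(n_trials, dtype=int)
        outcomes = np.empty(n_trials, dtype=int)
        signals = np.empty(n_trials)
        for t in range(n_trials):
            values = forward_prediction(net, s_in)
            choice = softmax_choice(values, 1.0, rng)
            outcome = env.sample(choice)
            choices[t], outcomes[t], signals[t] = choice, outcome, values[choice]
            mask = np.zeros(2, dtype=bool)
            mask[choice] = True
            target = np.zeros(2)
            target[choice] = float(outcome)
            if rule == "pc":
                net = pcn.learn(net, s_in, target, alpha, config, output_mask=mask)
            else:
                net = backprop.backprop_update(net, s_in, target, alpha, output_mask=mask)
        for t in range(n_trials):
            relation = "undefined" if t == n_trials - 1 else ("stay" if choices[t + 1] == choices[t] else "switch")
            rows.append(
                {
                    "participant": participant,
                    "trial": t,
                    "choice": int(choices[t]),
                    "outcome": int(outcomes[t]),
                    "signal": float(signals[t]),
                    "relation": relation,
                }
            )
    records = pd.DataFrame(rows)
    punished = (records.outcome == -1) & (records.relation != "undefined")
    nxt = records.shift(-1)  # next trial of the same participant (pairs never cross participants: relation=="undefined" at the last trial)
    mean_signal = {
        "punish_stay": float(records.loc[punished & (records.relation == "stay"), "signal"].mean()),
        "stay": float(nxt.loc[punished & (records.relation == "stay"), "signal"].mean()),
        "punish_switch": float(records.loc[punished & (records.relation == "switch"), "signal"].mean()),
        "switch": float(nxt.loc[punished & (records.relation == "switch"), "signal"].mean()),
    }
    return ReversalResult(mean_signal, records)
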