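"""Trial schedule of the contextual sensorimotor-learning experiment.

Participants move a stick to a target under force perturbations whose
direction (+ or -) is tied to a background color (blue B or red R): during
training, B comes with + and R with -.  Single-trial learning is probed by
*triplets* -- an unperturbed B0 probe, one exposure trial, and a second B0
probe -- so the change in predicted perturbation between the two probes
measures what that one exposure taught about the blue context.

A participant's schedule has a training stage of 24 blocks followed by a
testing stage of 8 repetitions of the 4 test combinations (B+, R+, B-, R-).
Washout lengths are sampled without replacement from small sets that are
replenished when exhausted, and binary design choices (B0/R0 pair order,
which exposure a training triplet uses) are counterbalanced across
consecutive blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MotorTrial", "MotorSchedule", "build_motor_schedule", "TEST_COMBINATIONS"]

TEST_COMBINATIONS = ("B+", "R+", "B-", "R-")


@dataclass(frozen=True)
class MotorTrial:
    """One trial: a background color, a perturbation direction and context.

    ``role`` marks triplet structure (``triplet_pre`` / ``triplet_exposure``
    / ``triplet_post``); ``combination`` is set on triplet trials to the
    exposure combination the triplet probes.  ``block`` indexes the block
    within its stage.
    """

    background: str  # "B" or "R"
    perturbation: str  # "+", "-" or "0"
    session: str  # "training", "washout" or "testing"
    role: str = "standard"
    block: int = -1
    combination: str = ""

    @property
    def name(self) -> str:
        return f"{self.background}{self.perturbation}"


class _ReplenishingBag:
    """Sampling without replacement from a small set, refilled when empty."""

    def __init__(self, values, rng: np.random.Generator):
        self._values = list(values)
        self._rng = rng
        self._bag: list[int] = []

    def draw(self) -> int:
        if not self._bag:
            self._bag = list(self._values)
            self._rng.shuffle(self._bag)
        return self._bag.pop()


@dataclass
class MotorSchedule:
    trials: list[MotorTrial]
    participant: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "trial": np.arange(len(self.trials)),
                "session": [t.session for t in self.trials],
                "background": [t.background for t in self.trials],
                "perturbation": [t.perturbation for t in self.trials],
                "role": [t.role for t in self.trials],
                "block": [t.block for t in self.trials],
                "combination": [t.combination for t in self.trials],
            }
        )


def _pair(first_B: bool, session: str, block: int) -> list[MotorTrial]:
    b0 = MotorTrial("B", "0", session, block=block)
    r0 = MotorTrial("R", "0", session, block=block)
    return [b0, r0] if first_B else [r0, b0]


def _washout(n: int, rng: np.random.Generator, block: int) -> list[MotorTrial]:
    # equal numbers of B0 and R0 in pseudorandom order
    names = ["B"] * (n // 2) + ["R"] * (n // 2)
    rng.shuffle(names)
    return [MotorTrial(b, "0", "washout", block=block) for b in names]


def _perturbation_section(rng: np.random.Generator, block: int) -> list[MotorTrial]:
    # 32 trials; every consecutive 8 hold 4 B+ and 4 R- in pseudorandom order
    trials: list[MotorTrial] = []
    for _ in range(4):
        chunk = ["B+"] * 4 + ["R-"] * 4
        rng.shuffle(chunk)
        for name in chunk:
            trials.append(MotorTrial(name[0], name[1], "training", block=block))
    return trials


def _triplet(exposure: str, session: str, block: int) -> list[MotorTrial]:
    return [
        MotorTrial("B", "0", session, role="triplet_pre", block=block, combination=exposure),
        MotorTrial(exposure[0], exposure[1], session, role="triplet_exposure", block=block, combination=exposure),
        MotorTrial("B", "0", session, role="triplet_post", block=block, combination=exposure),
    ]


def build_motor_schedule(seed: int, participant: int = 0) -> MotorSchedule:
    """Full trial sequence for one simulated participant.

    Training: 24 blocks of [counterbalanced B0/R0 pair; 32 perturbation
    trials (4 B+ and 4 R- per consecutive 8); B0/R0 pair; washout of
    {14,16,18} trials; a triplet whose exposure alternates between B+ and
    R-; washout of {6,8,10}; a triplet with the other exposure].  Testing:
    8 repetitions of the 4 combinations in shuffled order, each preceded by
    a washout of {2,4,6} trials.  Counterbalanced binary choices alternate
    across consecutive blocks, with the starting arm set by participant
    parity.
    """
    rng = np.random.default_rng(seed)
    long_washout = _ReplenishingBag([14, 16, 18], rng)
    short_washout = _ReplenishingBag([6, 8, 10], rng)
    test_washout = _ReplenishingBag([2, 4, 6], rng)

    trials: list[MotorTrial] = []
    pair_first_B = participant % 2 == 0
    exposure_first_Bplus = participant % 2 == 0
    for block in range(24):
        first_B = pair_first_B if block % 2 == 0 else not pair_first_B
        first_exposure = "B+" if (exposure_first_Bplus if block % 2 == 0 else not exposure_first_Bplus) else "R-"
        second_exposure = "R-" if first_exposure == "B+" else "B+"
        trials += _pair(first_B, "training", block)
        trials += _perturbation_section(rng, block)
        trials += _pair(first_B, "training", block)
        trials += _washout(long_washout.draw(), rng, block)
        trials += _triplet(first_exposure, "training", block)
        trials += _washout(short_washout.draw(), rng, block)
        trials += _triplet(second_exposure, "training", block)

    # testing blocks are numbered from 100 so they never collide with the
    # training blocks 0..23 in per-block analyses
    block_index = 100
    for _ in range(8):
        order = list(TEST_COMBINATIONS)
        rng.shuffle(order)
        for combination in order:
            trials += _washout(test_washout.draw(), rng, block_index)
            trials += _triplet(combination, "testing", block_index)
            block_index += 1
    return MotorSchedule(trials, participant, seed)
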