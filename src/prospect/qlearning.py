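"""Q-learning with experience replay for either learning rule.

A value network maps a (normalized) observation to one Q value per action.
Episodes are rolled out epsilon-greedily with an annealed exploration
probability; transitions go to a FIFO replay buffer, and once the buffer
passes its training threshold each episode ends with several replay epochs
of minibatch training.  The replay target is the one-step bootstrap

    R_hat = r_t                                  if terminal
          = r_t + discount * max_a Q(s_{t+1},a)  otherwise,

and only the chosen action's output is supervised: prospective
configuration leaves the other outputs free during relaxation, while
backpropagation masks their error.  Observations are normalized to mean 0
and s.d. 1 with Welford's online algorithm; statistics update on every
observed state, transitions store raw observations, and normalization is
applied with the current statistics at replay time.

Environments plug in through a minimal contract: ``reset() -> observation``
and ``step(action) -> (observation, reward, terminal)``.  A deterministic
two-state chain environment is built in so the loop can be validated
against exact value iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Protocol

import numpy as np

from . import backprop, pcn
from .network import LayeredNetwork, forward_prediction, init_network

__all__ = [
    "Transition",
    "ReplayBuffer",
    "WelfordNormalizer",
    "QConfig",
    "Environment",
    "ToyChainEnv",
    "epsilon",
    "q_target",
    "masked_q_learn",
    "q_learning_loop",
    "greedy_policy",
]


class Environment(Protocol):
    """Minimal reset/step contract for pluggable environments."""

    def reset(self) -> np.ndarray: ...

    def step(self, action: int) -> tuple[np.ndarray, float, bool]: ...


class Transition(NamedTuple):
    s_t: np.ndarray
    a_t: int
    r_t: float
    s_next: np.ndarray
    d_t: bool


class ReplayBuffer:
    """FIFO ring store of transitions."""

    def __init__(self, capacity: int = 50000):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._store: list[Transition] = []
        self._next = 0

    def __len__(self) -> int:
        return len(self._store)

    def add(self, t: Transition) -> None:
        if len(self._store) < self.capacity:
            self._store.append(t)
        else:
            self._store[self._next] = t
            self._next = (self._next + 1) % self.capacity

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._store), size=n)
        return [self._store[i] for i in idx]


class WelfordNormalizer:
    """Streaming per-entry mean/variance for observation normalization.

    Welford's update keeps the running mean and the sum of squared
    deviations M2; after n updates these equal the two-pass batch
    statistics.  ``apply`` standardizes with an s.d. floor so constant
    entries normalize to 0.
    """

    def __init__(self, dim: int, sd_floor: float = 1e-8):
        self.count = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)
        self.sd_floor = sd_floor

    def update(self, obs: np.ndarray) -> "WelfordNormalizer":
        obs = np.asarray(obs, dtype=float)
        self.count += 1
        delta = obs - self.mean
        self.mean = self.mean + delta / self.count
        self.m2 = self.m2 + delta * (obs - self.mean)
        return self

    @property
    def variance(self) -> np.ndarray:
        if self.count < 2:
            return np.zeros_like(self.mean)
        return self.m2 / self.count

    def apply(self, obs: np.ndarray) -> np.ndarray:
        sd = np.sqrt(self.variance)
        sd = np.maximum(sd, self.sd_floor)
        obs = np.asarray(obs, dtype=float)
        if obs.ndim == 1:
            return (obs - self.mean) / sd
        return (obs - self.mean[:, None]) / sd[:, None]


@dataclass
class QConfig:
    """Q-learning hyperparameters (defaults are the reference settings).

    The prospective-configuration rule uses a fixed, shorter relaxation
    (gamma 0.05 for 32 sweeps, non-adaptive) because bootstrapped value
    targets make training less stable and more expensive than supervised
    learning.  ``hidden`` sets the value-network body (two hidden layers of
    64 by default); ``train_threshold`` is the buffer size above which
    replay training starts.
    """

    episodes: int = 10000
    discount: float = 0.98
    minibatch: int = 60
    replay_epochs: int = 10
    capacity: int = 50000
    train_threshold: int = 2000
    hidden: tuple[int, ...] = (64, 64)
    epsilon_start: float = 0.08
    epsilon_floor: float = 0.01
    epsilon_slope: float = 0.01
    epsilon_scale: float = 200.0
    relaxation: pcn.RelaxationConfig = field(default_factory=pcn.RelaxationConfig.rl_defaults)


def epsilon(episode: int, config: QConfig | None = None) -> float:
    """Annealed exploration probability: max(0.01, 0.08 - 0.01*(episode/200))."""
    if episode < 0:
        raise ValueError("episode must be >= 0")
    c = config if config is not None else QConfig()
    return max(c.epsilon_floor, c.epsilon_start - c.epsilon_slope * (episode / c.epsilon_scale))


def q_target(
    t: Transition,
    net: LayeredNetwork,
    discount: float = 0.98,
    normalizer: WelfordNormalizer | None = None,
) -> float:
    """Bootstrap target: r_t, plus discounted max next-state Q if non-terminal."""
    if t.d_t:
        return float(t.r_t)
    s = normalizer.apply(t.s_next) if normalizer is not None else np.asarray(t.s_next, dtype=float)
    q_next = forward_prediction(net, s)
    return float(t.r_t + discount * np.max(q_next))


def masked_q_learn(
    net: LayeredNetwork,
    rule: str,
    s_in: np.ndarray,
    a_t: int | np.ndarray,
    target_value: float | np.ndarray,
    alpha: float,
    config: pcn.RelaxationConfig | None = None,
) -> LayeredNetwork:
    """Learning step supervising only the chosen action's output neuron.

    ``a_t``/``target_value`` may be arrays for a batch (inputs as columns).
    Prospective configuration clamps the chosen output to the target and
    lets the rest relax freely; backpropagation masks their error.
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    s = np.asarray(s_in, dtype=float)
    batch = 1 if s.ndim == 1 else s.shape[1]
    actions = np.atleast_1d(np.asarray(a_t, dtype=int))
    values = np.atleast_1d(np.asarray(target_value, dtype=float))
    if len(actions) != batch or len(values) != batch:
        raise ValueError("need one action and target value per example")
    if np.any(actions < 0) or np.any(actions >= net.out_size):
        raise ValueError("action index out of range")
    mask = np.zeros((net.out_size, batch), dtype=bool)
    mask[actions, np.arange(batch)] = True
    target = np.zeros((net.out_size, batch))
    target[actions, np.arange(batch)] = values
    if s.ndim == 1:
        mask1, target1 = mask[:, 0], target[:, 0]
        if rule == "pc":
            return pcn.learn(net, s, target1, alpha, config, output_mask=mask1)
        return backprop.backprop_update(net, s, target1, alpha, output_mask=mask1)
    if rule == "pc":
        return pcn.learn(net, s, target, alpha, config, output_mask=mask)
    return backprop.backprop_update(net, s, target, alpha, output_mask=mask)


def _greedy_action(q_values: np.ndarray) -> int:
    # ties broken by lowest action index (np.argmax convention)
    return int(np.argmax(q_values))


def greedy_policy(net: LayeredNetwork, observations: np.ndarray, normalizer: WelfordNormalizer | None = None) -> np.ndarray:
    """Greedy action for each observation row."""
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    acts = []
    for o in obs:
        s = normalizer.apply(o) if normalizer is not None else o
        acts.append(_greedy_action(forward_prediction(net, s)))
    return np.array(acts, dtype=int)


@dataclass
class QLearningResult:
    rewards: list[float]
    net: LayeredNetwork
    normalizer: WelfordNormalizer

    def sliding_mean(self, window: int = 200) -> np.ndarray:
        r = np.asarray(self.rewards)
        if len(r) < window:
            return np.array([r.mean()]) if len(r) else np.array([])
        kernel = np.ones(window) / window
        return np.convolve(r, kernel, mode="valid")


def q_learning_loop(
    env: Environment,
    rule: str,
    config: QConfig | None = None,
    alpha: float = 0.01,
    seed: int | None = None,
    net: LayeredNetwork | None = None,
    max_episode_steps: int = 1000,
) -> QLearningResult:
    """Full training loop: epsilon-greedy rollouts plus replay training.

    Returns the per-episode sum of rewards alongside the trained network
    and the observation normalizer (needed to act greedily afterwards).
    """
    if rule not in ("pc", "bp"):
        raise ValueError(f"rule must be 'pc' or 'bp', got {rule!r}")
    cfg = config if config is not None else QConfig()
    rng = np.random.default_rng(seed)
    obs0 = np.asarray(env.reset(), dtype=float)
    dim = obs0.shape[0]
    if net is None:
        n_actions = getattr(env, "n_actions", 2)
        net = init_network([dim, *cfg.hidden, n_actions], activation="sigmoid", seed=int(rng.integers(2**31)))
    buffer = ReplayBuffer(cfg.capacity)
    normalizer = WelfordNormalizer(dim)
    rewards: list[float] = []
    relax_cfg = cfg.relaxation if rule == "pc" else None
    for episode in range(cfg.episodes):
        rho = epsilon(episode, cfg)
        s_t = np.asarray(env.reset(), dtype=float)
        normalizer.update(s_t)
        done = False
        ep_reward = 0.0
        steps = 0
        while not done and steps < max_episode_steps:
            if rng.random() < rho:
                a_t = int(rng.integers(net.out_size))
            else:
                a_t = _greedy_action(forward_prediction(net, normalizer.apply(s_t)))
            s_next, r_t, done = env.step(a_t)
            s_next = np.asarray(s_next, dtype=float)
            normalizer.update(s_next)
            ep_reward += r_t
            buffer.add(Transition(s_t, a_t, float(r_t), s_next, bool(done)))
            s_t = s_next
            steps += 1
        rewards.append(ep_reward)
        if len(buffer) > cfg.train_threshold:
            for _ in range(cfg.replay_epochs):
                batch = buffer.sample(cfg.minibatch, rng)
                targets = np.array([q_target(t, net, cfg.discount, normalizer) for t in batch])
                actions = np.array([t.a_t for t in batch])
                s_in = normalizer.apply(np.stack([t.s_t for t in batch]).T)
                net = masked_q_learn(net, rule, s_in, actions, targets, alpha, relax_cfg)
    return QLearningResult(rewards, net, normalizer)


class ToyChainEnv:
    """Deterministic two-state chain with a terminal goal reward.

    States 0 and 1 (observation: the state index as a 1-vector).  Action 1
    ("advance") moves 0 -> 1 with reward 0 and 1 -> terminal with reward +1;
    action 0 ("quit") terminates immediately with reward -0.1 (quitting is
    mildly costly, so the value landscape is informative everywhere).
    Episodes start from states 0 and 1 alternately, so both states are
    visited densely regardless of the current policy.  The optimal policy
    advances in both states; its exact action values are
    Q*(0, advance) = discount, Q*(1, advance) = 1 and Q*(., quit) = -0.1.
    """

    n_actions = 2

    def __init__(self):
        self._state = 0
        self._next_start = 0

    def reset(self) -> np.ndarray:
        self._state = self._next_start
        self._next_start = 1 - self._next_start
        return np.array([float(self._state)])

    def step(self, action: int) -> tuple[np.ndarray, float, bool]:
        if action not in (0, 1):
            raise ValueError("action must be 0 or 1")
        if action == 0:
            return np.array([float(self._state)]), -0.1, True
        if self._state == 0:
            self._state = 1
            return np.array([1.0]), 0.0, False
        return np.array([1.0]), 1.0, True

    @staticmethod
    def optimal_q(discount: float = 0.98) -> np.ndarray:
        """Exact action values from value iteration, rows = states."""
        return np.array([[-0.1, discount], [-0.1, 1.0]])
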