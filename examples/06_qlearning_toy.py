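"""Q-learning with experience replay on the built-in two-state chain.

A value network (either learning rule) is trained from epsilon-greedy
rollouts with replayed minibatches and bootstrap targets.  Exact value
iteration on the chain gives Q*(0, advance) = 0.98, Q*(1, advance) = 1 and
Q*(., quit) = 0, so the optimal greedy policy advances in both states.
"""

import numpy as np

from prospect.qlearning import QConfig, ToyChainEnv, greedy_policy, q_learning_loop

cfg = QConfig(episodes=300, train_threshold=100, hidden=(16, 16))
for rule in ("pc", "bp"):
    result = q_learning_loop(ToyChainEnv(), rule, cfg, alpha=0.05, seed=0)
    policy = greedy_policy(result.net, np.array([[0.0], [1.0]]), result.normalizer)
    print(
        f"{rule}: mean reward over last 100 episodes {np.mean(result.rewards[-100:]):.2f}; "
        f"greedy policy per state {policy.tolist()} (value-iteration optimum [1, 1])"
    )
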