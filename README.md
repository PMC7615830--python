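# prospect

Prospective configuration — inference-first learning in energy-based
predictive coding networks — with a weight-matched backpropagation
baseline, interference metrics, minimal-network reproductions of two human
learning experiments, and Q-learning with experience replay.

## The problem

Credit assignment asks which weights in a network should change when the
output is wrong.  Backpropagation answers by gradient descent on the output
loss; applied to biological settings it is sample-hungry and suffers from
interference: correcting one output degrades others that were already
correct.  Energy-based predictive coding networks follow a different
principle.  Before any weight changes, neural activity *relaxes* to the
pattern it should show once the target is correctly predicted — the
prospective configuration — and the weights then consolidate that pattern
with a purely Hebbian step.  This package implements that principle and the
tools to compare it, head to head, with backpropagation on identical
networks.

## The model

A layered network (no biases, activation `f` applied presynaptically)
carries value neurons `x^l` and prediction errors
`ε^l = x^l − w^{l−1} f(x^{l−1})`, with energy

    E = Σ_l E^l,   E^l = ½‖ε^l‖²

Learning one pattern pair clamps the input and (a mask of) the output, then

1. relaxation: `Δx^l = γ(−ε^l + f′(x^l) ∘ (w^l)ᵀ ε^{l+1})` to convergence
   (adaptive step: γ starts at 0.1 and halves whenever a sweep fails to
   decrease E; stop at the second halving),
2. consolidation: `Δw^l = α ε^{l+1} (f(x^l))ᵀ` at the settled state.

The baseline trains the same `LayeredNetwork` by backpropagation on
`L = ½‖s_target − x^{L+1}‖²`; both rules share the feedforward prediction
`x^{l+1} = w^l f(x^l)`, so they start identical and differ only in credit
assignment.  Interference is measured by *target alignment*: the cosine
between the output-space direction toward the target and the direction the
(free) prediction actually moves after one update.

## Worked example

The minimal interference scenario: a 1-1-2 linear network with all weights
1 predicts `[1, 1]` from input `[1]`; the observed outcome is `[0, 1]`, so
the first output is wrong and the second already right.

```python
from prospect import backprop, bear_fixture, forward_prediction, pcn

fix = bear_fixture()
for rule in ("pc", "bp"):
    net, correct = fix.net.copy(), []
    for _ in range(fix.iterations):
        correct.append(forward_prediction(net, fix.pattern.s_in)[1])
        if rule == "pc":
            net = pcn.learn(net, fix.pattern.s_in, fix.pattern.s_target, fix.alpha)
        else:
            net = backprop.backprop_update(net, fix.pattern.s_in, fix.pattern.s_target, fix.alpha)
    y = forward_prediction(net, fix.pattern.s_in)
    print(rule, [round(v, 3) for v in y], "min correct output:", round(min(correct), 3))
```

prints

```
pc [0.049, 0.992] min correct output: 0.932
bp [0.038, 0.998] min correct output: 0.761
```

Both rules fix the wrong output (first number → 0) and keep the right one
(second number → 1), but along the way backpropagation drags the correct
prediction down to 0.76 — interference — while prospective configuration
never lets it fall below 0.93: the relaxation phase foresees the side
effect and compensates for it.

The `examples/` directory has one short script per capability: the example
above, the target-alignment depth sweep, batched training on synthetic
blobs, the sensorimotor and reversal-learning simulations, and Q-learning
on the built-in toy chain.  A thin CLI mirrors them
(`prospect bear|alignment-sweep|train|motor|reversal|qlearn`, see
`prospect --help`).

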