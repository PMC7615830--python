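"""Batched supervised training on synthetic Gaussian-blob classification.

Both rules train the same sigmoid network on the same data; the per-epoch
test error (fraction of argmax-misclassified test points) is summarized by
its mean over epochs (how fast learning is) and its minimum (how good it
gets).
"""

from prospect import init_network, synthetic_classification, train_loop

data = synthetic_classification(n_train=200, n_test=100, class_count=3, dim=8, separation=5.0, seed=0)
net = init_network([data.dim, 16, data.class_count], activation="sigmoid", seed=1)

for rule in ("pc", "bp"):
    trace = train_loop(net, rule, data, alpha=0.5, batch_size=8, epochs=12, seed=2)
    print(
        f"{rule}: test error per epoch {['%.2f' % e for e in trace.test_errors]}; "
        f"mean {trace.mean_test_error:.3f}, min {trace.min_test_error:.3f}"
    )
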