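"""Grid-search-selected simulation parameters for the behavioral tasks.

These are the best-fitting grid points returned by
:func:`prospect.behavior.grid_search_fit` run against the approximate
per-condition targets shipped in ``examples/data``.  The reversal fit ran
the full grid (init s.d. and rate from {0.01, 0.05, 0.1}) at 16
participants.  The motor fit screened the full grid (init s.d.
{0.01, 0.05, 0.1} x layer rates {0.00005, 0.0001, 0.0005, 0.01, 0.05}^2)
at a reduced participant count and refitted the leading candidates at the
full 24 participants; the values below are the refit argmin per rule.
They are recorded here so single-point simulations and the acceptance
checks can run the fitted models without repeating the search; rerun the
search (see ``examples/``) to regenerate them for different target data.
"""

FITTED_MOTOR_PARAMS: dict[str, dict[str, float]] = {
    "pc": {"init_sd": 0.01, "lr_layer1": 0.0005, "lr_layer2": 0.01},
    "bp": {"init_sd": 0.01, "lr_layer1": 0.01, "lr_layer2": 0.01},
}

FITTED_REVERSAL_PARAMS: dict[str, dict[str, float]] = {
    "pc": {"init_sd": 0.01, "alpha": 0.1},
    "bp": {"init_sd": 0.1, "alpha": 0.1},
}
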