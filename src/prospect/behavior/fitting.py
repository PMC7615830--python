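"""Fitting model output to per-condition behavioral data.

Model predictions ``x_c`` and data ``d_c`` live on different scales
(arbitrary network units versus behavioral or %BOLD units), so the model is
fitted by a scale ``a`` (restricted to be non-negative) and, for the
fMRI-signal comparison, an additional bias ``b``, minimizing

    sum_c (a x_c [+ b] - d_c)^2 .

Both fits have closed forms; the grid search exhaustively evaluates every
combination of simulation parameters, resolves the scale analytically for
each, and returns the combination with the smallest residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FitResult", "DegenerateFitError", "fit_scale", "grid_search_fit"]


class DegenerateFitError(ValueError):
    """The scale is undetermined (all model values zero)."""


@dataclass
class FitResult:
    """Best grid point with its analytic scale (and bias) and objective."""

    params: dict
    a: float
    b: float | None
    objective: float


def fit_scale(x: np.ndarray, d: np.ndarray, with_bias: bool = False) -> FitResult:
    """Closed-form least squares of ``d ~ a*x (+ b)`` with ``a`` clipped at 0.

    Without bias, ``a = max(0, sum(x d) / sum(x^2))``.  With bias, the
    ordinary least-squares pair is used; if the slope comes out negative it
    is clipped to 0 and the bias refitted (``b = mean(d)``).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    if x.shape != d.shape:
        raise ValueError("model and data vectors must have equal length")
    if np.all(x == 0.0):
        raise DegenerateFitError("all model values are zero; scale is undetermined")
    if not with_bias:
        a = max(0.0, float(np.dot(x, d) / np.dot(x, x)))
        obj = float(np.sum((a * x - d) ** 2))
        return FitResult({}, a, None, obj)
    xc = x - x.mean()
    dc = d - d.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise DegenerateFitError("model values are constant; slope is undetermined")
    a = float(np.dot(xc, dc) / denom)
    if a < 0.0:
        a = 0.0
    b = float(d.mean() - a * x.mean())
    obj = float(np.sum((a * x + b - d) ** 2))
    return FitResult({}, a, b, obj)


def grid_search_fit(
    rule: str,
    task: str,
    data: dict[str, float],
    grids: dict[str, list[float]],
    n_participants: int,
    seed: int = 0,
    **task_kwargs,
) -> tuple[FitResult, pd.DataFrame]:
    """Exhaustive grid search over simulation parameters for one rule.

    ``task`` is ``"motor"`` (grid keys ``init_sd``, ``lr1``, ``lr2``; scale
    only) or ``"reversal"`` (grid keys ``init_sd``, ``alpha``; scale and
    bias).  ``data`` maps condition names to the behavioral values ``d_c``;
    conditions are taken in the order of the dict.  Returns the best fit
    (with its grid point in ``params``) and a tidy frame of all grid
    evaluations.  Deterministic given ``seed``: every grid point reuses the
    same participant seeds.
    """
    from .motor import run_motor_experiment
    from .reversal import run_reversal_experiment

    if task not in ("motor", "reversal"):
        raise ValueError(f"task must be 'motor' or 'reversal', got {task!r}")
    conditions = list(data)
    d = np.array([data[c] for c in conditions])
    rows = []
    best: FitResult | None = None
    if task == "motor":
        combos = [
            {"init_sd": sd, "lr1": l1, "lr2": l2}
            for sd in grids["init_sd"]
            for l1 in grids["lr1"]
            for l2 in grids["lr2"]
        ]
    else:
        combos = [
            {"init_sd": sd, "alpha": a}
            for sd in grids["init_sd"]
            for a in grids["alpha"]
        ]
    for params in combos:
        if task == "motor":
            res = run_motor_experiment(
                rule, params["init_sd"], params["lr1"], params["lr2"],
                n_participants=n_participants, seed=seed, **task_kwargs,
            )
        else:
            res = run_reversal_experiment(
                rule, params["init_sd"], params["alpha"],
                n_participants=n_participants, seed=seed, **task_kwargs,
            )
        x = np.array([res.mean_signal[c] if task == "reversal" else res.mean_change[c] for c in conditions])
        try:
            fit = fit_scale(x, d, with_bias=(task == "reversal"))
        except DegenerateFitError:
            continue
        fit = FitResult(params, fit.a, fit.b, fit.objective)
        rows.append({**params, "a": fit.a, "b": fit.b, "objective": fit.objective})
        if best is None or fit.objective < best.objective:
            best = fit
    if best is None:
        raise DegenerateFitError("every grid point produced a degenerate fit")
    return best, pd.DataFrame(rows)
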