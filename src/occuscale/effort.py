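"""Survey-effort design: cumulative detection probabilities and minimum effort.

If a single water sample captures target eDNA with probability theta, the
chance that at least one of j independent samples does is

    theta* = 1 - (1 - theta)**j

and likewise p* = 1 - (1 - p)**k over k qPCR replicates.  These derived
curves, evaluated per posterior draw, give credible bands for how much
effort a survey needs before a benchmark probability (conventionally 0.95)
is exceeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CumulativeCurve", "cumulative_probability", "n_required", "posterior_cumulative"]


@dataclass(frozen=True)
class CumulativeCurve:
    """Cumulative probability vs effort, with credible bands when from draws."""

    efforts: np.ndarray
    median: np.ndarray
    cri_lower: np.ndarray | None = None
    cri_upper: np.ndarray | None = None

    def as_table(self):
        import pandas as pd

        data = {"effort": self.efforts, "median": self.median}
        if self.cri_lower is not None:
            data["cri_lower"] = self.cri_lower
            data["cri_upper"] = self.cri_upper
        return pd.DataFrame(data)


def cumulative_probability(prob, n) -> float | np.ndarray:
    """P(at least one success in n trials) = 1 - (1 - prob)**n."""
    prob = np.asarray(prob, dtype=float)
    n_arr = np.asarray(n)
    if (n_arr < 1).any():
        raise ValueError("effort n must be >= 1")
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("prob must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # prob = 1 -> log 0 -> cumulative 1
        out = -np.expm1(n_arr * np.log1p(-prob))
    return float(out) if out.ndim == 0 else out


def n_required(prob: float, target: float = 0.95) -> int:
    """Smallest effort whose cumulative probability strictly exceeds ``target``.

    Closed form ceil(log(1-target)/log(1-prob)), bumped by one when the
    cumulative probability at that effort ties the target exactly (the
    benchmark must be exceeded, not met).
    """
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    if prob >= 1:
        return 1
    if prob <= 0:
        raise ValueError("prob <= 0: no finite effort can exceed the target")
    n = max(1, math.ceil(math.log1p(-target) / math.log1p(-prob)))
    while cumulative_probability(prob, n) <= target:  # strictness / fp guard
        n += 1
    return n


def posterior_cumulative(draws, efforts) -> CumulativeCurve:
    """Apply the cumulative-probability transform per posterior draw.

    Because the transform is monotone in the base probability, per-draw
    transformation followed by quantiles is exact under the posterior.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws supplied")
    efforts = np.asarray(efforts, dtype=int)
    curves = cumulative_probability(draws[:, None], efforts[None, :])
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    return CumulativeCurve(efforts=efforts, median=med, cri_lower=lo, cri_upper=hi)
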