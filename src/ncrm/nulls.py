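"""Seeded resampling nulls shared by the enrichment and motif analyses."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import DataError


@dataclass
class ResampleNull:
    """A resampling null distribution of a mean statistic.

    ``expected`` is the mean over repetitions; empirical p-values use the
    +1-smoothed estimator (r + 1) / (n_reps + 1), so they are bounded in
    [1/(n_reps+1), 1]. The two-sided p doubles the smaller tail, capped
    at 1.
    """

    n_draw: int
    n_reps: int
    values: np.ndarray
    expected: float
    seed: Optional[int]
    observed: Optional[float] = None
    p_upper: Optional[float] = None
    p_lower: Optional[float] = None
    p_two_sided: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n_draw": self.n_draw,
            "n_reps": self.n_reps,
            "expected": self.expected,
            "observed": self.observed,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "p_two_sided": self.p_two_sided,
            "seed": self.seed,
        }


def resample_mean_null(
    values,
    n_draw: int,
    n_reps: int,
    seed: Optional[int],
    observed: Optional[float] = None,
    replace: bool = False,
) -> ResampleNull:
    """Resample ``n_draw``-element means of ``values`` ``n_reps`` times.

    Sampling is without replacement within a repetition by default and
    independent across repetitions. Deterministic under ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if n_draw <= 0 or n_reps <= 0:
        raise DataError("n_draw and n_reps must be positive")
    if not replace and n_draw > values.size:
        raise DataError(
            f"cannot draw {n_draw} from a pool of {values.size} without replacement"
        )
    if replace and values.size == 0:
        raise DataError("empty pool")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        idx = rng.choice(values.size, size=n_draw, replace=replace)
        draws[rep] = values[idx].mean()
    result = ResampleNull(
        n_draw=n_draw,
        n_reps=n_reps,
        values=draws,
        expected=float(draws.mean()),
        seed=seed,
        observed=observed,
    )
    if observed is not None:
        upper = (float((draws >= observed).sum()) + 1.0) / (n_reps + 1.0)
        lower = (float((draws <= observed).sum()) + 1.0) / (n_reps + 1.0)
        result.p_upper = upper
        result.p_lower = lower
        result.p_two_sided = min(1.0, 2.0 * min(upper, lower))
    return result
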