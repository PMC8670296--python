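"""Rank statistics and descriptive quantiles.

Two primitives used throughout the package:

* the two-sided Mann-Whitney U test (exact by enumeration for small pooled
  samples, tie-corrected normal approximation with continuity correction
  otherwise), and
* five-number summaries (min, q25, median, q75, max) with a configurable
  quartile convention.

The default quartile convention is rank ``k = p * (n + 1)`` with linear
interpolation between order statistics, clamped to ``[1, n]`` — Hyndman-Fan
type 6, the convention used by several commercial statistics packages for
box-plot percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import ValidationError

#: map from package-facing percentile method names to numpy.quantile methods
PERCENTILE_METHODS = {
    "rank_plus_one": "weibull",     # k = p(n+1), Hyndman-Fan 6 (default)
    "linear": "linear",             # k = 1 + p(n-1), Hyndman-Fan 7
    "median_unbiased": "median_unbiased",
}

DEFAULT_PERCENTILE_METHOD = "rank_plus_one"

#: largest pooled sample size for which exact Mann-Whitney enumeration is run
EXACT_LIMIT = 20


@dataclass(frozen=True)
class FiveNumberSummary:
    """min <= q25 <= median <= q75 <= max, optionally tagged by gene/class."""

    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    gene: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        q = (self.minimum, self.q25, self.median, self.q75, self.maximum)
        if any(b < a for a, b in zip(q, q[1:])):
            raise ValidationError(f"non-monotone five-number summary: {q}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.minimum, self.q25, self.median, self.q75, self.maximum)


def five_number_summary(
    values: Sequence[float],
    percentile_method: str = DEFAULT_PERCENTILE_METHOD,
    gene: str | None = None,
    class_label: str | None = None,
) -> FiveNumberSummary:
    """Five-number summary of a sample under the configured quartile rule."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("five_number_summary: empty input")
    if np.isnan(x).any():
        raise ValidationError("five_number_summary: NaN in input")
    try:
        method = PERCENTILE_METHODS[percentile_method]
    except KeyError:
        raise ValidationError(
            f"unknown percentile method {percentile_method!r}; "
            f"choose from {sorted(PERCENTILE_METHODS)}"
        ) from None
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75], method=method)
    return FiveNumberSummary(
        float(x.min()), float(q25), float(med), float(q75), float(x.max()),
        gene=gene, class_label=class_label,
    )


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney result.

    ``u_statistic`` counts pairwise wins of group A over group B plus half
    the ties, so ``0 <= U <= n1 * n2`` and ``U / (n1 * n2)`` is the empirical
    AUC of A-scores against B-scores.
    """

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: Literal["exact", "normal_approx"]
    all_tied: bool = False  # pooled data constant; p = 1 by convention


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration over the pooled multiset.

    Every C(n1+n2, n1) assignment of pooled values to group A is scored; the
    two-sided p doubles the smaller tail probability (capped at 1).
    """
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = np.fromiter(
        (sum(ranks[i] for i in idx) - offset
         for idx in combinations(range(pooled.size), n1)),
        dtype=float,
    )
    eps = 1e-9
    p_low = np.mean(us <= u_obs + eps)
    p_high = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _normal_approx_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> tuple[float, bool]:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # pooled data constant
        return 1.0, True
    mean = n1 * n2 / 2.0
    # continuity correction shrinks |U - mean| by 0.5
    z = (abs(u_obs - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - _phi(z))
    return float(min(1.0, p)), False


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
) -> RankTestResult:
    """Two-sided Mann-Whitney U test of group A versus group B.

    Parameters
    ----------
    mode
        ``"exact"`` enumerates all assignments (pooled n <= 20);
        ``"normal_approx"`` uses the tie-corrected normal approximation with
        continuity correction; ``"auto"`` picks exact when the pooled size
        permits it, the approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney: both groups must be nonempty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("mann_whitney: NaN in input")
    u = _u_statistic(a, b)
    pooled_constant = np.unique(np.concatenate([a, b])).size == 1
    if mode == "auto":
        mode = "exact" if a.size + b.size <= EXACT_LIMIT else "normal_approx"
    if mode == "exact":
        if a.size + b.size > EXACT_LIMIT:
            raise ValidationError(
                f"exact mode limited to pooled n <= {EXACT_LIMIT}; "
                f"got {a.size + b.size}"
            )
        p = 1.0 if pooled_constant else _exact_p(a, b, u)
        return RankTestResult(u, p, a.size, b.size, "exact", pooled_constant)
    if mode == "normal_approx":
        p, tied = _normal_approx_p(a, b, u)
        return RankTestResult(u, p, a.size, b.size, "normal_approx",
                              tied or pooled_constant)
    raise ValidationError(f"unknown mode {mode!r}")
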