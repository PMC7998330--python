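"""Intrapair (intraclass) correlations per zygosity group.

Twin order within a pair is arbitrary, so the estimator must be invariant
to swapping co-twins.  The maximum-likelihood common correlation of a
bivariate normal with equal means and equal variances across twin order is
used; it coincides exactly with the Pearson correlation of the
double-entered data (each pair contributing both orderings).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .cohort_io import TwinPair
from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationSummary:
    """One zygosity group's intrapair correlation with its CI and pair count."""

    zygosity: str
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int


def _pairs_to_array(pairs: Sequence[TwinPair] | np.ndarray) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DataError("pair array must have shape (n_pairs, 2)")
        return arr
    return np.array([(p.value_1, p.value_2) for p in pairs], dtype=float)


def intrapair_correlation(
    pairs: Sequence[TwinPair] | np.ndarray,
    zygosity: str | None = None,
    *,
    level: float = 0.95,
    ci_method: str = "fisher",
) -> CorrelationSummary:
    """ML common correlation of one zygosity group's pairs.

    Equivalent to the one-way intraclass correlation: mean and variance are
    pooled over both twins, so the result is invariant to the order of the
    two values within any pair.

    ``ci_method`` is ``"fisher"`` (z-transform, default) or ``"profile"``
    (likelihood-based, deviance rise of the chi-square(1) quantile).
    """
    arr = _pairs_to_array(pairs)
    n = arr.shape[0]
    if n < 3:
        raise DataError(f"need at least 3 pairs, got {n}")
    if zygosity is None:
        zygs = {p.zygosity for p in pairs} if not isinstance(pairs, np.ndarray) else set()
        if len(zygs) == 1:
            zygosity = zygs.pop()
        elif len(zygs) > 1:
            raise DataError(f"pairs span multiple zygosities: {sorted(zygs)}")
        else:
            zygosity = "?"

    m = arr.mean()
    dev = arr - m
    v = np.mean(dev**2)
    if v <= 0:
        raise DataError("zero variance: intrapair correlation undefined")
    cov = np.mean(dev[:, 0] * dev[:, 1])
    r = float(cov / v)

    if ci_method == "fisher":
        if abs(r) >= 1.0:
            logger.warning("degenerate |r| = 1; returning point interval")
            lo = hi = r
        else:
            lo, hi = correlation_ci(r, n, level=level)
    elif ci_method == "profile":
        lo, hi = _profile_correlation_ci(arr, r, level=level)
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")
    return CorrelationSummary(zygosity, r, lo, hi, n)


def correlation_ci(r: float, n_pairs: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval with SE 1/sqrt(n_pairs - 3)."""
    if not -1.0 < r < 1.0:
        raise DataError(f"|r| must be < 1 for a Fisher interval, got {r}")
    if n_pairs < 4:
        raise DataError(f"need at least 4 pairs for a Fisher interval, got {n_pairs}")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n_pairs - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


def _group_deviance(arr: np.ndarray, rho: float) -> float:
    """Summary deviance of one group under an exchangeable correlation rho.

    The total variance is profiled out in closed form (the deviance is a
    scale family in the common variance).
    """
    n = arr.shape[0]
    m = arr.mean()
    dev = arr - m
    s11 = np.mean(dev**2)
    s12 = np.mean(dev[:, 0] * dev[:, 1])
    # tr(S R^{-1}) for S=[[s11,s12],[s12,s11]], R=[[1,rho],[rho,1]]
    tr = 2.0 * (s11 - rho * s12) / (1.0 - rho**2)
    v_hat = tr / 2.0
    if v_hat <= 0:
        return np.inf
    return n * (2.0 * math.log(v_hat) + math.log1p(-(rho**2)) + 2.0)


def _profile_correlation_ci(
    arr: np.ndarray, r_hat: float, level: float = 0.95
) -> tuple[float, float]:
    """Likelihood-based interval: deviance rise of chi2(1) quantile around r_hat."""
    q = stats.chi2.ppf(level, df=1)
    d0 = _group_deviance(arr, r_hat)

    def f(rho: float) -> float:
        return _group_deviance(arr, rho) - d0 - q

    eps = 1e-9
    lo = -1.0 + eps
    hi = 1.0 - eps
    low = optimize.brentq(f, lo, r_hat) if f(lo) > 0 else -1.0
    high = optimize.brentq(f, r_hat, hi) if f(hi) > 0 else 1.0
    return float(low), float(high)
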