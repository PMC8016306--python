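"""Aggregation and inference toolkit for the tactile-illusion analyses.

Tools used when pooling per-participant tactile cues and comparing
experimental conditions: a logistic ("sigmoidal membership") normalization
applied per participant before aggregation, the Mann-Whitney U test with an
exact small-sample path, the absolute Cohen's d effect size, and percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "NormalizedSample",
    "sigmoid_normalize",
    "mann_whitney_u",
    "MannWhitneyResult",
    "cohens_d",
    "bootstrap_ci",
]

#: product n*m at or below which the exact permutation null is enumerated
EXACT_ENUMERATION_LIMIT = 64


@dataclass(frozen=True)
class NormalizedSample:
    """A sample mapped through a logistic membership function.

    ``normalized = 1 / (1 + exp(-growth_rate * (raw - center)))`` with the
    transition center at the raw-sample mean, so the mapping is strictly
    increasing and confined to the open interval (0, 1).
    """

    raw: np.ndarray
    normalized: np.ndarray
    center: float
    growth_rate: float


def sigmoid_normalize(values: Sequence[float], growth_rate: float = 1.0) -> NormalizedSample:
    """Normalize ``values`` to (0, 1) with a logistic membership function.

    The transition center is the sample mean and the logistic growth rate
    defaults to 1.  The map is strictly monotone, hence rank preserving; it
    is applied per participant (and per cue / task) before pooling data
    across participants.

    Parameters
    ----------
    values : sequence of float
        Raw cue values (any units); must be finite and non-empty.
    growth_rate : float
        Logistic growth rate (1 / units of ``values``).

    Raises
    ------
    ValueError
        If ``values`` is empty or contains non-finite entries.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid_normalize requires finite values")
    center = float(arr.mean())
    normalized = expit(growth_rate * (arr - center))
    # keep the open interval (0, 1) under floating-point saturation
    tiny = np.finfo(float).tiny
    normalized = np.clip(normalized, tiny, 1.0 - np.finfo(float).epsneg)
    return NormalizedSample(raw=arr, normalized=normalized, center=center,
                            growth_rate=float(growth_rate))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    significant: bool
    method: str  # "exact" or "asymptotic"


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Return (U_a, U_b) using midranks for ties."""
    n, m = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[:n].sum()
    u_a = r_a - n * (n + 1) / 2.0
    u_b = n * m - u_a
    return u_a, u_b


def mann_whitney_u(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Reports ``U = min(U_a, U_b)`` computed with midranks.  When
    ``n*m <= 64`` the two-sided p-value is obtained by exhaustive
    enumeration of all group assignments of the pooled sample
    (``P(min-U <= observed)`` under the permutation null, which is
    two-sided because extremeness in either direction shrinks the
    minimum U).  Larger samples use the normal approximation with tie
    correction and continuity correction.

    Raises
    ------
    ValueError
        If either sample is empty.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    n, m = a.size, b.size
    u_a, u_b = _u_statistics(a, b)
    u_obs = min(u_a, u_b)

    if n * m <= EXACT_ENUMERATION_LIMIT:
        pooled = np.concatenate([a, b])
        idx = np.arange(n + m)
        total = comb(n + m, n)
        count = 0
        for chosen in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(chosen)] = True
            ua, ub = _u_statistics(pooled[mask], pooled[~mask])
            if min(ua, ub) <= u_obs + 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        # normal approximation with tie correction
        pooled = np.concatenate([a, b])
        nn = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (nn * (nn - 1.0))
        mu = n * m / 2.0
        sigma2 = n * m / 12.0 * (nn + 1.0 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            # continuity-corrected two-sided p from the smaller U
            z = (u_obs - mu + 0.5) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "asymptotic"

    return MannWhitneyResult(u=float(u_obs), p_value=float(p),
                             significant=bool(p < alpha), method=method)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Absolute Cohen's d with the Bessel-corrected pooled SD.

    ``|mean(a) - mean(b)| / s_pooled`` where
    ``s_pooled^2 = ((n-1)s_a^2 + (m-1)s_b^2) / (n+m-2)``.

    Raises
    ------
    ValueError
        If either sample has fewer than two values or the pooled SD is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires at least two values per sample")
    n, m = a.size, b.size
    pooled_var = ((n - 1) * a.var(ddof=1) + (m - 1) * b.var(ddof=1)) / (n + m - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    iterations: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``statistic``.

    Resamples ``values`` with replacement ``iterations`` times (default
    1000) and returns the equal-tail percentile interval at ``level``.
    Deterministic for a fixed ``seed``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("bootstrap_ci requires at least two values")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    samples = rng.choice(arr, size=(iterations, arr.size), replace=True)
    stat = np.apply_along_axis(statistic, 1, samples)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
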