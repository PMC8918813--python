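"""Statistics for discrete count distributions and circular data.

Three families, matching how the morphodynamic quantities are compared:

* an adapted Kolmogorov-Smirnov test for discrete distributions (per-ISV
  event counts are small integers with heavy ties, where the classical KS
  null distribution is invalid): the D statistic is the sup-norm ECDF
  difference over the shared support, with an exact conditional permutation
  p-value when the enumeration is feasible and a seeded Monte-Carlo
  permutation p otherwise;
* circular statistics for migration directionality: first-trigonometric-
  moment mean direction / resultant length / circular SD, and Watson's
  two-sample U^2 homogeneity test (rotation invariant) with the asymptotic
  tail series or a permutation p-value;
* Welch's unequal-variance two-sample t-test (delegated to scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "DiscreteKsResult",
    "WatsonU2Result",
    "CircularSummary",
    "WelchTResult",
    "discrete_ks",
    "watson_u2",
    "circular_mean_sd",
    "welch_t",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DiscreteKsResult:
    statistic: float
    pvalue: float
    method: str           # "exact" | "permutation" | "simulated"
    n_a: int
    n_b: int
    n_resamples: int | None = None


@dataclass(frozen=True)
class WatsonU2Result:
    statistic: float
    pvalue: float
    method: str           # "asymptotic" | "permutation"
    n_a: int
    n_b: int
    n_resamples: int | None = None


@dataclass(frozen=True)
class CircularSummary:
    mean_direction: float     # radians; nan when the resultant vanishes
    resultant_length: float   # in [0, 1]
    circular_sd: float        # sqrt(-2 ln R); inf when R = 0
    n: int

    @property
    def mean_defined(self) -> bool:
        return np.isfinite(self.mean_direction)


@dataclass(frozen=True)
class WelchTResult:
    statistic: float
    df: float
    pvalue: float


# ---------------------------------------------------------------------------
# discrete Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _ecdf_sup_diff(a: np.ndarray, b: np.ndarray, support: np.ndarray) -> float:
    fa = np.searchsorted(np.sort(a), support, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), support, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def _perm_stats(pooled: np.ndarray, n_a: int, picks: np.ndarray) -> np.ndarray:
    """D statistics for many permutations; ``picks`` is (B, N) of argsorted labels."""
    support = np.unique(pooled)
    n_b = len(pooled) - n_a
    # indicator[b, j] = 1 if pooled[j] assigned to sample a in permutation b
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    # positions of the last occurrence of each support value in the sorted pool
    last = np.searchsorted(sorted_vals, support, side="right") - 1
    in_a = picks[:, order]
    ca = np.cumsum(in_a, axis=1)[:, last] / n_a
    cb = (np.cumsum(1 - in_a, axis=1)[:, last]) / n_b
    return np.max(np.abs(ca - cb), axis=1)


def discrete_ks(
    sample_a,
    sample_b=None,
    reference: tuple | None = None,
    n_resamples: int = 10_000,
    seed: int | None = 0,
    exact_limit: int = 100_000,
) -> DiscreteKsResult:
    """Two-sample (or one-sample) KS test adapted to discrete distributions.

    Two-sample: D is the sup ECDF difference over the pooled support; the
    p-value is the exact conditional permutation probability when
    C(n_a + n_b, n_a) <= ``exact_limit``, else a seeded Monte-Carlo
    permutation estimate (two-sided by construction).

    One-sample: pass ``reference=(values, pmf)``; the p-value is estimated by
    parametric simulation from the reference distribution.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    if len(a) == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)

    if sample_b is None:
        if reference is None:
            raise ValueError("provide sample_b or reference=(values, pmf)")
        vals, pmf = (np.asarray(v, dtype=float).ravel() for v in reference)
        if np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
            raise ValueError("reference pmf must be non-negative and sum to 1")
        order = np.argsort(vals)
        vals, pmf = vals[order], pmf[order]
        support = np.unique(np.concatenate([a, vals]))
        cdf_ref = np.cumsum(pmf)[np.searchsorted(vals, support, side="right") - 1]
        cdf_ref = np.where(np.searchsorted(vals, support, side="right") == 0, 0.0, cdf_ref)
        fa = np.searchsorted(np.sort(a), support, side="right") / len(a)
        d_obs = float(np.max(np.abs(fa - cdf_ref)))
        sims = rng.choice(vals, size=(n_resamples, len(a)), p=pmf)
        d_sim = np.array([
            np.max(np.abs(np.searchsorted(np.sort(s), support, side="right") / len(a)
                          - cdf_ref)) for s in sims
        ])
        p = (1.0 + np.sum(d_sim >= d_obs - _EPS)) / (n_resamples + 1.0)
        return DiscreteKsResult(d_obs, float(p), "simulated", len(a), 0, n_resamples)

    b = np.asarray(sample_b, dtype=float).ravel()
    if len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    support = np.unique(pooled)
    d_obs = _ecdf_sup_diff(a, b, support)
    n_a, n_b, n = len(a), len(b), len(pooled)

    if comb(n, n_a) <= exact_limit:
        count = 0
        total = 0
        for idx in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            d = _ecdf_sup_diff(pooled[mask], pooled[~mask], support)
            count += d >= d_obs - _EPS
            total += 1
        return DiscreteKsResult(d_obs, count / total, "exact", n_a, n_b, None)

    picks = np.zeros((n_resamples, n), dtype=np.int8)
    for row in picks:
        row[rng.choice(n, size=n_a, replace=False)] = 1
    d_perm = _perm_stats(pooled, n_a, picks)
    p = (1.0 + np.sum(d_perm >= d_obs - _EPS)) / (n_resamples + 1.0)
    return DiscreteKsResult(d_obs, float(p), "permutation", n_a, n_b, n_resamples)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_mean_sd(angles) -> CircularSummary:
    """Mean direction, resultant length and circular SD of angles in radians."""
    a = np.asarray(angles, dtype=float).ravel()
    if len(a) == 0:
        raise ValueError("empty angle sample")
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return CircularSummary(np.nan, 0.0, np.inf, len(a))
    sd = float(np.sqrt(-2.0 * np.log(min(r, 1.0)))) if r < 1.0 else 0.0
    return CircularSummary(float(np.arctan2(s, c)), r, sd, len(a))


def _watson_u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Watson's two-sample U^2 via the ECDF-difference form (ties averaged)."""
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    is_a = np.concatenate([np.ones(n_a), np.zeros(n_b)])[order]
    fa = np.cumsum(is_a) / n_a
    fb = np.cumsum(1.0 - is_a) / n_b
    d = fa - fb
    n = n_a + n_b
    return float(n_a * n_b / n**2 * (np.sum(d**2) - np.sum(d)**2 / n))


def _watson_asymptotic_p(u2: float, terms: int = 50) -> float:
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(np.clip(p, 0.0, 1.0))


def watson_u2(
    angles_a,
    angles_b,
    method: str = "auto",
    n_resamples: int = 9_999,
    seed: int | None = 0,
) -> WatsonU2Result:
    """Watson's two-sample U^2 test of homogeneity for circular data.

    The statistic is invariant to a common rotation of both samples.  The
    asymptotic tail series is used for n >= 8 per sample ("auto"); smaller
    samples (or ``method="permutation"``) get a seeded permutation p-value.
    """
    a = np.mod(np.asarray(angles_a, dtype=float).ravel(), 2 * np.pi)
    b = np.mod(np.asarray(angles_b, dtype=float).ravel(), 2 * np.pi)
    for s in (a, b):
        if len(np.unique(s)) < 2:
            raise ValueError("need at least two distinct angles per sample")
    u2 = _watson_u2_statistic(a, b)
    if method == "auto":
        method = "asymptotic" if min(len(a), len(b)) >= 8 else "permutation"
    if method == "asymptotic":
        return WatsonU2Result(u2, _watson_asymptotic_p(u2), "asymptotic",
                              len(a), len(b))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    pooled = np.sort(np.concatenate([a, b]))
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    # vectorized label permutations on the sorted pool
    picks = np.zeros((n_resamples, n), dtype=np.int8)
    for row in picks:
        row[rng.choice(n, size=n_a, replace=False)] = 1
    d = np.cumsum(picks, axis=1) / n_a - np.cumsum(1 - picks, axis=1) / n_b
    u2_perm = n_a * n_b / n**2 * (np.sum(d**2, axis=1) - np.sum(d, axis=1) ** 2 / n)
    count = int(np.sum(u2_perm >= u2 - _EPS))
    p = (1.0 + count) / (n_resamples + 1.0)
    return WatsonU2Result(u2, float(p), "permutation", len(a), len(b), n_resamples)


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(sample_a, sample_b) -> WelchTResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchTResult(float(res.statistic), float(res.df), float(res.pvalue))
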