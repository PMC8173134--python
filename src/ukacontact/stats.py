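"""The statistical battery used for the contact-excursion comparisons.

Implemented directly from first principles (sums of squares, rank
enumeration, stepwise range testing) rather than delegated, so each test's
behaviour is fully specified here:

* Kolmogorov-Smirnov normality check with sample-estimated parameters
  (the p-value uses the asymptotic Kolmogorov distribution and is
  anti-conservative when parameters are estimated — adequate as the
  screening test it is used for);
* one-way ANOVA across activities;
* Duncan's multiple range post hoc test with protection level
  ``1 - (1 - alpha)^(p-1)`` and studentized-range critical values;
* two-sample Wilcoxon-Mann-Whitney rank-sum test, exact by full
  enumeration for small samples, normal approximation with tie and
  continuity corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence
import math
import warnings

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, InvalidInputError

__all__ = [
    "AnovaResult",
    "DuncanResult",
    "ks_normality",
    "one_way_anova",
    "duncan_posthoc",
    "rank_sum_test",
]


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov normality
# ---------------------------------------------------------------------------


def ks_normality(
    sample: Sequence[float],
    mu: Optional[float] = None,
    sigma: Optional[float] = None,
) -> tuple[float, float]:
    """One-sample KS statistic against a normal distribution.

    D = sup_x |F_n(x) - Phi((x - mu) / sigma)|; by default both parameters
    are the maximum-likelihood estimates from the sample (pass ``mu`` /
    ``sigma`` to test against a fully specified normal instead).  The
    supremum is attained at a sample point, evaluated from both sides of
    each ECDF step.  p-value from the asymptotic Kolmogorov distribution.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise InvalidInputError("KS normality needs n >= 4")
    mu = x.mean() if mu is None else float(mu)
    sigma = x.std(ddof=0) if sigma is None else float(sigma)
    if sigma == 0:
        raise DegenerateSampleError("zero-variance sample")
    cdf = sps.norm.cdf((x - mu) / sigma)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    d = max(np.abs(ecdf_hi - cdf).max(), np.abs(cdf - ecdf_lo).max())
    p = float(sps.kstwobign.sf(np.sqrt(n) * d))
    return float(d), min(p, 1.0)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    group_labels: tuple
    group_means: tuple
    F: float
    df_between: int
    df_within: int
    ms_error: float
    p_value: float


def one_way_anova(groups: Sequence[Sequence[float]], labels: Optional[Sequence] = None) -> AnovaResult:
    """Fixed-effects one-way ANOVA from sums of squares."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise InvalidInputError("need >= 2 groups with n >= 2 each")
    labels = tuple(labels) if labels is not None else tuple(range(len(gs)))
    all_x = np.concatenate(gs)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = len(all_x) - len(gs)
    ms_w = ss_within / df_w
    if ms_w == 0:
        raise DegenerateSampleError("zero within-group variance")
    F = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        group_labels=labels,
        group_means=tuple(float(g.mean()) for g in gs),
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        ms_error=float(ms_w),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuncanResult:
    ordered_labels: tuple
    ordered_means: tuple
    pairwise_significant: dict  # (label_i, label_j) -> bool
    homogeneous_subsets: tuple  # tuple of tuples of labels
    critical_ranges: dict  # stretch length p -> R_p
    alpha: float


def _studentized_range_quantile(alpha_p: float, p: int, df: int) -> float:
    """Upper quantile of the studentized range (numerical CDF inversion)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # integration accuracy chatter
        return float(sps.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence] = None,
) -> DuncanResult:
    """Duncan's multiple range test on the ordered group means.

    For a stretch of ``p`` consecutive ordered means the critical range is
    ``R_p = q(alpha_p, p, df_w) * sqrt(MS_w / n_h)`` with Duncan's
    protection level ``alpha_p = 1 - (1 - alpha)^(p - 1)`` and ``n_h`` the
    harmonic mean group size.  Testing proceeds outside-in: a stretch whose
    range does not exceed ``R_p`` is declared homogeneous, and no pair
    inside a homogeneous stretch may be declared significant.
    """
    anova = one_way_anova(groups, labels)
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    if ns.max() / ns.min() > 2.0:
        warnings.warn(
            "group sizes beyond 2:1 — harmonic-mean approximation is rough",
            stacklevel=2,
        )
    n_h = len(ns) / (1.0 / ns).sum()
    if anova.df_within < 2:
        raise InvalidInputError("Duncan's test needs within df >= 2")

    order = np.argsort(anova.group_means)
    means = np.asarray(anova.group_means)[order]
    labs = tuple(np.asarray(anova.group_labels, dtype=object)[order])
    se = math.sqrt(anova.ms_error / n_h)
    crit = {
        p: _studentized_range_quantile(1.0 - (1.0 - alpha) ** (p - 1), p, anova.df_within) * se
        for p in range(2, k + 1)
    }

    # outside-in stepwise testing with the containment constraint
    nonsig = np.zeros((k, k), dtype=bool)  # stretch i..j homogeneous
    for span in range(k - 1, 0, -1):  # longer stretches first
        for i in range(0, k - span):
            j = i + span
            contained = any(
                nonsig[a, b] for a in range(0, i + 1) for b in range(j, k) if (b - a) > span
            )
            if contained or (means[j] - means[i]) <= crit[span + 1]:
                nonsig[i, j] = True

    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(labs[i], labs[j])] = not nonsig[i, j]

    # homogeneous subsets: maximal non-significant stretches
    subsets = []
    for i in range(k):
        for j in range(k - 1, i - 1, -1):
            if i == j or nonsig[i, j]:
                covered = any(set(range(i, j + 1)) <= s for s in subsets)
                if not covered:
                    subsets.append(set(range(i, j + 1)))
                break
    subsets = tuple(tuple(labs[i] for i in sorted(s)) for s in subsets)

    return DuncanResult(
        ordered_labels=labs,
        ordered_means=tuple(float(m) for m in means),
        pairwise_significant=pairwise,
        homogeneous_subsets=subsets,
        critical_ranges=crit,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney rank-sum
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Returns (W, p) with W the rank sum of ``x`` (midranks under ties).
    ``mode='exact'`` enumerates all C(n, n_x) assignments of the pooled
    midranks; ``'approx'`` uses the normal approximation with tie and
    continuity corrections; ``'auto'`` picks exact when n_x + n_y <= 12.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise InvalidInputError("both samples must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    nx, ny = len(xa), len(ya)
    pooled = np.concatenate([xa, ya])
    ranks = _midranks(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (nx + ny + 1) / 2.0

    if mode == "exact" or (mode == "auto" and nx + ny <= 12):
        dev = abs(w - mu)
        count = 0
        total = 0
        for comb in combinations(range(nx + ny), nx):
            ws = ranks[list(comb)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-12:
                count += 1
        return w, count / total

    # normal approximation with tie correction
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)  # continuity-corrected
    p = 2.0 * float(sps.norm.sf(max(z, 0.0)))
    return w, min(p, 1.0)
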