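"""Survival, kinetics, and association statistics for xenograft studies.

The tests whose exactness matters downstream (Fisher's 2x2 exact test, the
exact Wilcoxon rank-sum test, the Kaplan-Meier product-limit estimator and
the Mantel-Cox log-rank statistic, the Monte-Carlo Dunnett adjustment) are
implemented here from first principles by hypergeometric / permutation
enumeration, so their behavior is fully specified and auditable.  Ordinary
linear-model machinery (the ANCOVA slope comparison) goes through
statsmodels, and power calculations use scipy's noncentral-t distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .curve_prep import DailySeries, interpolate_daily
from .growth_io import AnimalCourse, ValidationError

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's (time, event, group): time in days > 0, event=True when
    the endpoint was observed (False = right-censored)."""

    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"survival time must be > 0, got {self.time}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValidationError("2x2 counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValidationError("2x2 table total must be >= 1")


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test design: standardized effect size d, two-sided alpha,
    target power."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not self.effect_size_d > 0:
            raise ValidationError("effect size d must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    """Generic (statistic, p) container with the settings that produced it."""

    statistic: float
    p_value: float
    method: str
    note: str | None = None


# ---------------------------------------------------------------------------
# Time-to-event derivation
# ---------------------------------------------------------------------------


def time_to_event(
    course: AnimalCourse,
    cap: float = 800.0,
    daily: DailySeries | None = None,
) -> SurvivalRecord:
    """Derive one survival record from an (aligned) animal course.

    Resected animals are events at the resection day.  Unresected animals
    whose tumor reached the volume cap are events at the first day the daily
    series exceeds the cap (explicitly not censored).  Animals ending the
    study below the cap without resection are censored at their last day.
    """
    if course.n < 1 and course.endpoint is None:
        raise ValidationError(
            f"animal {course.animal_id!r}: no endpoint and no measurements"
        )
    if course.endpoint is not None and course.endpoint.reason == "resected":
        return SurvivalRecord(
            time=float(course.endpoint.day), event=True, group=course.arm
        )
    if daily is None:
        daily = interpolate_daily(course)
    above = np.nonzero(daily.volumes > cap)[0]
    if above.size:
        return SurvivalRecord(
            time=float(daily.days[above[0]]), event=True, group=course.arm
        )
    last = course.last().study_day
    if course.endpoint is not None:
        last = max(last, course.endpoint.day)
    return SurvivalRecord(time=float(last), event=False, group=course.arm)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def km_estimate(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame with one row per distinct time (plus a time-0 row),
    columns ``time, at_risk, events, censored, survival``.  Subjects censored
    at an event time are counted at risk at that time (events precede
    censorings at ties, the standard convention); S(0) = 1 and S is
    non-increasing.
    """
    if not records:
        raise ValidationError("km_estimate: no records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    rows = [{"time": 0.0, "at_risk": len(records), "events": 0, "censored": 0,
             "survival": 1.0}]
    s = 1.0
    at_risk = len(records)
    for t in np.unique(times):
        here = times == t
        d = int(events[here].sum())
        c = int((~events[here]).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append(
            {"time": float(t), "at_risk": at_risk, "events": d, "censored": c,
             "survival": s}
        )
        at_risk -= d + c
    return pd.DataFrame(rows)


def logrank_test(groups: list[list[SurvivalRecord]]) -> TestResult:
    """Mantel-Cox log-rank test over k >= 2 groups.

    At each pooled event time the observed-minus-expected event counts per
    group accumulate with the hypergeometric variance/covariance; the
    statistic is the quadratic form over the first k-1 groups, referred to a
    chi-square with k-1 degrees of freedom.  With no events anywhere the
    test is vacuous: chi2 = 0, p = 1 (with a warning).
    """
    k = len(groups)
    if k < 2 or any(not g for g in groups):
        raise ValidationError("logrank_test: need >= 2 non-empty groups")
    times = np.concatenate([[r.time for r in g] for g in groups])
    events = np.concatenate([[r.event for r in g] for g in groups]).astype(bool)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])

    event_times = np.unique(times[events])
    if event_times.size == 0:
        warnings.warn("logrank_test: no events in any group; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "logrank", note="no events")

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int((events & (times == t)).sum())
        n_g = np.array([int((at_risk & (labels == i)).sum()) for i in range(k)])
        d_g = np.array(
            [int((events & (times == t) & (labels == i)).sum()) for i in range(k)]
        )
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            frac = d * (n - d) / (n - 1)
            p_g = n_g / n
            cov += frac * (np.diag(p_g) - np.outer(p_g, p_g))

    v = o_minus_e[: k - 1]
    V = cov[: k - 1, : k - 1]
    chi2 = float(v @ np.linalg.pinv(V) @ v)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    return TestResult(chi2, p, "logrank")


# ---------------------------------------------------------------------------
# Growth-curve kinetics
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "cube": lambda v: v**3,
    "cube_root": np.cbrt,
    "log": np.log,
    "identity": lambda v: v,
}


def _apply_transform(volumes: np.ndarray, transform: str) -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise ValidationError(f"unknown transform {transform!r}")
    v = np.asarray(volumes, dtype=float)
    if transform == "log" and np.any(v <= 0):
        raise ValidationError("log transform requires strictly positive volumes")
    return _TRANSFORMS[transform](v)


def slope_fit(daily: DailySeries, transform: str = "cube") -> tuple[float, float]:
    """OLS slope (and its standard error) of the pointwise-transformed volume
    on study day.  Requires >= 3 days."""
    if len(daily.volumes) < 3:
        raise ValidationError("slope_fit requires >= 3 days")
    y = _apply_transform(daily.volumes, transform)
    res = sps.linregress(daily.days.astype(float), y)
    return float(res.slope), float(res.stderr)


def compare_slopes(
    groups: list[list[DailySeries]], transform: str = "cube"
) -> TestResult:
    """ANCOVA-style slope comparison: pooled linear model of transformed
    volume on day with per-group intercepts, F-test of the group x day
    interaction (slope equality).  Animals are pooled as independent
    observations.  A (near-)zero-residual full model is flagged and reported
    with p at the smallest positive float."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("compare_slopes: need >= 2 groups with >= 2 series each")
    rows = []
    for gi, series_list in enumerate(groups):
        for si, s in enumerate(series_list):
            y = _apply_transform(s.volumes, transform)
            for day, val in zip(s.days, y):
                rows.append({"day": float(day), "y": float(val), "group": f"g{gi}"})
    d = pd.DataFrame(rows)
    full = smf.ols("y ~ C(group) * day", data=d).fit()
    reduced = smf.ols("y ~ C(group) + day", data=d).fit()
    scale = float(np.square(d["y"]).sum()) or 1.0
    if full.ssr / scale < 1e-14:
        return TestResult(
            math.inf,
            float(np.finfo(float).tiny),
            f"ancova_interaction[{transform}]",
            note="degenerate zero-residual fit; p below machine precision",
        )
    f_stat, p, _ = full.compare_f_test(reduced)
    return TestResult(float(f_stat), float(p), f"ancova_interaction[{transform}]")


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p is the probability-mass definition: the sum of
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (relative
    tolerance 1e-7 on the comparison).  Computed in exact integer
    arithmetic.  A table with a zero margin is degenerate: p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
        ContingencyTable2x2(a, b, c, d)  # validate
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("fisher_exact_2x2: zero margin; p = 1", stacklevel=2)
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    # integer weights: P(k) = w_k / C(n, c1), w_k = C(r1, k) * C(n-r1, c1-k)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    # w_k <= w_obs * (1 + 1e-7), in integers
    total = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return float(total / comb(n, c1))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (mid-ranks for ties)
    p_value: float
    mode: str  # "exact" or "approx"


def _ranksum_exact_p(ranks2: np.ndarray, m: int, w2: int) -> float:
    """Exact two-sided tail probability of the rank-sum statistic over all
    C(m+n, m) equally likely labelings, by dynamic programming over the
    doubled (integer) mid-ranks.  Two-sided: labelings at least as far from
    the null mean as observed, on either side."""
    n_tot = len(ranks2)
    total_sum = int(ranks2.sum())
    # dp[j][s] = number of j-subsets with doubled-rank sum s
    max_s = total_sum
    dp = np.zeros((m + 1, max_s + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for j in range(m, 0, -1):
            dp[j, r:] += dp[j - 1, : max_s + 1 - r]
    counts = dp[m]
    # null mean of the doubled rank sum: m * mean(doubled ranks)
    mu2 = m * total_sum / n_tot
    dev = abs(w2 - mu2) - 1e-9
    sums = np.arange(max_s + 1)
    extreme = np.abs(sums - mu2) >= dev
    return float(counts[extreme].sum() / comb(n_tot, m))


def rank_sum_test(
    x,
    y,
    mode: str = "auto",
    exact_cap: int = 10_000_000,
    auto_threshold: int = 10_000,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``exact`` enumerates all C(m+n, m) labelings of the pooled mid-ranks
    (via an equivalent generating-function count) and returns the two-sided
    tail probability of the rank-sum statistic; ``approx`` uses the normal
    approximation with tie-corrected variance and continuity correction;
    ``auto`` uses exact up to ``auto_threshold`` labelings.  Requesting
    exact beyond ``exact_cap`` labelings is an error suggesting approx.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test: both samples must be non-empty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    w = float(ranks[:m].sum())

    n_labelings = comb(m + n, m)
    if mode == "auto":
        mode = "exact" if n_labelings <= auto_threshold else "approx"
    if mode == "exact":
        if n_labelings > exact_cap:
            raise ValidationError(
                f"exact enumeration of {n_labelings} labelings exceeds the cap "
                f"({exact_cap}); use mode='approx'"
            )
        ranks2 = np.round(ranks * 2).astype(np.int64)
        p = _ranksum_exact_p(ranks2, m, int(round(w * 2)))
        return RankSumResult(w, min(p, 1.0), "exact")
    if mode != "approx":
        raise ValidationError(f"unknown mode {mode!r}")

    n_tot = m + n
    mu = m * (n_tot + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = m * n / 12.0 * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if var <= 0:
        return RankSumResult(w, 1.0, "approx")
    z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return RankSumResult(w, p, "approx")


# ---------------------------------------------------------------------------
# ANOVA with Dunnett-style adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DunnettResult:
    t_statistics: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    df: int
    n_mc: int


def anova_dunnett(
    control,
    treatment_groups,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> DunnettResult:
    """Many-to-one comparisons against a shared control, family-wise adjusted.

    Per-comparison t statistics use the one-way-ANOVA pooled variance; the
    adjusted p for comparison i is the null probability that the maximum
    |t| over all comparisons reaches |t_i|, estimated by seeded Monte Carlo
    from the exact null structure (shared control mean and shared variance
    estimate), which reduces to classical Dunnett in the balanced case.

    Zero pooled variance with unequal group means is an error; with all
    groups identical the statistics are 0 and every adjusted p is 1.
    """
    groups = [np.asarray(control, dtype=float)] + [
        np.asarray(g, dtype=float) for g in treatment_groups
    ]
    if len(groups) < 2:
        raise ValidationError("anova_dunnett: need a control and >= 1 treatment group")
    if any(g.size < 2 for g in groups):
        raise ValidationError("anova_dunnett: every group needs n >= 2")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    ss_within = sum(float(np.square(g - g.mean()).sum()) for g in groups)
    df = int(ns.sum()) - len(groups)
    mse = ss_within / df
    k = len(groups) - 1
    se = np.sqrt(np.maximum(mse, 0.0) * (1.0 / ns[1:] + 1.0 / ns[0]))

    if mse <= 0:
        if np.allclose(means, means[0]):
            zeros = tuple(0.0 for _ in range(k))
            return DunnettResult(zeros, tuple(1.0 for _ in range(k)), df, 0)
        raise ValidationError(
            "anova_dunnett: zero pooled variance with unequal means"
        )

    t_obs = (means[1:] - means[0]) / se

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, k + 1))
    s = np.sqrt(rng.chisquare(df, n_mc) / df)
    num = z[:, 1:] / np.sqrt(ns[1:]) - z[:, :1] / np.sqrt(ns[0])
    t_null = num / (s[:, None] * np.sqrt(1.0 / ns[1:] + 1.0 / ns[0]))
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = tuple(float(np.mean(max_abs >= abs(t))) for t in t_obs)
    return DunnettResult(tuple(float(t) for t in t_obs), p_adj, df, n_mc)


# ---------------------------------------------------------------------------
# Simple summaries and design
# ---------------------------------------------------------------------------


def delta_percent(treated_pct: float, control_pct: float) -> float:
    """Percentage-point difference treated - control (both in [0, 100])."""
    for v in (treated_pct, control_pct):
        if not 0 <= v <= 100:
            raise ValidationError(f"percentage {v} outside [0, 100]")
    return float(treated_pct) - float(control_pct)


@dataclass(frozen=True)
class ProportionSummary:
    positive: int
    total: int
    percent_exact: float
    percent: int  # rounded half away from zero


def proportion_summary(positive: int, total: int) -> ProportionSummary:
    """Exact and integer-rounded percentage of a count (rounding half away
    from zero, the convention of printed '16 of 102 (16%)'-style reports)."""
    if total <= 0:
        raise ValidationError("proportion_summary: total must be > 0")
    if not 0 <= positive <= total:
        raise ValidationError("proportion_summary: need 0 <= positive <= total")
    exact = 100.0 * positive / total
    return ProportionSummary(positive, total, exact, int(math.floor(exact + 0.5)))


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test at n per group, effect size d:
    noncentral-t tail probability at noncentrality d * sqrt(n/2)."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = d * math.sqrt(n_per_group / 2.0)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_two_t(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n per group at which the two-sided two-sample t-test at
    level alpha has power >= the target, by iterating the noncentral-t
    power function upward from the minimum n = 2."""
    # normal-approximation starting point, stepped back to stay conservative
    z = sps.norm.ppf(1 - spec.alpha / 2) + sps.norm.ppf(spec.power)
    n0 = max(2, int(2 * (z / spec.effect_size_d) ** 2) - 3)
    n = n0
    while power_two_sample_t(n, spec.effect_size_d, spec.alpha) >= spec.power and n > 2:
        n -= 1  # the start may overshoot; walk down to the boundary
    while power_two_sample_t(n, spec.effect_size_d, spec.alpha) < spec.power:
        n += 1
        if n > n_max:
            raise ValidationError("sample_size_two_t: target power unreachable")
    return n
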