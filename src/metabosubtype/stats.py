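"""Statistical primitives shared by every pipeline stage.

Implements Benjamini–Hochberg correction, the classical two-group and k-group
tests, an empirical-Bayes moderated t for feature-wise differential testing
(limma-style hierarchical variance model with method-of-moments hyperparameter
estimation), and Kaplan–Meier / log-rank survival comparisons.

Standard tests are delegated to scipy / lifelines; the moderated t and its
hyperparameter fit are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "ModeratedFitSummary",
    "benjamini_hochberg",
    "chi_square_independence",
    "t_test_from_summary",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "moderated_t_two_group",
    "km_curve",
    "logrank_test",
]


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p outside [0,1]: {self.p}")


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct event times (increasing); ``survival`` the
    step values S(t) just after each event time; ``at_risk`` the risk-set size
    at each event time; ``censor_times`` the censored observation times.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ModeratedFitSummary:
    d0: float
    s0_sq: float
    table: pd.DataFrame  # per-feature: log2fc, s2, s2_post, t, df, p, zero_variance

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("invalid hyperparameters")


# ---------------------------------------------------------------------------
# multiplicity


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# classical tests (scipy-backed)


def chi_square_independence(table: np.ndarray, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    res = sps.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(res.statistic), df=float(res.dof), p=float(res.pvalue))


def t_test_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = True
) -> TestResult:
    """Two-sided two-sample t from group summaries (pooled by default, else Welch)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=pooled)
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(statistic=float(res.statistic), df=df, p=float(res.pvalue))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact when n1+n2 <= 16 and there are no ties; otherwise the tie-corrected
    normal approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical across both groups; p = 1")
        return TestResult(statistic=0.0, df=None, p=1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), df=None, p=float(min(res.pvalue, 1.0)))


def kruskal_wallis(groups: list) -> TestResult:
    """Tie-corrected Kruskal–Wallis H test with chi-square p (df = k-1)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # all observations tied: no evidence against the null
        return TestResult(statistic=0.0, df=float(len(groups) - 1), p=1.0)
    res = sps.kruskal(*arrays)
    return TestResult(statistic=float(res.statistic), df=float(len(groups) - 1), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for residual variances.

    Models s2 ~ s0_sq * F(df, d0); returns (d0, s0_sq).  d0 = inf when the
    observed log-variance spread is no larger than expected under equal
    true variances.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread in log-variances: pooled variance is the MLE scale
        d0 = np.inf
        s0_sq = float(np.mean(s2[ok]))
    return float(d0), s0_sq


def moderated_t_two_group(
    log_matrix: pd.DataFrame,
    labels,
    group: str | None = None,
    reference: str | None = None,
    d0_override: float | None = None,
) -> ModeratedFitSummary:
    """Feature-wise two-group empirical-Bayes moderated t on log-scale values.

    Per feature g, the pooled residual variance s_g^2 (d_g = n1+n2-2 df) is
    shrunk towards a prior s0_sq with prior df d0, both estimated by the
    method of moments on log s_g^2.  The moderated statistic is

        t_g = log2fc_g / ( s_tilde_g * sqrt(1/n1 + 1/n2) ),
        s_tilde_g^2 = (d0*s0_sq + d_g*s_g^2) / (d0 + d_g),

    with d0 + d_g degrees of freedom.  ``log2fc`` is mean(group) -
    mean(reference).  ``d0_override`` pins the prior df (0 recovers the
    ordinary pooled t).
    """
    labels = pd.Series(list(labels), index=log_matrix.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 label levels, got {levels}")
    if reference is None or group is None:
        reference, group = levels[0], levels[1]
    g_cols = labels.index[labels == group]
    r_cols = labels.index[labels == reference]
    n1, n2 = len(g_cols), len(r_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")

    x1 = log_matrix[g_cols].to_numpy(dtype=float)
    x2 = log_matrix[r_cols].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = m1 - m2
    dg = n1 + n2 - 2
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = rss / dg
    zero_var = s2 <= 0

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    else:
        d0, s0_sq = _fit_f_dist(s2, float(dg))

    n_features = s2.size
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = float(n_features * dg)  # total-df cap at the pooled df
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = min(d0 + dg, float(n_features * dg))
    if d0 == 0.0:
        s2_post = s2.copy()
        df_total = float(dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
        t = np.where((se == 0) & (log2fc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "df": df_total,
            "p": p,
            "zero_variance": zero_var,
        },
        index=log_matrix.index,
    )
    return ModeratedFitSummary(d0=d0, s0_sq=s0_sq, table=table)


# ---------------------------------------------------------------------------
# survival


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    Censorings tied with an event time are counted as still at risk at that
    time (removed just after it).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return SurvivalCurve(
        event_times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, group_labels) -> TestResult:
    """k-group log-rank chi-square test (df = k-1), lifelines-backed."""
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(list(group_labels))
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 1).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups.to_numpy(), events)
    return TestResult(
        statistic=float(res.test_statistic),
        df=float(len(counts) - 1),
        p=float(res.p_value),
    )
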