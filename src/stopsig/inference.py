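"""Frequentist and Bayesian inference for two-group, two-effector designs.

This module reproduces the inferential toolkit of a classical expertise
comparison: pooled-SD standardized mean differences with noncentral-t
confidence intervals, Student t-tests (optionally one-tailed), the 2 x 2
between-within (split-plot) ANOVA with partial eta squared, Fisher-z
correlation intervals and comparisons, t-test Bayes factors under shifted and
truncated Cauchy effect-size priors, and an a-priori sample-size calculation
for the between-groups effect of the mixed design.

Sign convention: every two-group function takes the first group's summaries
first and reports ``second minus first``, so calling with (expert, control)
yields a positive difference when experts have the smaller mean (e.g. SSRT,
where smaller is better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .exceptions import NumericalError, StopsigError

__all__ = [
    "EffectSize",
    "TTestResult",
    "AnovaEffect",
    "AnovaResult",
    "BayesFactorResult",
    "CorrelationResult",
    "pooled_cohens_d",
    "independent_t_test",
    "smd_confidence_interval",
    "partial_eta_squared",
    "mixed_anova_2x2",
    "split_plot_f_stats",
    "jzs_bayes_factor",
    "bf_robustness",
    "pearson_ci",
    "compare_independent_correlations",
    "power_mixed_anova_between",
    "sample_size_mixed_anova",
]

SIDES = ("two_sided", "positive", "negative")


def _check_summaries(sd1: float, n1: int, sd2: float, n2: int) -> None:
    if sd1 <= 0 or sd2 <= 0:
        raise StopsigError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise StopsigError("each group needs n >= 2")


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise StopsigError("pooled variance is zero")
    return math.sqrt(sp2)


@dataclass(frozen=True)
class EffectSize:
    """Pooled-SD standardized mean difference with a noncentral-t CI."""

    d: float
    ci_low: float
    ci_high: float
    conf_level: float
    n1: int
    n2: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    side: str


def pooled_cohens_d(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, conf_level: float = 0.95
) -> EffectSize:
    """Cohen's d = (m2 - m1) / pooled SD, with a noncentral-t confidence interval."""
    _check_summaries(sd1, n1, sd2, n2)
    d = (m2 - m1) / _pooled_sd(sd1, n1, sd2, n2)
    lo, hi = smd_confidence_interval(d, n1, n2, conf_level)
    return EffectSize(d=d, ci_low=lo, ci_high=hi, conf_level=conf_level, n1=n1, n2=n2)


def independent_t_test(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, side: str = "two_sided"
) -> TTestResult:
    """Student (pooled-variance) two-sample t-test from group summaries.

    ``side='positive'`` tests the directional hypothesis m2 > m1 (p is the
    upper tail of t), ``'negative'`` the reverse.
    """
    _check_summaries(sd1, n1, sd2, n2)
    if side not in SIDES:
        raise StopsigError(f"unknown side {side!r}")
    sp = _pooled_sd(sd1, n1, sd2, n2)
    df = n1 + n2 - 2
    t = (m2 - m1) / (sp * math.sqrt(1 / n1 + 1 / n2))
    if side == "two_sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif side == "positive":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return TTestResult(t=t, df=df, p=float(p), side=side)


def smd_confidence_interval(
    d: float, n1: int, n2: int, conf_level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for a standardized mean difference.

    The observed t = d * sqrt(n1 n2 / (n1 + n2)) follows a noncentral-t
    distribution with noncentrality delta * sqrt(n1 n2 / (n1 + n2)); the
    interval inverts that distribution so that the tail probability at each
    bound equals (1 +- conf_level) / 2, then rescales back to the d axis.
    """
    if not (0.0 < conf_level < 1.0):
        raise StopsigError("conf_level must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise StopsigError("each group needs n >= 2")
    df = n1 + n2 - 2
    c = math.sqrt(n1 * n2 / (n1 + n2))
    t = d * c
    lo = _ncp_for_tail(t, df, (1 + conf_level) / 2) / c
    hi = _ncp_for_tail(t, df, (1 - conf_level) / 2) / c
    return float(lo), float(hi)


def _ncp_for_tail(t: float, df: int, prob: float) -> float:
    """Noncentrality ncp with P(T_{df,ncp} <= t) = prob; brentq fallback."""
    ncp = special.nctdtrinc(df, prob, t)
    if np.isfinite(ncp) and abs(stats.nct.cdf(t, df, ncp) - prob) < 1e-7:
        return float(ncp)
    lo, hi = t - 60.0, t + 60.0
    try:
        return float(
            optimize.brentq(lambda x: stats.nct.cdf(t, df, x) - prob, lo, hi, xtol=1e-10)
        )
    except ValueError as exc:  # pragma: no cover - pathological inputs
        raise NumericalError(
            f"noncentrality inversion failed for t={t}, df={df}, prob={prob}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# split-plot (between-within) ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, AnovaEffect]

    def __getitem__(self, key: str) -> AnovaEffect:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": k, "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                 "partial_eta_sq": e.partial_eta_sq}
                for k, e in self.effects.items()
            ]
        )


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """eta_p^2 recovered from an F ratio: F df1 / (F df1 + df2)."""
    if F < 0:
        raise StopsigError("F must be nonnegative")
    return F * df1 / (F * df1 + df2)


def split_plot_f_stats(
    y: np.ndarray, group_index: np.ndarray
) -> dict[str, tuple[np.ndarray, tuple[int, int]]]:
    """Vectorized split-plot F statistics.

    ``y`` has shape (..., N, m): leading axes are independent replicates,
    N subjects (each in one group) by m repeated measures. ``group_index``
    assigns each subject to a group (0..k-1). Returns, per effect, the F
    array over the leading axes and its (df1, df2). The between effect is
    tested against subjects-within-groups, the within and interaction effects
    against the measure x subject error. Group sizes should be (near)
    balanced; marginal means are weighted by group size.
    """
    y = np.asarray(y, dtype=float)
    group_index = np.asarray(group_index)
    N, m = y.shape[-2], y.shape[-1]
    groups = np.unique(group_index)
    k = groups.size
    if k < 2 or m < 2:
        raise StopsigError("need >= 2 groups and >= 2 repeated measures")
    n_g = np.array([(group_index == g).sum() for g in groups])
    if (n_g < 2).any():
        raise StopsigError("every group needs >= 2 subjects")

    grand = y.mean(axis=(-2, -1))
    subj_mean = y.mean(axis=-1)                                   # (..., N)
    cond_mean = y.mean(axis=-2)                                   # (..., m)
    group_mean = np.stack(
        [subj_mean[..., group_index == g].mean(axis=-1) for g in groups], axis=-1
    )                                                             # (..., k)
    cell_mean = np.stack(
        [y[..., group_index == g, :].mean(axis=-2) for g in groups], axis=-2
    )                                                             # (..., k, m)

    ss_group = m * (n_g * (group_mean - grand[..., None]) ** 2).sum(axis=-1)
    dev_subj = subj_mean - np.take(group_mean, np.searchsorted(groups, group_index), axis=-1)
    ss_subj = m * (dev_subj**2).sum(axis=-1)
    ss_cond = N * ((cond_mean - grand[..., None]) ** 2).sum(axis=-1)
    inter_dev = (
        cell_mean
        - group_mean[..., :, None]
        - cond_mean[..., None, :]
        + grand[..., None, None]
    )
    ss_inter = (n_g[:, None] * inter_dev**2).sum(axis=(-2, -1))
    cell_for_subj = np.take(cell_mean, np.searchsorted(groups, group_index), axis=-2)
    resid = y - subj_mean[..., :, None] - cell_for_subj + np.take(
        group_mean, np.searchsorted(groups, group_index), axis=-1
    )[..., :, None]
    ss_err = (resid**2).sum(axis=(-2, -1))

    df_group, df_subj = k - 1, N - k
    df_cond = m - 1
    df_inter = (k - 1) * (m - 1)
    df_err = (N - k) * (m - 1)

    # effects whose SS is zero up to float noise report F = 0 even when the
    # error SS is itself degenerate (e.g. an exactly additive within shift)
    total_ss = ss_group + ss_subj + ss_cond + ss_inter + ss_err
    eps = 1e-12 * (total_ss + 1.0)

    def ratio(ss_eff, df_eff, ss_error, df_error):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df_eff) / (ss_error / df_error)
        return np.where(ss_eff <= eps, 0.0, f)

    return {
        "between": (ratio(ss_group, df_group, ss_subj, df_subj), (df_group, df_subj)),
        "within": (ratio(ss_cond, df_cond, ss_err, df_err), (df_cond, df_err)),
        "interaction": (ratio(ss_inter, df_inter, ss_err, df_err), (df_inter, df_err)),
    }


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> AnovaResult:
    """Between-within ANOVA on a long-format table.

    Every subject must contribute one value per level of ``within``. Effects
    are keyed by the ``between`` and ``within`` column names plus
    ``"interaction"``; each carries F, degrees of freedom, p and partial eta
    squared (SS_effect / (SS_effect + SS_error)).
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise StopsigError(f"missing within-subject cells for subjects {missing}")
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    if groups.reindex(wide.index).isna().any():
        raise StopsigError("every subject needs a group label")
    labels = groups.reindex(wide.index).to_numpy()
    codes = pd.factorize(labels, sort=True)[0]
    y = wide.to_numpy()

    raw = split_plot_f_stats(y, codes)
    effects = {}
    for name, key in ((between, "between"), (within, "within"), ("interaction", "interaction")):
        F, (df1, df2) = raw[key]
        F = float(F)
        effects[name] = AnovaEffect(
            F=F,
            df1=df1,
            df2=df2,
            p=float(stats.f.sf(F, df1, df2)),
            partial_eta_sq=partial_eta_squared(F, df1, df2),
        )
    return AnovaResult(effects=effects)


# ---------------------------------------------------------------------------
# Bayes factors


@dataclass(frozen=True)
class BayesFactorResult:
    """t-test Bayes factor under a (shifted, possibly truncated) Cauchy prior."""

    bf10: float
    prior_location: float
    prior_scale: float
    side: str
    numerical_error: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def jzs_bayes_factor(
    t: float,
    n1: int,
    n2: int,
    prior_location: float = 0.0,
    prior_scale: float = 0.707,
    side: str = "two_sided",
) -> BayesFactorResult:
    """Bayes factor BF10 for a two-sample t statistic.

    The alternative places a Cauchy(location, scale) prior on the
    standardized effect size delta, truncated and renormalized to the
    positive or negative half-line for directional hypotheses. BF10 is the
    marginal likelihood of ``t`` under that prior — the noncentral-t density
    with noncentrality delta * sqrt(n1 n2 / (n1 + n2)), integrated over the
    prior by adaptive quadrature — divided by the central-t density at
    delta = 0. ``numerical_error`` is the quadrature's absolute error
    estimate propagated to the BF scale.
    """
    if prior_scale <= 0:
        raise StopsigError("prior_scale must be positive")
    if n1 < 2 or n2 < 2:
        raise StopsigError("each group needs n >= 2")
    if side not in SIDES:
        raise StopsigError(f"unknown side {side!r}")
    df = n1 + n2 - 2
    c = math.sqrt(n1 * n2 / (n1 + n2))
    prior = stats.cauchy(prior_location, prior_scale)
    if side == "positive":
        lo, hi, mass = 0.0, np.inf, prior.sf(0.0)
    elif side == "negative":
        lo, hi, mass = -np.inf, 0.0, prior.cdf(0.0)
    else:
        lo, hi, mass = -np.inf, np.inf, 1.0

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * c) * prior.pdf(delta) / mass

    try:
        # split at the prior center so the quadrature sees the Cauchy peak
        # (quad cannot mix break points with infinite limits)
        edges = [lo] + [p for p in (prior_location,) if lo < p < hi] + [hi]
        num, err = 0.0, 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            v, e = integrate.quad(integrand, a, b, epsabs=1e-12, epsrel=1e-10, limit=300)
            num += v
            err += e
    except Exception as exc:  # pragma: no cover - quadrature failure
        raise NumericalError(f"Bayes-factor quadrature failed: {exc}") from exc
    denom = stats.t.pdf(t, df)
    if num <= 0 or denom <= 0:
        raise NumericalError("degenerate marginal likelihoods in Bayes factor")
    return BayesFactorResult(
        bf10=num / denom,
        prior_location=prior_location,
        prior_scale=prior_scale,
        side=side,
        numerical_error=err / denom,
    )


def bf_robustness(
    t: float, n1: int, n2: int, scales: Sequence[float], side: str = "two_sided"
) -> list[BayesFactorResult]:
    """Bayes factor robustness sweep: location-zero priors across widths."""
    if not scales:
        raise StopsigError("scales must be nonempty")
    return [jzs_bayes_factor(t, n1, n2, 0.0, s, side) for s in scales]


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    conf_level: float
    sidedness: str


def pearson_ci(
    r: float, n: int, conf_level: float = 0.95, sidedness: str = "two_sided"
) -> CorrelationResult:
    """Fisher-z confidence interval for a Pearson correlation.

    Two-sided: both bounds from the Normal interval on atanh(r) with
    SE = 1/sqrt(n - 3). One-sided: a lower bound at the full confidence
    level, the upper bound pinned at 1.
    """
    if abs(r) >= 1.0:
        raise StopsigError("degenerate correlation |r| >= 1")
    if n < 4:
        raise StopsigError("need n >= 4 for a Fisher-z interval")
    if not (0.0 < conf_level < 1.0):
        raise StopsigError("conf_level must lie in (0, 1)")
    if sidedness not in ("two_sided", "one_sided"):
        raise StopsigError(f"unknown sidedness {sidedness!r}")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    if sidedness == "two_sided":
        crit = stats.norm.ppf((1 + conf_level) / 2)
        lo, hi = math.tanh(z - crit * se), math.tanh(z + crit * se)
    else:
        crit = stats.norm.ppf(conf_level)
        lo, hi = math.tanh(z - crit * se), 1.0
    return CorrelationResult(r=r, n=n, ci_low=lo, ci_high=hi, conf_level=conf_level,
                             sidedness=sidedness)


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int, sidedness: str = "two_sided"
) -> tuple[float, float]:
    """Fisher-z test for equality of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the one-sided p
    tests r1 > r2.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise StopsigError("degenerate correlation |r| >= 1")
        if n < 4:
            raise StopsigError("need n >= 4")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    if sidedness == "two_sided":
        p = 2 * stats.norm.sf(abs(z))
    elif sidedness == "one_sided":
        p = stats.norm.sf(z)
    else:
        raise StopsigError(f"unknown sidedness {sidedness!r}")
    return float(z), float(p)


# ---------------------------------------------------------------------------
# a-priori power for the between-groups effect of a mixed design


def power_mixed_anova_between(
    f: float,
    n_total: int,
    alpha: float = 0.05,
    n_groups: int = 2,
    n_measures: int = 2,
    rho: float = 0.5,
) -> float:
    """Power of the between-groups F test in a between-within design.

    Uses the noncentral-F approximation with noncentrality
    lambda = f^2 N m / (1 + (m - 1) rho), where rho is the assumed
    correlation among the repeated measures (averaging m correlated measures
    shrinks the between-subject error).
    """
    if f <= 0:
        raise StopsigError("effect size f must be positive")
    if not (0.0 < alpha < 1.0):
        raise StopsigError("alpha must lie in (0, 1)")
    if not (-1.0 < rho < 1.0):
        raise StopsigError("rho must lie in (-1, 1)")
    df1, df2 = n_groups - 1, n_total - n_groups
    if df2 < 1:
        raise StopsigError("n_total too small for the design")
    lam = f**2 * n_total * n_measures / (1 + (n_measures - 1) * rho)
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sample_size_mixed_anova(
    f: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_groups: int = 2,
    n_measures: int = 2,
    rho: float = 0.5,
    max_n: int = 100_000,
) -> int:
    """Smallest total N (multiple of n_groups) reaching the target power.

    The assumed repeated-measures correlation ``rho`` and the targeted effect
    (the between-groups test) are explicit parameters: the published
    sample-size arithmetic cannot be reproduced without fixing them.
    """
    if not (0.0 < power < 1.0):
        raise StopsigError("power must lie in (0, 1)")
    n = 2 * n_groups
    while n <= max_n:
        if power_mixed_anova_between(f, n, alpha, n_groups, n_measures, rho) >= power:
            return n
        n += n_groups
    raise NumericalError(f"power {power} unreachable below N = {max_n} for f = {f}")
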