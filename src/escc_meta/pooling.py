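"""Fixed-effect and DerSimonian–Laird random-effects meta-analysis.

All pooling happens on the log-OR scale.  The fixed-effect model weights each
study by its inverse variance; the random-effects model adds the
DerSimonian–Laird moment estimate of the between-study variance tau² to every
study variance before weighting.  Heterogeneity is summarised by Cochran's Q
(always computed with the fixed-effect weights) and Higgins' I² on the
percent scale.

Model selection follows the common I² rule used in this evidence base:
fixed effect when I² ≤ 50%, random effects above.  The module also provides
leave-one-out sensitivity analysis, subgroup analysis with an interaction
test, and single-covariate method-of-moments meta-regression.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .records import (
    EffectEstimate,
    StudyRecord,
    ValidationError,
    Z_95,
    effect_from_record,
)

__all__ = [
    "PooledResult",
    "Heterogeneity",
    "SubgroupResult",
    "MetaRegressionResult",
    "as_effects",
    "pool_fixed",
    "pool_random_dl",
    "pool_auto",
    "heterogeneity",
    "select_model",
    "leave_one_out",
    "subgroup_analysis",
    "meta_regression",
]


@dataclass(frozen=True)
class PooledResult:
    """A pooled log-OR with its CI, heterogeneity statistics and model tag."""

    k: int
    model_type: str  # "fixed" | "random"
    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    q_stat: float
    df: int
    p_q: float
    i2: float
    tau2: float

    @property
    def or_point(self) -> float:
        return math.exp(self.mu_hat)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value for the pooled effect against OR = 1."""
        return 2.0 * stats.norm.sf(abs(self.mu_hat) / self.se)


class Heterogeneity(NamedTuple):
    q_stat: float
    df: int
    p_q: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class SubgroupResult:
    group_key: str
    per_group: "OrderedDict[str, PooledResult]"
    p_interaction: float
    singleton_groups: tuple[str, ...] = ()


@dataclass(frozen=True)
class MetaRegressionResult:
    covariate: str
    slope: float
    se_slope: float
    p_slope: float
    intercept: float
    tau2_residual: float


def as_effects(
    items: Sequence[EffectEstimate] | Sequence[StudyRecord],
) -> list[EffectEstimate]:
    """Accept either effect estimates or study records (auto-converting)."""
    out: list[EffectEstimate] = []
    for it in items:
        if isinstance(it, EffectEstimate):
            out.append(it)
        elif isinstance(it, StudyRecord):
            out.append(effect_from_record(it))
        else:
            raise TypeError(f"expected EffectEstimate or StudyRecord, got {type(it)!r}")
    return out


def _theta_se(estimates: Sequence[EffectEstimate] | Sequence[StudyRecord]):
    eff = as_effects(estimates)
    if not eff:
        raise ValidationError("no estimates supplied")
    theta = np.array([e.log_or for e in eff], dtype=float)
    se = np.array([e.se for e in eff], dtype=float)
    return theta, se


def _fixed_core(theta: np.ndarray, se: np.ndarray):
    w = 1.0 / se**2
    mu = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - mu) ** 2))
    return w, mu, pooled_se, q


def _het_from_q(q: float, df: int) -> tuple[float, float]:
    if df <= 0:
        return 1.0, 0.0
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return p_q, i2


def _single(theta: float, se: float) -> PooledResult:
    return PooledResult(
        k=1, model_type="fixed", mu_hat=theta, se=se,
        ci_low=theta - Z_95 * se, ci_high=theta + Z_95 * se,
        q_stat=0.0, df=0, p_q=1.0, i2=0.0, tau2=0.0,
    )


def pool_fixed(estimates: Sequence[EffectEstimate] | Sequence[StudyRecord]) -> PooledResult:
    """Inverse-variance fixed-effect pooling on the log-OR scale."""
    theta, se = _theta_se(estimates)
    k = len(theta)
    if k == 1:
        return _single(float(theta[0]), float(se[0]))
    _, mu, pooled_se, q = _fixed_core(theta, se)
    p_q, i2 = _het_from_q(q, k - 1)
    return PooledResult(
        k=k, model_type="fixed", mu_hat=mu, se=pooled_se,
        ci_low=mu - Z_95 * pooled_se, ci_high=mu + Z_95 * pooled_se,
        q_stat=q, df=k - 1, p_q=p_q, i2=i2, tau2=0.0,
    )


def _dl_tau2(theta: np.ndarray, se: np.ndarray) -> float:
    w, _, _, q = _fixed_core(theta, se)
    k = len(theta)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (k - 1)) / c)


def pool_random_dl(estimates: Sequence[EffectEstimate] | Sequence[StudyRecord]) -> PooledResult:
    """DerSimonian–Laird random-effects pooling.

    Q and I² are reported from the fixed-weight pass; tau² is the (truncated)
    moment estimate.  With tau² = 0 this reduces exactly to :func:`pool_fixed`
    apart from the model tag.
    """
    theta, se = _theta_se(estimates)
    k = len(theta)
    if k == 1:
        return _single(float(theta[0]), float(se[0]))
    _, _, _, q = _fixed_core(theta, se)
    tau2 = _dl_tau2(theta, se)
    w_star = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w_star * theta) / np.sum(w_star))
    pooled_se = float(np.sum(w_star) ** -0.5)
    p_q, i2 = _het_from_q(q, k - 1)
    return PooledResult(
        k=k, model_type="random", mu_hat=mu, se=pooled_se,
        ci_low=mu - Z_95 * pooled_se, ci_high=mu + Z_95 * pooled_se,
        q_stat=q, df=k - 1, p_q=p_q, i2=i2, tau2=tau2,
    )


def heterogeneity(estimates: Sequence[EffectEstimate] | Sequence[StudyRecord]) -> Heterogeneity:
    """Cochran's Q, its p-value, Higgins' I² (percent), and DL tau²."""
    theta, se = _theta_se(estimates)
    k = len(theta)
    if k < 2:
        raise ValidationError(f"heterogeneity requires k >= 2, got k={k}")
    _, _, _, q = _fixed_core(theta, se)
    p_q, i2 = _het_from_q(q, k - 1)
    return Heterogeneity(q_stat=q, df=k - 1, p_q=p_q, i2=i2, tau2=_dl_tau2(theta, se))


def select_model(i2: float) -> str:
    """I² ≤ 50% → fixed effect; I² > 50% → random effects.

    The published rule leaves I² exactly 50 unassigned; it is assigned to the
    fixed-effect side here.
    """
    if not (0.0 <= i2 < 100.0):
        raise ValidationError(f"i2 must lie in [0, 100), got {i2}")
    return "fixed" if i2 <= 50.0 else "random"


def pool_auto(estimates: Sequence[EffectEstimate] | Sequence[StudyRecord]) -> PooledResult:
    """Pool with the model chosen by the I² rule."""
    eff = as_effects(estimates)
    if len(eff) == 1:
        return pool_fixed(eff)
    het = heterogeneity(eff)
    if select_model(het.i2) == "fixed":
        return pool_fixed(eff)
    return pool_random_dl(eff)


def leave_one_out(
    estimates: Sequence[EffectEstimate] | Sequence[StudyRecord],
) -> list[PooledResult]:
    """Re-pool k times, omitting one study each time (model re-selected per subset)."""
    eff = as_effects(estimates)
    k = len(eff)
    if k < 3:
        raise ValidationError(f"leave-one-out requires k >= 3, got k={k}")
    return [pool_auto(eff[:i] + eff[i + 1:]) for i in range(k)]


def subgroup_analysis(
    records: Sequence[StudyRecord],
    group_key: str | Callable[[StudyRecord], str],
) -> SubgroupResult:
    """Pool within groups and test for a between-group difference.

    With two groups the interaction p comes from the normal z-test on the
    difference of pooled log-ORs; with more, from the Q-between chi-square
    statistic on G − 1 df.  Singleton groups are pooled (k = 1 passthrough)
    but flagged.
    """
    if callable(group_key):
        labeller, key_name = group_key, getattr(group_key, "__name__", "custom")
    else:
        key_name = group_key
        labeller = lambda r: str(getattr(r, group_key))  # noqa: E731

    groups: OrderedDict[str, list[StudyRecord]] = OrderedDict()
    for rec in records:
        groups.setdefault(labeller(rec), []).append(rec)
    if len(groups) < 2:
        raise ValidationError(
            f"subgroup analysis needs >= 2 groups; grouping by {key_name!r} gave {len(groups)}"
        )

    per_group: OrderedDict[str, PooledResult] = OrderedDict(
        (label, pool_auto(members)) for label, members in groups.items()
    )
    singletons = tuple(label for label, res in per_group.items() if res.k == 1)

    results = list(per_group.values())
    if len(results) == 2:
        a, b = results
        z = (a.mu_hat - b.mu_hat) / math.hypot(a.se, b.se)
        p_int = float(2.0 * stats.norm.sf(abs(z))) if z != 0 else 1.0
    else:
        wg = np.array([1.0 / r.se**2 for r in results])
        mug = np.array([r.mu_hat for r in results])
        mu_bar = float(np.sum(wg * mug) / np.sum(wg))
        q_between = float(np.sum(wg * (mug - mu_bar) ** 2))
        p_int = float(stats.chi2.sf(q_between, len(results) - 1))
    return SubgroupResult(
        group_key=key_name, per_group=per_group, p_interaction=p_int,
        singleton_groups=singletons,
    )


def meta_regression(
    estimates: Sequence[EffectEstimate] | Sequence[StudyRecord],
    covariate: Sequence[float],
    covariate_name: str = "covariate",
) -> MetaRegressionResult:
    """Single-covariate random-effects meta-regression.

    The residual between-study variance is estimated by the method of moments
    from the fixed-weight residual Q; the final fit uses weights
    1/(s² + tau²).  The slope p-value uses a t reference with k − 2 df
    (no Knapp–Hartung variance inflation).
    """
    theta, se = _theta_se(estimates)
    k = len(theta)
    x = np.asarray(covariate, dtype=float)
    if k < 3:
        raise ValidationError(f"meta-regression requires k >= 3, got k={k}")
    if x.shape != (k,):
        raise ValidationError(f"covariate length {x.shape} does not match k={k}")
    if np.ptp(x) == 0:
        raise ValidationError("covariate is constant")

    X = np.column_stack([np.ones(k), x])
    w0 = 1.0 / se**2
    # fixed-weight WLS pass -> residual Q and the moment tau² estimate
    xtwx = X.T @ (w0[:, None] * X)
    beta0 = np.linalg.solve(xtwx, X.T @ (w0 * theta))
    resid0 = theta - X @ beta0
    q_e = float(np.sum(w0 * resid0**2))
    trace_p = float(np.sum(w0) - np.trace(np.linalg.solve(xtwx, X.T @ (w0[:, None] ** 2 * X))))
    tau2 = max(0.0, (q_e - (k - 2)) / trace_p)

    w = 1.0 / (se**2 + tau2)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * theta))
    cov = np.linalg.inv(xtwx)  # model-based: study variances are known
    se_slope = float(np.sqrt(cov[1, 1]))
    tstat = beta[1] / se_slope
    p_slope = float(2.0 * stats.t.sf(abs(tstat), df=k - 2))
    return MetaRegressionResult(
        covariate=covariate_name, slope=float(beta[1]), se_slope=se_slope,
        p_slope=p_slope, intercept=float(beta[0]), tau2_residual=tau2,
    )
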