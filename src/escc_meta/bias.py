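"""Small-study and publication-bias diagnostics.

Funnel-plot coordinates, Begg–Mazumdar's rank-correlation test, and Egger's
regression test.  Begg's test correlates the variance-standardized deviations
from the fixed-effect pooled estimate with the study variances; small
meta-analyses (k ≤ 6) use the exact permutation null for Kendall's S, larger
ones the tie-corrected normal approximation with a continuity correction.
Egger's test regresses the standardized effect θ/s on precision 1/s and asks
whether the intercept differs from zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import EffectEstimate, StudyRecord, ValidationError
from .pooling import PooledResult, as_effects, pool_fixed

__all__ = ["FunnelData", "BiasTestResult", "funnel_data", "beggs_test", "eggers_test"]

#: below k ≤ this, Begg's p comes from the exact permutation distribution
EXACT_PERMUTATION_MAX_K = 6

#: variance floor applied when a study variance does not exceed the pooled one
_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class FunnelData:
    points: tuple[tuple[float, float], ...]  # (log_or, se) per study, input order
    center: float  # pooled log-OR of the selected model


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # "begg" | "egger"
    statistic: float  # Kendall's tau (begg) or regression intercept (egger)
    se_or_scale: float
    p_value: float


def funnel_data(
    estimates: Sequence[EffectEstimate] | Sequence[StudyRecord],
    pooled: PooledResult,
) -> FunnelData:
    """Per-study (log-OR, SE) coordinates centred on the pooled estimate."""
    eff = as_effects(estimates)
    if len(eff) < 2:
        raise ValidationError(f"funnel data requires k >= 2, got k={len(eff)}")
    return FunnelData(
        points=tuple((e.log_or, e.se) for e in eff),
        center=pooled.mu_hat,
    )


def _kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    s = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


def _tie_counts(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _kendall_var(n: int, x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected null variance of Kendall's S (Kendall 1970)."""
    t = _tie_counts(x)
    u = _tie_counts(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(t * (t - 1) * (2 * t + 5)) if t.size else 0.0
    vu = np.sum(u * (u - 1) * (2 * u + 5)) if u.size else 0.0
    var = (v0 - vt - vu) / 18.0
    if t.size and u.size:
        var += (np.sum(t * (t - 1)) * np.sum(u * (u - 1))) / (2.0 * n * (n - 1))
        var += (
            np.sum(t * (t - 1) * (t - 2)) * np.sum(u * (u - 1) * (u - 2))
        ) / (9.0 * n * (n - 1) * (n - 2))
    return float(var)


def _tau_b(s: int, n: int, x: np.ndarray, y: np.ndarray) -> float:
    n_pairs = n * (n - 1) / 2.0
    t = _tie_counts(x)
    u = _tie_counts(y)
    tx = np.sum(t * (t - 1) / 2.0) if t.size else 0.0
    ty = np.sum(u * (u - 1) / 2.0) if u.size else 0.0
    denom = math.sqrt((n_pairs - tx) * (n_pairs - ty))
    return s / denom if denom > 0 else 0.0


def beggs_test(
    estimates: Sequence[EffectEstimate] | Sequence[StudyRecord],
) -> BiasTestResult:
    """Begg–Mazumdar rank correlation between standardized deviates and variance.

    Deviates are t_i = (θ_i − μ̂_fixed)/√(s_i² − se_fixed²); a study whose
    variance does not exceed the pooled variance gets a floored denominator
    (with a warning).  Two-sided p.
    """
    eff = as_effects(estimates)
    n = len(eff)
    if n < 3:
        raise ValidationError(f"Begg's test requires k >= 3, got k={n}")
    theta = np.array([e.log_or for e in eff])
    se = np.array([e.se for e in eff])
    pooled = pool_fixed(eff)
    v = se**2 - pooled.se**2
    if np.any(v <= 0):
        warnings.warn(
            "Begg's test: some study variances do not exceed the pooled variance; "
            "flooring the standardizing denominator",
            RuntimeWarning,
            stacklevel=2,
        )
        v = np.maximum(v, _VARIANCE_FLOOR)
    deviates = (theta - pooled.mu_hat) / np.sqrt(v)
    variances = se**2

    s = _kendall_s(variances, deviates)
    tau = _tau_b(s, n, variances, deviates)

    if n <= EXACT_PERMUTATION_MAX_K:
        perm_s = [
            abs(_kendall_s(variances, np.array(p)))
            for p in itertools.permutations(deviates)
        ]
        p_value = float(np.mean([ps >= abs(s) for ps in perm_s]))
        se_scale = float(np.std(perm_s))
    else:
        var_s = _kendall_var(n, variances, deviates)
        se_scale = math.sqrt(var_s)
        z = max(0.0, (abs(s) - 1.0)) / se_scale  # continuity correction
        p_value = float(2.0 * stats.norm.sf(z))
    return BiasTestResult(method="begg", statistic=float(tau), se_or_scale=se_scale,
                          p_value=min(1.0, p_value))


def eggers_test(
    estimates: Sequence[EffectEstimate] | Sequence[StudyRecord],
) -> BiasTestResult:
    """Egger's regression test: OLS of θ_i/s_i on 1/s_i, intercept tested vs 0."""
    eff = as_effects(estimates)
    n = len(eff)
    if n < 3:
        raise ValidationError(f"Egger's test requires k >= 3, got k={n}")
    theta = np.array([e.log_or for e in eff])
    se = np.array([e.se for e in eff])
    z = theta / se
    precision = 1.0 / se

    X = np.column_stack([np.ones(n), precision])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    # pinv handles the degenerate all-equal-SE regressor (constant precision)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se_int = math.sqrt(max(cov[0, 0], 0.0))
    intercept = float(beta[0])
    scale = max(1.0, float(np.mean(z**2)))
    if sigma2 <= 1e-20 * scale:
        # numerically exact fit: a (near-)zero intercept carries no evidence
        # of asymmetry; a genuinely nonzero one is unambiguous
        p_value = 1.0 if abs(intercept) <= 1e-8 * math.sqrt(scale) else 0.0
        se_int = 0.0
    else:
        tstat = intercept / se_int
        p_value = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return BiasTestResult(method="egger", statistic=intercept, se_or_scale=se_int,
                          p_value=p_value)
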