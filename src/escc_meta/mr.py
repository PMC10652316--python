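"""Two-sample Mendelian randomization from GWAS summary statistics.

Given per-SNP effects on an exposure (here: alcohol intake) and on an outcome
(esophageal cancer, on the log-odds scale), the module selects independent
genome-wide-significant instruments and estimates the causal effect with the
inverse-variance-weighted (IVW) estimator, the weighted median, and MR-Egger
regression, with Cochran's Q and the Egger intercept as heterogeneity and
directional-pleiotropy diagnostics.

Inputs are assumed pre-harmonized: every beta pair must already refer to the
same effect allele.  No allele flipping or palindromic-SNP handling is done
here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import ValidationError, Z_95

__all__ = [
    "MRInstrument",
    "MREstimate",
    "select_instruments",
    "ivw",
    "weighted_median",
    "mr_egger",
    "load_instruments",
]

INSTRUMENT_FIELDS = [
    "snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "p_exposure",
]


@dataclass(frozen=True)
class MRInstrument:
    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    p_exposure: float
    chromosome: str | None = None
    bp: int | None = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")
        if not (0.0 <= self.p_exposure <= 1.0):
            raise ValidationError(f"{self.snp_id}: p_exposure must lie in [0, 1]")


@dataclass(frozen=True)
class MREstimate:
    method: str  # "ivw" | "wald_ratio" | "weighted_median" | "mr_egger"
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    q_stat: float | None = None
    p_q: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def _ld_lookup(ld, instruments: Sequence[MRInstrument]):
    """Return r²(i, j) accessor for an LD matrix given as DataFrame or ndarray."""
    if isinstance(ld, pd.DataFrame):
        return lambda a, b: float(ld.loc[a.snp_id, b.snp_id])
    arr = np.asarray(ld, dtype=float)
    idx = {ins.snp_id: i for i, ins in enumerate(instruments)}
    return lambda a, b: float(arr[idx[a.snp_id], idx[b.snp_id]])


def select_instruments(
    candidates: Sequence[MRInstrument],
    p_threshold: float = 5e-8,
    ld=None,
    r2_threshold: float = 0.05,
    window_bp: int = 10_000_000,
) -> list[MRInstrument]:
    """Keep genome-wide-significant SNPs, then greedily prune LD neighbours.

    Survivors are visited in ascending p_exposure (ties broken by snp_id); a
    SNP is dropped if an already-kept SNP on the same chromosome within
    ``window_bp`` has r² ≥ ``r2_threshold``.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValidationError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    if not (0.0 < r2_threshold < 1.0):
        raise ValidationError(f"r2_threshold must lie in (0, 1), got {r2_threshold}")
    survivors = [c for c in candidates if c.p_exposure < p_threshold]
    if ld is None:
        return sorted(survivors, key=lambda c: (c.p_exposure, c.snp_id))
    if any(c.chromosome is None or c.bp is None for c in survivors):
        raise ValidationError("LD pruning with a window requires chromosome and bp positions")
    r2 = _ld_lookup(ld, candidates)
    kept: list[MRInstrument] = []
    for cand in sorted(survivors, key=lambda c: (c.p_exposure, c.snp_id)):
        linked = any(
            k.chromosome == cand.chromosome
            and abs(k.bp - cand.bp) <= window_bp
            and r2(k, cand) >= r2_threshold
            for k in kept
        )
        if not linked:
            kept.append(cand)
    return kept


def _arrays(instruments: Sequence[MRInstrument]):
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    sx = np.array([i.se_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sy = np.array([i.se_outcome for i in instruments], dtype=float)
    return bx, sx, by, sy


def _finish(method: str, beta: float, se: float, k: int, **extra) -> MREstimate:
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z_95 * se, ci_high=beta + Z_95 * se,
        p_value=p, n_snps=k, **extra,
    )


def ivw(
    instruments: Sequence[MRInstrument],
    multiplicative: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    Algebraically the fixed-effect meta-analysis of the per-SNP Wald ratios
    βY/βX weighted by (βX/σY)².  With ``multiplicative=True`` the SE is
    inflated by √(Q/(k−1)) when Q exceeds its df (multiplicative random
    error).  A single instrument degenerates to the Wald ratio.
    """
    if not instruments:
        raise ValidationError("no instruments supplied")
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k == 1:
        if bx[0] == 0:
            raise ValidationError("Wald ratio undefined: beta_exposure is zero")
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        return _finish("wald_ratio", beta, se, 1)
    wy = 1.0 / sy**2
    denom = float(np.sum(bx**2 * wy))
    beta = float(np.sum(bx * by * wy) / denom)
    se = denom**-0.5
    # Cochran's Q over per-SNP Wald ratios with weights (βX/σY)²
    nz = bx != 0
    ratios = by[nz] / bx[nz]
    wq = (bx[nz] / sy[nz]) ** 2
    q = float(np.sum(wq * (ratios - beta) ** 2))
    p_q = float(stats.chi2.sf(q, int(nz.sum()) - 1)) if nz.sum() > 1 else 1.0
    if multiplicative and q > nz.sum() - 1:
        se *= math.sqrt(q / (nz.sum() - 1))
    return _finish("ivw", beta, se, k, q_stat=q, p_q=p_q)


def weighted_median(
    instruments: Sequence[MRInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments carrying at least half of the total weight
    are valid.  The SE resamples (βX, βY) from normal sampling distributions
    ``n_boot`` times under the stored ``seed``.
    """
    if len(instruments) < 3:
        raise ValidationError(f"weighted median requires k >= 3, got k={len(instruments)}")
    usable = [i for i in instruments if i.beta_exposure != 0]
    if len(usable) < len(instruments):
        warnings.warn("weighted median: excluding instruments with zero beta_exposure",
                      RuntimeWarning, stacklevel=2)
    if len(usable) < 3:
        raise ValidationError("fewer than 3 usable instruments after excluding zero betas")
    bx, sx, by, sy = _arrays(usable)

    def wm(bx_, by_):
        ratios = by_ / bx_
        weights = bx_**2 / sy**2
        order = np.argsort(ratios)
        r = ratios[order]
        w = weights[order] / np.sum(weights)
        cum = np.cumsum(w) - w / 2.0
        return float(np.interp(0.5, cum, r))

    beta = wm(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = wm(rng.normal(bx, sx), rng.normal(by, sy))
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, len(usable))


def mr_egger(instruments: Sequence[MRInstrument]) -> MREstimate:
    """MR-Egger: weighted regression of βY on βX with a free intercept.

    All instruments are first oriented so that βX ≥ 0; weights are 1/σY².
    The slope is the causal estimate, the intercept the average directional
    pleiotropy (t test with k − 2 df), and Q is computed over the weighted
    residuals.
    """
    if len(instruments) < 3:
        raise ValidationError(f"MR-Egger requires k >= 3, got k={len(instruments)}")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValidationError("MR-Egger requires spread in |beta_exposure|")
    k = len(bx)
    X = sm.add_constant(bx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels complains on exact fits
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_slope = float(fit.bse[1])
    se_int = float(fit.bse[0])
    if se_int > 0 and math.isfinite(se_int):
        p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df=k - 2))
    else:
        p_int = 1.0 if math.isclose(intercept, 0.0, abs_tol=1e-12) else 0.0
    resid = by - fit.fittedvalues
    q = float(np.sum(resid**2 / sy**2))
    p_q = float(stats.chi2.sf(q, k - 2))
    if se_slope > 0 and math.isfinite(se_slope):
        p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df=k - 2))
    else:
        p_slope = 1.0 if math.isclose(slope, 0.0, abs_tol=1e-12) else 0.0
        se_slope = 0.0
    return MREstimate(
        method="mr_egger", beta=slope, se=se_slope,
        ci_low=slope - Z_95 * se_slope, ci_high=slope + Z_95 * se_slope,
        p_value=p_slope, n_snps=k,
        intercept=intercept, se_intercept=se_int, p_intercept=p_int,
        q_stat=q, p_q=p_q,
    )


def load_instruments(path, delimiter: str = ",") -> list[MRInstrument]:
    """Read a delimited summary-statistics table of instruments."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in INSTRUMENT_FIELDS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(MRInstrument(
            snp_id=str(row.snp_id),
            beta_exposure=float(row.beta_exposure),
            se_exposure=float(row.se_exposure),
            beta_outcome=float(row.beta_outcome),
            se_outcome=float(row.se_outcome),
            p_exposure=float(row.p_exposure),
            chromosome=str(row.chromosome) if "chromosome" in df.columns else None,
            bp=int(row.bp) if "bp" in df.columns else None,
        ))
    return out
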