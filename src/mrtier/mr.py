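"""Two-sample MR estimators and multiple-testing control.

Implements the Wald ratio with a two-term delta-method (Taylor) standard
error for single-instrument exposures, multiplicative random-effects IVW with
Cochran's Q for multi-instrument exposures, MR-Egger regression for
directional pleiotropy, and Benjamini-Hochberg / Bonferroni appraisal of the
resulting p-values.

Effect inputs are harmonised per-allele effects: ``bx, sx`` variant-exposure,
``by, sy`` variant-outcome.  Wald/IVW p-values use the normal approximation;
Egger slope and intercept use the t distribution with k-2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientInstrumentsError, UndefinedRatioError


@dataclass
class MRResult:
    exposure_id: str
    outcome_id: str
    method: str  # wald | ivw | egger
    beta_mr: float
    se_mr: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


@dataclass
class MultipleTestingResult:
    pvals: np.ndarray
    q_values: np.ndarray
    fdr_pass: np.ndarray
    bonferroni_threshold: float
    bonferroni_pass: np.ndarray
    fdr_level: float
    alpha: float
    n_tests_bonferroni: int


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(
    bx: float, sx: float, by: float, sy: float,
    exposure_id: str = "", outcome_id: str = "",
) -> MRResult:
    """Single-instrument causal estimate by/bx with two-term Taylor SE.

    se = sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4), the second-order delta-method
    expansion of the ratio's sampling variance.
    """
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined for zero exposure effect")
    if sx <= 0 or sy <= 0:
        raise ValueError("standard errors must be positive")
    beta = by / bx
    se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return MRResult(exposure_id, outcome_id, "wald", beta, se, _norm_p(beta / se), 1)


def ivw(
    bx: Sequence[float], sx: Sequence[float], by: Sequence[float], sy: Sequence[float],
    exposure_id: str = "", outcome_id: str = "",
) -> MRResult:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Zero-intercept weighted regression of by on bx with weights 1/sy^2; the
    fixed-effect SE is inflated by max(1, sqrt(Q/(k-1))) so that
    between-instrument heterogeneity widens the interval but never narrows it.
    """
    bx, sx = np.asarray(bx, float), np.asarray(sx, float)
    by, sy = np.asarray(by, float), np.asarray(sy, float)
    k = bx.size
    if k < 2:
        raise InsufficientInstrumentsError("IVW requires >= 2 instruments; use wald_ratio")
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_df = k - 1
    inflate = max(1.0, math.sqrt(q / q_df))
    se = se_fixed * inflate
    return MRResult(
        exposure_id, outcome_id, "ivw", beta, se, _norm_p(beta / se), k,
        q_stat=q, q_df=q_df, q_pval=float(stats.chi2.sf(q, q_df)),
    )


def egger(
    bx: Sequence[float], sx: Sequence[float], by: Sequence[float], sy: Sequence[float],
    exposure_id: str = "", outcome_id: str = "",
) -> MRResult:
    """MR-Egger weighted regression with intercept (directional pleiotropy test).

    Pairs are re-oriented so all exposure effects are non-negative (negating
    both members), then by is regressed on bx with weights 1/sy^2.  Slope and
    intercept inference uses t with k-2 df and the regression-estimated
    residual scale, as in standard MR-Egger practice.
    """
    bx, sx = np.asarray(bx, float), np.asarray(sx, float)
    by, sy = np.asarray(by, float), np.asarray(sy, float)
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    icpt, slope = fit.params
    icpt_se, slope_se = fit.bse
    icpt_p, slope_p = fit.pvalues
    return MRResult(
        exposure_id, outcome_id, "egger",
        float(slope), float(slope_se), float(slope_p), k,
        egger_intercept=float(icpt), egger_intercept_se=float(icpt_se),
        egger_intercept_pval=float(icpt_p),
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def display_threshold(alpha: float, n_tests: int, sig_figs: int = 1) -> float:
    """Threshold rounded to sig_figs significant figures (presentation only)."""
    x = bonferroni_threshold(alpha, n_tests)
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + sig_figs - 1)


def adjust_pvalues(
    pvals: Sequence[float],
    alpha: float = 0.05,
    n_tests_bonferroni: int | None = None,
    fdr_level: float = 0.05,
) -> MultipleTestingResult:
    """BH step-up q-values plus a Bonferroni gate at alpha/n_tests.

    ``n_tests_bonferroni`` may exceed len(pvals) when the gate is defined over
    a larger family of tests than the p-values at hand; gating always uses the
    exact ratio, never a display-rounded value.
    """
    p = np.asarray(list(pvals), float)
    if n_tests_bonferroni is None:
        n_tests_bonferroni = p.size
    if p.size == 0:
        thr = bonferroni_threshold(alpha, max(n_tests_bonferroni, 1))
        empty = np.array([])
        return MultipleTestingResult(p, empty, empty.astype(bool), thr,
                                     empty.astype(bool), fdr_level, alpha,
                                     n_tests_bonferroni)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if n_tests_bonferroni < p.size:
        raise ValueError("n_tests_bonferroni must be >= number of p-values")
    _, q, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    thr = bonferroni_threshold(alpha, n_tests_bonferroni)
    return MultipleTestingResult(
        pvals=p, q_values=q, fdr_pass=q <= fdr_level,
        bonferroni_threshold=thr, bonferroni_pass=p <= thr,
        fdr_level=fdr_level, alpha=alpha, n_tests_bonferroni=n_tests_bonferroni,
    )
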