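"""Colocalisation with Wakefield approximate Bayes factors, conditional
analysis of summary statistics, and pairwise conditional colocalisation.

``coloc_posteriors`` evaluates the five single-causal-variant hypotheses for
a pair of traits over one region: H0 no association, H1/H2 association with
one trait only, H3 two distinct causal variants, H4 one shared causal
variant.  Per-SNP evidence is the Wakefield log approximate Bayes factor

    log ABF = 0.5 * [ log(v/(v+w)) + z^2 * w/(v+w) ]

with v the squared standard error and w the squared prior effect s.d.
Hypothesis sums are accumulated in log space over all single-variant
configurations with per-SNP priors p1, p2 and p12.

``conditional_stats`` / ``stepwise_select`` implement joint/conditional
estimation from marginal summary statistics and an LD panel (COJO-style), and
``pwcoco`` combines them: each region is decomposed into conditionally
independent signals and every exposure-signal x outcome-signal pair is
colocalised alongside the marginal-marginal pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import EmptyOverlapError
from .gwas_io import RegionDataset
from .ld import LDReference

__all__ = [
    "LDReference", "ColocResult", "ConditionalSignal", "PWCoCoResult",
    "log_abf", "coloc_posteriors", "conditional_stats", "stepwise_select", "pwcoco",
    "DEFAULT_PRIORS", "PRIOR_SD",
]

#: per-SNP configuration priors (p1, p2, p12)
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: Wakefield prior effect standard deviation by trait type
PRIOR_SD = {"quantitative": 0.15, "case_control": 0.2}

DEFAULT_P_SELECT = 5e-8
DEFAULT_COLLINEARITY_R2 = 0.9
DEFAULT_FREQ_TOL = 0.2
MAX_SIGNALS = 10


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    priors: tuple[float, float, float]
    per_snp_log_abf: pd.DataFrame | None = None

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


@dataclass
class ConditionalSignal:
    lead_variant_id: str
    conditional_dataset: RegionDataset


@dataclass
class PWCoCoResult:
    pair_results: list[tuple[str, str, ColocResult]] = field(default_factory=list)

    @property
    def max_h4(self) -> float:
        return max(r.pp_h4 for _, _, r in self.pair_results)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "exposure_signal": a, "outcome_signal": b, "n_snps": r.n_snps,
                "PP.H0": r.pp_h0, "PP.H1": r.pp_h1, "PP.H2": r.pp_h2,
                "PP.H3": r.pp_h3, "PP.H4": r.pp_h4,
            }
            for a, b, r in self.pair_results
        ]
        return pd.DataFrame(rows)


def log_abf(z: float, v: float, w: float) -> float:
    """Wakefield log approximate Bayes factor for one variant."""
    if v <= 0 or w <= 0:
        raise ValueError("v and w must be positive")
    r = w / (v + w)
    return 0.5 * (math.log(v / (v + w)) + z * z * r)


def dataset_log_abf(ds: RegionDataset, prior_sd: float | None = None) -> np.ndarray:
    """Vector of per-SNP Wakefield log-ABFs for one trait."""
    if prior_sd is None:
        prior_sd = PRIOR_SD[ds.trait.trait_type]
    z = ds.variants["beta"].to_numpy() / ds.variants["se"].to_numpy()
    v = ds.variants["se"].to_numpy() ** 2
    w = prior_sd**2
    r = w / (v + w)
    return 0.5 * (np.log(v / (v + w)) + z**2 * r)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_posteriors(
    d1: RegionDataset,
    d2: RegionDataset,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    keep_per_snp: bool = False,
) -> ColocResult:
    """Posterior probabilities of H0-H4 for two harmonised datasets.

    Datasets are matched on variant_id (the shared set must be non-empty);
    each trait's prior effect s.d. follows its trait type.
    """
    p1, p2, p12 = priors
    ids1, ids2 = set(d1.ids), set(d2.ids)
    shared = ids1 & ids2
    if not shared:
        raise EmptyOverlapError("no shared variants for colocalisation")
    a = d1.variants[d1.variants["variant_id"].isin(shared)].sort_values("variant_id")
    b = d2.variants[d2.variants["variant_id"].isin(shared)].sort_values("variant_id")
    da = RegionDataset(trait=d1.trait, variants=a.reset_index(drop=True))
    db = RegionDataset(trait=d2.trait, variants=b.reset_index(drop=True))

    l1 = dataset_log_abf(da)
    l2 = dataset_log_abf(db)
    m = l1.size

    lsum1 = float(logsumexp(l1))
    lsum2 = float(logsumexp(l2))
    lsum12 = float(logsumexp(l1 + l2))
    # sum over i != j of exp(l1_i + l2_j)
    lh3 = _log_diff_exp(lsum1 + lsum2, lsum12) if m > 1 else -np.inf

    terms = np.array([
        0.0,
        math.log(p1) + lsum1,
        math.log(p2) + lsum2,
        (math.log(p1) + math.log(p2) + lh3) if np.isfinite(lh3) else -np.inf,
        math.log(p12) + lsum12,
    ])
    post = np.exp(terms - logsumexp(terms))
    post /= post.sum()

    per_snp = None
    if keep_per_snp:
        per_snp = pd.DataFrame({
            "variant_id": da.ids.to_numpy(), "log_abf_1": l1, "log_abf_2": l2,
        })
    return ColocResult(*post, n_snps=m, priors=tuple(priors), per_snp_log_abf=per_snp)


def _prepare_ld_arrays(ds: RegionDataset, ld: LDReference, freq_tol: float):
    """Restrict to panel-covered, frequency-consistent variants; return work frame."""
    df = ds.variants[ds.variants["variant_id"].map(lambda v: v in ld)].copy()
    if df.empty:
        return df
    ref_f = ld.freqs(df["variant_id"].tolist())
    gwas_f = df["eaf"].to_numpy(float)
    use_f = np.where(np.isfinite(gwas_f), gwas_f, ref_f)
    ok = np.abs(use_f - ref_f) <= freq_tol
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} variant(s) dropped for GWAS/reference frequency mismatch")
    df = df[ok].copy()
    return df


def conditional_stats(
    ds: RegionDataset,
    ld: LDReference,
    condition_on: Sequence[str],
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    freq_tol: float = DEFAULT_FREQ_TOL,
) -> RegionDataset:
    """Summary-statistic conditional association analysis.

    Computes, for every variant not in ``condition_on``, its effect and SE
    conditional on the conditioning set, from marginal statistics and the LD
    panel's dosage covariance (the joint-model normal equations with X'X
    approximated by n * panel covariance).  Conditional SEs rescale the
    observed marginal SE by the conditioning variance-inflation factor, so
    conditioning on an uncorrelated variant leaves a variant's statistics
    exactly unchanged.  Variants whose LD with the conditioning set exceeds
    ``collinearity_r2`` (multiple-R^2) are omitted from the output.
    """
    condition_on = list(condition_on)
    if not condition_on:
        out = ds.copy()
        return out
    df = _prepare_ld_arrays(ds, ld, freq_tol)
    missing = [v for v in condition_on if v not in set(df["variant_id"])]
    if missing:
        raise KeyError(f"conditioning variants missing from data/panel: {missing}")

    ids = df["variant_id"].tolist()
    n = df["n"].to_numpy(float) * ds.trait.effective_n_factor
    C = ld.cov(ids)
    is_cond = df["variant_id"].isin(condition_on).to_numpy()
    ci = np.flatnonzero(is_cond)
    ri = np.flatnonzero(~is_cond)
    if ri.size == 0:
        raise ValueError("no variants left after removing the conditioning set")

    # X'X in per-allele units: n-scaled panel covariance (sqrt(n_i n_j) for
    # unequal per-variant n); X'y recovered from the marginal estimates.
    sqn = np.sqrt(n)
    B = C * np.outer(sqn, sqn)
    D = np.diag(B).copy()
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    Xy = D * beta

    A = B[np.ix_(ci, ci)]
    a = B[np.ix_(ri, ci)]  # (n_rest, n_cond)
    try:
        Ainv_at = np.linalg.solve(A, a.T)  # (n_cond, n_rest)
        Ainv_xy = np.linalg.solve(A, Xy[ci])
    except np.linalg.LinAlgError:
        # collinear conditioning set: fall back to pseudo-inverse
        Ainv_at = np.linalg.pinv(A) @ a.T
        Ainv_xy = np.linalg.pinv(A) @ Xy[ci]

    denom = D[ri] - np.einsum("ij,ji->i", a, Ainv_at)
    mult_r2 = 1.0 - denom / D[ri]
    ok = mult_r2 <= collinearity_r2
    denom = np.clip(denom, 1e-12, None)
    beta_c = (Xy[ri] - a @ Ainv_xy) / denom
    se_c = se[ri] * np.sqrt(D[ri] / denom)
    z = beta_c / se_c
    pval_c = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    pval_c = np.maximum(pval_c, 1e-300)

    out = df.iloc[ri].copy()
    out["beta"], out["se"], out["pval"] = beta_c, se_c, pval_c
    out = out[ok]
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} variant(s) collinear with conditioning set; omitted")
    return RegionDataset(trait=ds.trait, variants=out.reset_index(drop=True), window=ds.window)


def stepwise_select(
    ds: RegionDataset,
    ld: LDReference,
    p_select: float = DEFAULT_P_SELECT,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    freq_tol: float = DEFAULT_FREQ_TOL,
    max_signals: int = MAX_SIGNALS,
) -> list[ConditionalSignal]:
    """Forward stepwise selection of conditionally independent signals.

    Iteratively adds the variant with the smallest (conditional) p-value
    while it passes ``p_select``; returns one signal per selected lead, each
    with the region's statistics conditioned on all *other* leads.
    """
    base = _prepare_ld_arrays(ds, ld, freq_tol)
    if base.empty:
        return []
    work = RegionDataset(trait=ds.trait, variants=base, window=ds.window)
    leads: list[str] = []
    while len(leads) < max_signals:
        cond = conditional_stats(work, ld, leads, collinearity_r2, freq_tol) if leads else work
        if len(cond) == 0:
            break
        best = cond.variants.loc[cond.variants["pval"].idxmin()]
        if best["pval"] > p_select:
            break
        leads.append(best["variant_id"])
    if not leads:
        return []
    if len(leads) == 1:
        return [ConditionalSignal(leads[0], work)]
    out = []
    for lead in leads:
        others = [v for v in leads if v != lead]
        out.append(ConditionalSignal(lead, conditional_stats(work, ld, others,
                                                             collinearity_r2, freq_tol)))
    return out


def pwcoco(
    d1: RegionDataset,
    d2: RegionDataset,
    ld: LDReference,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    p_select: float = DEFAULT_P_SELECT,
    collinearity_r2: float = DEFAULT_COLLINEARITY_R2,
    freq_tol: float = DEFAULT_FREQ_TOL,
) -> PWCoCoResult:
    """Pairwise conditional colocalisation of two harmonised regions.

    Runs stepwise signal selection on both sides and colocalises the
    marginal-marginal pair plus every conditional-exposure x
    conditional-outcome pair; a side with at most one signal contributes its
    marginal statistics.
    """
    shared = set(d1.ids) & set(d2.ids)
    if not shared:
        raise EmptyOverlapError("no shared variants in region")
    d1s, d2s = d1.subset(shared), d2.subset(shared)

    res = PWCoCoResult()
    res.pair_results.append(("marginal", "marginal", coloc_posteriors(d1s, d2s, priors)))

    sig1 = stepwise_select(d1s, ld, p_select, collinearity_r2, freq_tol)
    sig2 = stepwise_select(d2s, ld, p_select, collinearity_r2, freq_tol)
    if len(sig1) <= 1 and len(sig2) <= 1:
        return res

    side1 = sig1 if sig1 else [ConditionalSignal("marginal", d1s)]
    side2 = sig2 if sig2 else [ConditionalSignal("marginal", d2s)]
    for s1, s2 in product(side1, side2):
        try:
            r = coloc_posteriors(s1.conditional_dataset, s2.conditional_dataset, priors)
        except EmptyOverlapError:
            continue
        res.pair_results.append((s1.lead_variant_id, s2.lead_variant_id, r))
    return res
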