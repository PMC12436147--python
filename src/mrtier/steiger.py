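"""Steiger directionality filtering.

Compares the variance the instruments explain in the exposure with the
variance they explain in the outcome.  If the instruments explain more
variance in the outcome, the primary phenotype influenced by the variants is
plausibly the outcome (reverse causation) and the pair fails the filter.

Variance explained per variant:

* ``eaf_beta`` (quantitative traits with a unit-variance phenotype):
  r^2 = 2 f (1-f) beta^2
* ``p_n`` (any trait): r^2 = z^2 / (z^2 + n_eff - 2) with z the two-sided
  normal quantile of the p-value.  For case-control traits n_eff is the
  effective sample size n * cf * (1-cf), keeping quantitative and binary
  traits on a comparable observed scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import IncompleteEvidenceError
from .gwas_io import RegionDataset, TraitMeta
from .instruments import InstrumentSet


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_pval: float


def effective_n(trait: TraitMeta, n: float) -> float:
    return float(n) * trait.effective_n_factor


def variance_explained(v, trait: TraitMeta, method: str = "eaf_beta") -> float:
    """Variance in the trait explained by one variant; see module docstring."""
    if method not in ("eaf_beta", "p_n"):
        raise ValueError(f"unknown method {method!r}")
    eaf = getattr(v, "eaf", None)
    if eaf is not None and not np.isfinite(eaf):
        eaf = None
    if method == "eaf_beta" and trait.trait_type != "quantitative":
        method = "p_n"  # observed-scale fallback for binary traits
    if method == "eaf_beta" and eaf is None:
        warnings.warn(f"eaf absent for {v.variant_id}; falling back to p/n method")
        method = "p_n"
    if method == "eaf_beta":
        r2 = 2.0 * eaf * (1.0 - eaf) * v.beta**2
    else:
        n_eff = effective_n(trait, v.n)
        if n_eff < 3:
            raise ValueError("p_n method requires effective n >= 3")
        z = stats.norm.isf(min(max(v.pval, 1e-300), 1.0) / 2.0)
        r2 = z**2 / (z**2 + n_eff - 2.0)
    return float(min(max(r2, 0.0), 1.0))


def _summed_r2(ds: RegionDataset, variant_ids: list[str]) -> tuple[float, float]:
    """Sum per-instrument r^2 in a dataset; returns (r2, min effective n)."""
    total, n_min = 0.0, math.inf
    for vid in variant_ids:
        v = ds.variant(vid)
        total += variance_explained(v, ds.trait)
        n_min = min(n_min, effective_n(ds.trait, v.n))
    if total > 1.0:
        warnings.warn("summed variance explained exceeded 1; capped")
        total = 1.0
    return total, n_min


def steiger_direction(
    instruments: InstrumentSet,
    exposure: RegionDataset,
    outcome: RegionDataset,
) -> SteigerResult:
    """Directionality test over the instrument set.

    Sums per-instrument variance explained in each trait, declares the
    direction correct when the exposure r^2 is larger, and computes a Fisher-z
    comparison of the two correlations using the smaller of the two
    (effective) sample sizes.
    """
    ids = instruments.variant_ids
    if not ids:
        raise IncompleteEvidenceError("Steiger test undefined with zero instruments")
    try:
        r2_exp, n_exp = _summed_r2(exposure, ids)
        r2_out, n_out = _summed_r2(outcome, ids)
    except KeyError as e:
        raise IncompleteEvidenceError(f"instrument {e} missing from harmonised data") from e
    r_exp, r_out = math.sqrt(r2_exp), math.sqrt(r2_out)
    n = max(min(n_exp, n_out), 4.0)
    z = (math.atanh(min(r_exp, 1 - 1e-12)) - math.atanh(min(r_out, 1 - 1e-12)))
    z /= math.sqrt(2.0 / (n - 3.0))
    pval = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 1e-300)))
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out,
        correct_direction=bool(r2_exp > r2_out), steiger_pval=pval,
    )
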