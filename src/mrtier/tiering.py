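"""Three-tier evidence appraisal for drug-target prioritisation.

A biomarker-outcome finding is classified from seven boolean gates:

* Tier A: Bonferroni-significant, Steiger direction correct, colocalising
  (max H4 >= 0.8), cis-only instruments, no heterogeneity, no pleiotropy.
* Tier B: as A with the FDR gate (q <= 0.05) in place of Bonferroni.
* Tier C: as B but the instrument set includes trans variants.
* fdr_only: FDR-significant but failing at least one other gate.
* none: everything else.

Heterogeneity applies only with more than 2 instruments (Cochran's Q) and
pleiotropy only with more than 3 (Egger intercept); below those counts the
gates pass vacuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coloc import pwcoco, PWCoCoResult
from .errors import IncompleteEvidenceError
from .gwas_io import VariantAssoc
from .instruments import InstrumentSet
from .mr import MRResult
from .steiger import SteigerResult

GATE_NAMES = (
    "bonferroni_pass", "fdr_pass", "steiger_pass", "coloc_pass",
    "cis_only_instruments", "het_pass", "pleio_pass",
)

DEFAULT_TIER_THRESHOLDS = {
    "tier_a_p": 1.8e-6,
    "h4_min": 0.8,
    "fdr_level": 0.05,
    "het_alpha": 0.05,
    "pleio_alpha": 0.05,
    "steiger_p_max": None,  # direction-only gate by default
}


@dataclass
class TierAssignment:
    exposure_id: str
    outcome_id: str
    tier: str  # A | B | C | fdr_only | none
    gates: dict[str, bool] = field(default_factory=dict)
    mhc_flag: bool = False
    coloc_variant_id: str = ""


def select_coloc_variant(iset: InstrumentSet) -> VariantAssoc:
    """Choose the variant whose region is tested for colocalisation.

    Any cis instrument takes precedence (smallest p among cis); otherwise the
    trans variant with the smallest p; a singleton set is used regardless of
    locality.
    """
    if iset.empty:
        raise IncompleteEvidenceError("cannot select a colocalisation variant from an empty set")
    if len(iset) == 1:
        return iset.instruments[0].variant
    cis = [i for i in iset.instruments if i.locality == "cis"]
    pool = cis if cis else iset.instruments
    best = min(pool, key=lambda i: (i.variant.pval, i.variant.chrom, i.variant.pos))
    return best.variant


def tier_from_gates(gates: dict[str, bool]) -> str:
    """Pure mapping from the seven gate booleans to a tier label."""
    g = {k: bool(gates[k]) for k in GATE_NAMES}
    core = g["steiger_pass"] and g["coloc_pass"] and g["het_pass"] and g["pleio_pass"]
    if g["bonferroni_pass"] and core and g["cis_only_instruments"]:
        return "A"
    if g["fdr_pass"] and core:
        return "B" if g["cis_only_instruments"] else "C"
    if g["fdr_pass"]:
        return "fdr_only"
    return "none"


def assign_tier(
    mr: MRResult,
    q_value: float,
    st: SteigerResult,
    max_h4: float,
    iset: InstrumentSet,
    thresholds: dict | None = None,
    egger: MRResult | None = None,
    mhc_flag: bool | None = None,
) -> TierAssignment:
    """Compute the gate booleans for one exposure-outcome pair and classify it.

    ``mr`` is the primary estimate (Wald or IVW; carries Q when IVW),
    ``egger`` the MR-Egger fit when >= 3 instruments were available.
    """
    for name, val in (("mr", mr), ("steiger", st), ("instruments", iset)):
        if val is None:
            raise IncompleteEvidenceError(f"missing stage output: {name}")
    if q_value is None or max_h4 is None:
        raise IncompleteEvidenceError("missing stage output: multiple-testing or coloc")
    th = dict(DEFAULT_TIER_THRESHOLDS, **(thresholds or {}))

    steiger_pass = st.correct_direction
    if th["steiger_p_max"] is not None:
        steiger_pass = steiger_pass and st.steiger_pval <= th["steiger_p_max"]
    het_pass = mr.n_snp <= 2 or mr.q_pval is None or mr.q_pval > th["het_alpha"]
    pleio_pass = (
        mr.n_snp <= 3
        or egger is None
        or egger.egger_intercept_pval is None
        or egger.egger_intercept_pval > th["pleio_alpha"]
    )
    gates = {
        "bonferroni_pass": mr.pval <= th["tier_a_p"],
        "fdr_pass": q_value <= th["fdr_level"],
        "steiger_pass": bool(steiger_pass),
        "coloc_pass": max_h4 >= th["h4_min"],
        "cis_only_instruments": iset.all_cis,
        "het_pass": bool(het_pass),
        "pleio_pass": bool(pleio_pass),
    }
    coloc_variant = select_coloc_variant(iset)
    if mhc_flag is None:
        mhc_flag = iset.any_mhc
    return TierAssignment(
        exposure_id=mr.exposure_id or iset.exposure_id,
        outcome_id=mr.outcome_id,
        tier=tier_from_gates(gates),
        gates=gates,
        mhc_flag=bool(mhc_flag),
        coloc_variant_id=coloc_variant.variant_id,
    )


def cross_qtl_coloc(
    results: list[TierAssignment],
    regions: dict[str, "RegionDataset"],
    ld,
    priors=None,
    **pwcoco_kwargs,
) -> pd.DataFrame:
    """Colocalise the QTL datasets of one biomarker across QTL types/tissues.

    ``results`` are the tiered (A/B/C) findings for one biomarker, ``regions``
    maps each exposure_id to its QTL region dataset.  Pairs in which either
    QTL resides in the MHC are skipped with reason "MHC".
    """
    from .coloc import DEFAULT_PRIORS

    priors = priors or DEFAULT_PRIORS
    tiered = [r for r in results if r.tier in ("A", "B", "C")]
    rows = []
    for i in range(len(tiered)):
        for j in range(i + 1, len(tiered)):
            a, b = tiered[i], tiered[j]
            row = {"qtl_1": a.exposure_id, "qtl_2": b.exposure_id}
            if a.mhc_flag or b.mhc_flag:
                row.update(skipped=True, reason="MHC")
            else:
                res: PWCoCoResult = pwcoco(
                    regions[a.exposure_id], regions[b.exposure_id], ld,
                    priors=priors, **pwcoco_kwargs,
                )
                best = max(res.pair_results, key=lambda t: t[2].pp_h4)[2]
                row.update(
                    skipped=False, reason="",
                    n_snps=best.n_snps, max_h4=res.max_h4,
                    **{f"PP.H{k}": p for k, p in enumerate(best.posteriors)},
                )
            rows.append(row)
    return pd.DataFrame(rows)
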