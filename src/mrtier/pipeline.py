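"""End-to-end orchestration: forward MR with colocalisation and tiering, and
the reverse (bidirectional) MR pass.

The forward pass runs, for every exposure x outcome x selection mode:
instrument selection -> harmonisation -> MR (Wald for a single instrument,
IVW with Cochran's Q and MR-Egger otherwise) -> Steiger directionality ->
region extraction around the colocalisation variant -> pairwise conditional
colocalisation -> pooled multiple-testing control -> tier assignment.
The reverse pass instruments each outcome condition genome-wide (falling back
to p <= 5e-7 when fewer than 3 genome-wide instruments survive clumping) and
estimates its effect on every biomarker with a Bonferroni gate at
0.05 / (n_conditions * n_biomarkers).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr as mr_mod
from .coloc import DEFAULT_PRIORS, pwcoco
from .errors import EmptyOverlapError, MRTierError
from .gwas_io import (RegionDataset, TraitMeta, extract_region, harmonise_pair,
                      read_summary_stats)
from .instruments import (DEFAULT_THRESHOLDS, GeneRegion, InstrumentSet,
                          build_instrument_set, clump, read_gene_regions)
from .ld import LDReference
from .steiger import steiger_direction
from .tiering import DEFAULT_TIER_THRESHOLDS, TierAssignment, assign_tier, select_coloc_variant

log = logging.getLogger("mrtier")

DEFAULT_CONFIG = {
    **DEFAULT_THRESHOLDS,
    **DEFAULT_TIER_THRESHOLDS,
    "coloc_priors": DEFAULT_PRIORS,
    "coloc_half_width_bp": 500_000,
    "palindrome_eaf_limit": 0.42,
    "p_select": 5e-8,
    "collinearity_r2": 0.9,
    "alpha": 0.05,
    "bonferroni_n_tests": None,   # default: number of tests in the run
    "reverse_p_primary": 5e-8,
    "reverse_p_fallback": 5e-7,
    "reverse_min_instruments": 3,
}


@dataclass
class PairAnalysis:
    """All stage outputs for one exposure x outcome x mode."""

    exposure: RegionDataset
    outcome_id: str
    mode: str
    iset: InstrumentSet
    mr: "mr_mod.MRResult"
    egger: "mr_mod.MRResult | None"
    steiger: "object"
    max_h4: float
    marginal_h3: float
    marginal_h4: float
    coloc_variant_id: str
    mhc_flag: bool


@dataclass
class ForwardResults:
    table: pd.DataFrame
    assignments: list[TierAssignment]
    analyses: list[PairAnalysis]
    skips: list[tuple[str, str, str, str]]  # exposure, outcome, mode, reason


@dataclass
class ReverseMRResult:
    condition_id: str
    biomarker_id: str
    result: "mr_mod.MRResult"
    instrument_p_threshold_used: float
    bonferroni_pass: bool


def analyse_pair(
    exposure: RegionDataset,
    outcome: RegionDataset,
    ld: LDReference,
    gene: GeneRegion,
    mode: str,
    config: dict | None = None,
) -> PairAnalysis | str:
    """Run all per-pair stages; returns a PairAnalysis or a skip reason string."""
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    iset = build_instrument_set(exposure, gene, ld, mode, cfg)
    if iset.empty:
        return "empty_instrument_set"
    try:
        pair = harmonise_pair(exposure, outcome, cfg["palindrome_eaf_limit"])
    except EmptyOverlapError:
        return "no_shared_variants"

    harmonised_ids = set(pair.exposure.ids)
    kept = [i for i in iset.instruments if i.variant.variant_id in harmonised_ids]
    if not kept:
        return "instruments_lost_in_harmonisation"
    iset = InstrumentSet(iset.exposure_id, iset.gene, kept, iset.selection_mode)

    ex = pair.exposure.variants.set_index("variant_id")
    ou = pair.outcome.variants.set_index("variant_id")
    ids = iset.variant_ids
    bx, sx = ex.loc[ids, "beta"].to_numpy(), ex.loc[ids, "se"].to_numpy()
    by, sy = ou.loc[ids, "beta"].to_numpy(), ou.loc[ids, "se"].to_numpy()

    xid, oid = exposure.trait.trait_id, outcome.trait.trait_id
    if len(ids) == 1:
        primary = mr_mod.wald_ratio(bx[0], sx[0], by[0], sy[0], xid, oid)
    else:
        primary = mr_mod.ivw(bx, sx, by, sy, xid, oid)
    egger_fit = mr_mod.egger(bx, sx, by, sy, xid, oid) if len(ids) >= 3 else None

    st = steiger_direction(iset, pair.exposure, pair.outcome)

    cv = select_coloc_variant(iset)
    hw = cfg["coloc_half_width_bp"]
    r1 = extract_region(pair.exposure, cv.chrom, cv.pos, hw)
    r2 = extract_region(pair.outcome, cv.chrom, cv.pos, hw)
    marginal_h3 = marginal_h4 = 0.0
    max_h4 = 0.0
    try:
        pw = pwcoco(r1, r2, ld, cfg["coloc_priors"], cfg["p_select"], cfg["collinearity_r2"])
        max_h4 = pw.max_h4
        marg = pw.pair_results[0][2]
        marginal_h3, marginal_h4 = marg.pp_h3, marg.pp_h4
    except EmptyOverlapError:
        log.warning("empty colocalisation region for %s vs %s", xid, oid)

    mhc_lo, mhc_hi = cfg["mhc_interval"]
    cv_mhc = str(cv.chrom) == str(cfg["mhc_chrom"]) and mhc_lo <= cv.pos <= mhc_hi
    return PairAnalysis(
        exposure=exposure, outcome_id=oid, mode=mode, iset=iset,
        mr=primary, egger=egger_fit, steiger=st, max_h4=max_h4,
        marginal_h3=marginal_h3, marginal_h4=marginal_h4,
        coloc_variant_id=cv.variant_id, mhc_flag=iset.any_mhc or cv_mhc,
    )


def run_forward(
    exposures: list[tuple[RegionDataset, GeneRegion]],
    outcomes: list[RegionDataset],
    ld: LDReference,
    modes: tuple[str, ...] = ("cis_only",),
    config: dict | None = None,
) -> ForwardResults:
    """Forward MR across all exposure x outcome x mode combinations.

    FDR is controlled by BH across the pooled results of the run; the
    Bonferroni family size defaults to the number of pooled tests but can be
    fixed via ``bonferroni_n_tests`` (e.g. the full analysis-wide count).
    """
    if not modes:
        raise ValueError("at least one selection mode must be enabled")
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    analyses: list[PairAnalysis] = []
    skips: list[tuple[str, str, str, str]] = []
    for exposure, gene in exposures:
        for outcome in outcomes:
            for mode in modes:
                out = analyse_pair(exposure, outcome, ld, gene, mode, cfg)
                if isinstance(out, str):
                    skips.append((exposure.trait.trait_id, outcome.trait.trait_id, mode, out))
                    log.info("skip %s x %s [%s]: %s", exposure.trait.trait_id,
                             outcome.trait.trait_id, mode, out)
                else:
                    analyses.append(out)
                    log.info("pair %s x %s [%s]: n_snp=%d b=%.4g p=%.3g h4=%.3f",
                             exposure.trait.trait_id, outcome.trait.trait_id, mode,
                             out.mr.n_snp, out.mr.beta_mr, out.mr.pval, out.max_h4)

    pvals = [a.mr.pval for a in analyses]
    mt = mr_mod.adjust_pvalues(
        pvals, alpha=cfg["alpha"],
        n_tests_bonferroni=cfg["bonferroni_n_tests"] or (len(pvals) or 1),
        fdr_level=cfg["fdr_level"],
    )
    assignments, rows = [], []
    for a, q in zip(analyses, mt.q_values):
        ta = assign_tier(a.mr, float(q), a.steiger, a.max_h4, a.iset,
                         cfg, egger=a.egger, mhc_flag=a.mhc_flag)
        assignments.append(ta)
        rows.append({
            "exposure": a.mr.exposure_id, "outcome": a.outcome_id,
            "qtl_type": a.exposure.trait.qtl_type, "tissue": a.exposure.trait.tissue,
            "mode": a.mode, "method": a.mr.method, "nsnp": a.mr.n_snp,
            "b": a.mr.beta_mr, "se": a.mr.se_mr, "p": a.mr.pval,
            "q_value": float(q),
            "Q": a.mr.q_stat, "Q_df": a.mr.q_df, "Q_p": a.mr.q_pval,
            "egger_intercept": a.egger.egger_intercept if a.egger else np.nan,
            "egger_intercept_p": a.egger.egger_intercept_pval if a.egger else np.nan,
            "r2_exp": a.steiger.r2_exposure, "r2_out": a.steiger.r2_outcome,
            "steiger_dir": a.steiger.correct_direction, "steiger_p": a.steiger.steiger_pval,
            "PP.H4_max": a.max_h4, "PP.H3_marginal": a.marginal_h3,
            "PP.H4_marginal": a.marginal_h4,
            "coloc_variant": a.coloc_variant_id, "mhc_flag": a.mhc_flag,
            "tier": ta.tier, **{k: bool(v) for k, v in ta.gates.items()},
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["exposure", "outcome", "mode"], kind="mergesort").reset_index(drop=True)
    return ForwardResults(table=table, assignments=assignments, analyses=analyses, skips=skips)


def run_reverse(
    conditions: list[RegionDataset],
    biomarkers: list[RegionDataset],
    ld: LDReference,
    config: dict | None = None,
) -> pd.DataFrame:
    """Bidirectional pass: condition -> biomarker MR with instrument fallback.

    Instruments are clumped at 5e-8; when fewer than 3 survive, selection is
    repeated at 5e-7 and the threshold used is recorded.  The Bonferroni gate
    is 0.05 / (n_conditions * n_biomarkers).
    """
    cfg = dict(DEFAULT_CONFIG, **(config or {}))
    n_tests = max(len(conditions) * len(biomarkers), 1)
    thr = mr_mod.bonferroni_threshold(cfg["alpha"], n_tests)
    rows = []
    for cond in conditions:
        p_used = cfg["reverse_p_primary"]
        sel = clump(cond, ld, p_used, cfg["clump_r2"], cfg["clump_window_kb"])
        if len(sel) < cfg["reverse_min_instruments"]:
            p_used = cfg["reverse_p_fallback"]
            sel = clump(cond, ld, p_used, cfg["clump_r2"], cfg["clump_window_kb"])
            log.info("condition %s: fallback instrument threshold %.1e (n=%d)",
                     cond.trait.trait_id, p_used, len(sel))
        if not sel:
            log.info("condition %s skipped: no instruments", cond.trait.trait_id)
            continue
        ids = [v.variant_id for v in sel]
        for biom in biomarkers:
            try:
                pair = harmonise_pair(cond, biom, cfg["palindrome_eaf_limit"])
            except EmptyOverlapError:
                continue
            ex = pair.exposure.variants.set_index("variant_id")
            ou = pair.outcome.variants.set_index("variant_id")
            keep = [i for i in ids if i in ex.index]
            if not keep:
                continue
            bx, sx = ex.loc[keep, "beta"].to_numpy(), ex.loc[keep, "se"].to_numpy()
            by, sy = ou.loc[keep, "beta"].to_numpy(), ou.loc[keep, "se"].to_numpy()
            cid, bid = cond.trait.trait_id, biom.trait.trait_id
            if len(keep) == 1:
                res = mr_mod.wald_ratio(bx[0], sx[0], by[0], sy[0], cid, bid)
            else:
                res = mr_mod.ivw(bx, sx, by, sy, cid, bid)
            rows.append({
                "condition": cid, "biomarker": bid, "method": res.method,
                "nsnp": res.n_snp, "b": res.beta_mr, "se": res.se_mr, "p": res.pval,
                "instrument_p_threshold_used": p_used,
                "bonferroni_threshold": thr,
                "bonferroni_pass": res.pval <= thr,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based runs

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _read_trait_entry(entry: dict) -> tuple[RegionDataset, GeneRegion | None]:
    trait = TraitMeta(
        trait_id=entry.get("trait_id", Path(entry["path"]).stem),
        trait_type=entry.get("trait_type", "quantitative"),
        case_fraction=entry.get("case_fraction"),
        tissue=entry.get("tissue", "other"),
        qtl_type=entry.get("qtl_type", "none"),
    )
    ds = read_summary_stats(entry["path"], entry.get("dialect"), trait)
    gene = None
    if "gene" in entry:
        g = entry["gene"]
        gene = GeneRegion(g["gene_id"], str(g["chrom"]), int(g["start"]), int(g["end"]))
    return ds, gene


def run_from_config(config: dict, out_dir) -> ForwardResults:
    """File-based forward (and optionally reverse) run; writes result TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ld = LDReference.load(config["ld"]["prefix"])
    genes = read_gene_regions(config["genes"]) if "genes" in config else {}

    exposures = []
    for entry in config["exposures"]:
        ds, gene = _read_trait_entry(entry)
        if gene is None:
            gene = genes[entry["gene_id"]]
        exposures.append((ds, gene))
    outcomes = [_read_trait_entry(e)[0] for e in config["outcomes"]]

    cfg = dict(DEFAULT_CONFIG, **(config.get("thresholds") or {}))
    modes = tuple(config.get("modes", ["cis_only"]))
    res = run_forward(exposures, outcomes, ld, modes, cfg)
    res.table.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(res.skips, columns=["exposure", "outcome", "mode", "reason"]).to_csv(
        out / "skips.tsv", sep="\t", index=False
    )
    if config.get("bidirectional"):
        conditions = ([_read_trait_entry(e)[0] for e in config["conditions"]]
                      if config.get("conditions") else outcomes)
        rev = run_reverse(conditions, [ds for ds, _ in exposures], ld, cfg)
        rev.to_csv(out / "reverse.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "seed": config.get("seed"),
        "modes": list(modes),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return res
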