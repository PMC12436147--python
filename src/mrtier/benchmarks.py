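"""Simulation studies validating each stage against its known truth.

Each routine regenerates its own synthetic data from a seed, runs the
package's estimators, and reports calibration/discrimination summaries:
IVW bias and CI coverage, Egger intercept calibration and recovery, coloc
posterior discrimination, the conditional-colocalisation value-add scenario,
conditional-analysis accuracy against individual-level regression, Steiger
direction recovery, the tier truth table, and end-to-end scenario
expectations.  The defaults are the study conditions used throughout the
package's validation; they are not tuning knobs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from . import mr as mr_mod
from .coloc import DEFAULT_PRIORS, PRIOR_SD, coloc_posteriors, conditional_stats, pwcoco
from .gwas_io import RegionDataset, TraitMeta
from .instruments import Instrument, InstrumentSet
from .simulate import (SCENARIO_LABELS, build_scenario, gwas_from_genotypes,
                       simulate_gwas, simulate_ld_reference, simulate_phenotype)
from .steiger import steiger_direction
from .tiering import GATE_NAMES, tier_from_gates
from .pipeline import run_forward


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, n)


# ---------------------------------------------------------------------------
# IVW / Egger calibration

def simulate_instrument_effects(
    rng: np.random.Generator,
    k: int,
    beta_true: float,
    n_exp: int,
    n_out: int,
    u_range: tuple[float, float] = (0.08, 0.2),
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
):
    """Standardised-scale two-sample instrument effects for k valid-ish variants."""
    u = rng.uniform(*u_range, k)
    sx = np.full(k, 1.0 / math.sqrt(n_exp))
    sy = np.full(k, 1.0 / math.sqrt(n_out))
    bx = u + rng.normal(0.0, sx)
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, k) if (pleiotropy_sd or pleiotropy_mean) else 0.0
    by = beta_true * u + alpha + rng.normal(0.0, sy)
    return bx, sx, by, sy


def ivw_calibration(
    seed: int, reps: int = 500, k: int = 10, beta_true: float = 0.2,
    n_exp: int = 20_000, n_out: int = 50_000,
) -> dict:
    """Mean bias and 95% CI coverage of IVW under valid instruments."""
    rng = np.random.default_rng(seed)
    est, cover = [], 0
    for _ in range(reps):
        bx, sx, by, sy = simulate_instrument_effects(rng, k, beta_true, n_exp, n_out)
        r = mr_mod.ivw(bx, sx, by, sy)
        est.append(r.beta_mr)
        if abs(r.beta_mr - beta_true) <= 1.959963984540054 * r.se_mr:
            cover += 1
    est = np.asarray(est)
    return {
        "mean_estimate": float(est.mean()),
        "bias": float(est.mean() - beta_true),
        "coverage": cover / reps,
        "reps": reps,
    }


def egger_calibration(
    seed: int, reps: int = 2000, k: int = 10, beta_true: float = 0.2,
    n_exp: int = 100_000, n_out: int = 50_000,
    pleiotropy_sd: float = 0.01, intercept: float = 0.0, alpha: float = 0.05,
) -> dict:
    """Egger intercept test size (balanced) or recovery (directional pleiotropy)."""
    rng = np.random.default_rng(seed)
    icpts, rej = [], 0
    for _ in range(reps):
        bx, sx, by, sy = simulate_instrument_effects(
            rng, k, beta_true, n_exp, n_out, u_range=(0.1, 0.3),
            pleiotropy_mean=intercept, pleiotropy_sd=pleiotropy_sd,
        )
        r = mr_mod.egger(bx, sx, by, sy)
        icpts.append(r.egger_intercept)
        if r.egger_intercept_pval <= alpha:
            rej += 1
    icpts = np.asarray(icpts)
    return {
        "rejection_rate": rej / reps,
        "mean_intercept": float(icpts.mean()),
        "intercept_sem": float(icpts.std(ddof=1) / math.sqrt(reps)),
        "reps": reps,
    }


# ---------------------------------------------------------------------------
# colocalisation

def _coloc_panel(seed: int, n_ind: int = 4000, n_var: int = 200):
    return simulate_ld_reference(n_ind=n_ind, n_var=n_var, block_size=25, rho=0.9,
                                 maf_range=(0.05, 0.5), seed=seed)

_EXP_TRAIT = TraitMeta("exp", "quantitative", tissue="blood", qtl_type="pqtl")
_OUT_TRAIT = TraitMeta("out", "case_control", case_fraction=0.2)


def coloc_discrimination(seed: int, n_seeds: int = 100) -> dict:
    """H4 rate for shared-causal and H3>H4 rate for distinct-causal regions."""
    panel_seed, *gwas_seeds = _child_seeds(seed, 2 * n_seeds + 1)
    ld = _coloc_panel(int(panel_seed))
    shared_hit = distinct_hit = 0
    for i in range(n_seeds):
        s1, s2 = int(gwas_seeds[i]), int(gwas_seeds[n_seeds + i])
        d1 = simulate_gwas(ld, [(87, 0.225)], _EXP_TRAIT, 30_000, seed=s1, causal_scale="std")
        d2 = simulate_gwas(ld, [(87, 0.12)], _OUT_TRAIT, 50_000, seed=s2, causal_scale="std")
        if coloc_posteriors(d1, d2).pp_h4 >= 0.8:
            shared_hit += 1
        d2 = simulate_gwas(ld, [(137, 0.12)], _OUT_TRAIT, 50_000, seed=s2 + 1, causal_scale="std")
        r = coloc_posteriors(d1, d2)
        if r.pp_h3 > r.pp_h4:
            distinct_hit += 1
    return {
        "shared_h4_rate": shared_hit / n_seeds,
        "distinct_h3_rate": distinct_hit / n_seeds,
        "n_seeds": n_seeds,
    }


def pwcoco_value_add(seed: int, n_seeds: int = 100) -> dict:
    """Two-signal exposure / one-shared-(weaker)-signal outcome rescue rate."""
    panel_seed, *gwas_seeds = _child_seeds(seed, 2 * n_seeds + 1)
    ld = _coloc_panel(int(panel_seed))
    rescued = marginal_below = 0
    for i in range(n_seeds):
        d1 = simulate_gwas(ld, [(87, 0.30), (137, 0.135)], _EXP_TRAIT, 30_000,
                           seed=int(gwas_seeds[i]), causal_scale="std")
        d2 = simulate_gwas(ld, [(137, 0.12)], _OUT_TRAIT, 50_000,
                           seed=int(gwas_seeds[n_seeds + i]), causal_scale="std")
        res = pwcoco(d1, d2, ld)
        marg_h4 = res.pair_results[0][2].pp_h4
        if marg_h4 < 0.8:
            marginal_below += 1
            if res.max_h4 >= 0.8:
                rescued += 1
    return {
        "rescue_rate": rescued / n_seeds,
        "marginal_below_rate": marginal_below / n_seeds,
        "n_seeds": n_seeds,
    }


def coloc_enumeration_error(seed: int, n_regions: int = 50, max_snps: int = 20) -> dict:
    """Max |posterior - brute-force enumeration| over random small regions.

    The oracle enumerates every single-causal-variant configuration
    explicitly (O(M^2) terms) with its own inline ABF formula, independent of
    the vectorised log-sum-exp identities in the implementation.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_regions):
        m = int(rng.integers(2, max_snps + 1))
        traits, datasets, labfs = [], [], []
        for t in range(2):
            quant = bool(rng.integers(0, 2))
            trait = (TraitMeta(f"t{t}", "quantitative") if quant
                     else TraitMeta(f"t{t}", "case_control", case_fraction=0.3))
            se = rng.uniform(0.01, 0.05, m)
            z = rng.normal(0.0, 1.0, m)
            if rng.random() < 0.7:  # sometimes put a real signal in
                z[rng.integers(0, m)] += rng.uniform(4, 10)
            beta = z * se
            pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
            df = pd.DataFrame({
                "variant_id": [f"v{j}" for j in range(m)], "chrom": "1",
                "pos": np.arange(m) * 1000 + 1, "effect_allele": "A",
                "other_allele": "G", "eaf": rng.uniform(0.05, 0.95, m),
                "beta": beta, "se": se, "pval": pval, "n": 10_000,
            })
            datasets.append(RegionDataset(trait=trait, variants=df))
            w = PRIOR_SD[trait.trait_type] ** 2
            v = se**2
            labfs.append(0.5 * (np.log(v / (v + w)) + z**2 * w / (v + w)))

        got = coloc_posteriors(datasets[0], datasets[1]).posteriors
        l1, l2 = labfs
        p1, p2, p12 = DEFAULT_PRIORS
        t0 = [0.0]
        t1 = [math.log(p1) + l1[i] for i in range(m)]
        t2 = [math.log(p2) + l2[j] for j in range(m)]
        t3 = [math.log(p1) + math.log(p2) + l1[i] + l2[j]
              for i in range(m) for j in range(m) if i != j]
        t4 = [math.log(p12) + l1[i] + l2[i] for i in range(m)]
        logs = [logsumexp(t) if t else -np.inf for t in (t0, t1, t2, t3, t4)]
        expect = np.exp(logs - logsumexp(logs))
        worst = max(worst, float(np.max(np.abs(got - expect))))
    return {"max_abs_error": worst, "n_regions": n_regions}


# ---------------------------------------------------------------------------
# conditional analysis vs individual-level regression

def conditional_accuracy(seed: int, reps: int = 10, n_ind: int = 10_000) -> dict:
    """Compare conditional betas with multiple regression on the genotypes."""
    seeds = _child_seeds(seed, 3 * reps)
    worst = 0.0
    for r in range(reps):
        rng = np.random.default_rng(int(seeds[3 * r]))
        ld = simulate_ld_reference(n_ind=n_ind, n_var=60, block_size=15, rho=0.8,
                                   maf_range=(0.1, 0.5), seed=int(seeds[3 * r + 1]))
        n_causal = int(rng.integers(2, 6))
        idx = rng.choice(60, n_causal, replace=False)
        causal = [(int(i), float(rng.uniform(0.05, 0.15))) for i in idx]
        y = simulate_phenotype(ld, causal, seed=int(seeds[3 * r + 2]))
        ds = gwas_from_genotypes(ld, y, TraitMeta("sim", "quantitative"))
        cond_ids = [ld.variants["variant_id"].iloc[i] for i, _ in causal[:1]]
        cond = conditional_stats(ds, ld, cond_ids)
        cond_v = cond.variants.set_index("variant_id")

        x_cond = ld.dosages[:, [i for i, _ in causal[:1]]]
        for i, _ in causal[1:]:
            vid = ld.variants["variant_id"].iloc[i]
            X = np.column_stack([np.ones(n_ind), x_cond, ld.dosages[:, i]])
            oracle = np.linalg.lstsq(X, y, rcond=None)[0][-1]
            got = cond_v.loc[vid, "beta"]
            worst = max(worst, abs(got - oracle) / max(abs(oracle), 1e-3))
    return {"max_rel_error": float(worst), "reps": reps, "n_ind": n_ind}


# ---------------------------------------------------------------------------
# Steiger

def _one_variant_ds(trait: TraitMeta, beta_std: float, n: int, rng) -> RegionDataset:
    n_eff = n * trait.effective_n_factor
    se_std = 1.0 / math.sqrt(n_eff)
    f = 0.3
    sig = math.sqrt(2 * f * (1 - f))
    bhat = beta_std + rng.normal(0.0, se_std)
    z = abs(bhat / se_std)
    df = pd.DataFrame([{
        "variant_id": "rs1", "chrom": "1", "pos": 1000, "effect_allele": "A",
        "other_allele": "G", "eaf": f, "beta": bhat / sig, "se": se_std / sig,
        "pval": max(2 * stats.norm.sf(z), 1e-300), "n": n,
    }])
    return RegionDataset(trait=trait, variants=df)


def steiger_rates(seed: int, n_seeds: int = 200) -> dict:
    """Direction recovery in forward-causal and reverse-causation simulations."""
    from .instruments import GeneRegion
    from .gwas_io import VariantAssoc

    rng = np.random.default_rng(seed)
    gene = GeneRegion("G1", "1", 500, 2000)
    fwd = rev = 0
    for _ in range(n_seeds):
        # forward: exposure-first architecture, outcome effect via the exposure
        bx = rng.uniform(0.1, 0.25)
        exp_ds = _one_variant_ds(_EXP_TRAIT, bx, 20_000, rng)
        out_ds = _one_variant_ds(_OUT_TRAIT, 0.2 * bx, 50_000, rng)
        iset = InstrumentSet("exp", gene, [Instrument(
            VariantAssoc.from_row(next(exp_ds.variants.itertuples(index=False))),
            100.0, "cis", False)], "cis_only")
        if steiger_direction(iset, exp_ds, out_ds).correct_direction:
            fwd += 1
        # reverse: outcome-first, exposure signal is a diluted echo of it
        bo = rng.uniform(0.2, 0.3)
        out_ds = _one_variant_ds(_OUT_TRAIT, bo, 50_000, rng)
        exp_ds = _one_variant_ds(_EXP_TRAIT, 0.5 * bo, 20_000, rng)
        iset = InstrumentSet("exp", gene, [Instrument(
            VariantAssoc.from_row(next(exp_ds.variants.itertuples(index=False))),
            100.0, "cis", False)], "cis_only")
        if not steiger_direction(iset, exp_ds, out_ds).correct_direction:
            rev += 1
    return {
        "forward_pass_rate": fwd / n_seeds,
        "reverse_fail_rate": rev / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# tiering

def tier_truth_table_exact() -> bool:
    """Check all 2^7 gate combinations against the tier definitions."""
    for bits in itertools.product([False, True], repeat=len(GATE_NAMES)):
        g = dict(zip(GATE_NAMES, bits))
        tier = tier_from_gates(g)
        core = g["steiger_pass"] and g["coloc_pass"] and g["het_pass"] and g["pleio_pass"]
        if g["bonferroni_pass"] and core and g["cis_only_instruments"]:
            want = "A"
        elif g["fdr_pass"] and core and g["cis_only_instruments"]:
            want = "B"
        elif g["fdr_pass"] and core:
            want = "C"
        elif g["fdr_pass"]:
            want = "fdr_only"
        else:
            want = "none"
        if tier != want:
            return False
    return True


def _expectation_met(row: pd.Series, checks: dict) -> bool:
    for key, want in checks.items():
        if key == "tier":
            if row["tier"] not in want:
                return False
        elif key == "h3_gt_h4":
            if bool(row["PP.H3_marginal"] > row["PP.H4_marginal"]) != want:
                return False
        else:
            if bool(row[key]) != want:
                return False
    return True


def scenario_expectation_rates(seed: int, n_seeds: int = 20, labels=SCENARIO_LABELS) -> dict:
    """End-to-end pipeline runs per scenario: fraction of seeds meeting expectations."""
    seeds = _child_seeds(seed, n_seeds)
    rates = {}
    for label in labels:
        hits = 0
        for s in seeds:
            scenario, exposure, outcome, ld, gene, expect = build_scenario(label, int(s))
            res = run_forward([(exposure, gene)], [outcome], ld, (expect["mode"],))
            if res.table.empty:
                continue
            if _expectation_met(res.table.iloc[0], expect["checks"]):
                hits += 1
        rates[label] = hits / n_seeds
    return rates
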