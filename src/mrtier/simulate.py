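"""Synthetic GWAS generator with known ground truth.

Generates block-LD genotype panels, quantitative-trait (QTL) and
case-control (disease) summary statistics, and a labelled suite of scenarios
covering every situation the pipeline must distinguish: shared vs distinct
causal variants, cis vs trans instruments, reverse causation, instrument
heterogeneity, directional pleiotropy, and the null.

Sampling model (summary-level fast path): with panel correlation matrix R and
standardised causal effects ``beta_std``, the true standardised marginal
effect vector is ``R @ beta_std``; observed effects are drawn normally around
the truth with standard error ``1/sqrt(n_eff)`` on the standardised scale,
where ``n_eff`` is n for quantitative traits and ``n * cf * (1-cf)`` for
case-control traits (observed-scale log-odds).  Per-allele effects follow by
dividing by ``sqrt(2 f (1-f))``.  An individual-level slow path (explicit
genotypes and phenotypes) exists as the oracle for conditional-analysis and
variance-explained checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .gwas_io import RegionDataset, TraitMeta
from .instruments import GeneRegion
from .ld import LDReference

SCENARIO_LABELS = (
    "tierA_shared", "tierB_shared", "tierC_trans", "distinct_variants",
    "reverse_causation", "heterogeneous", "pleiotropic", "null",
)

#: default study conditions of the scenario suite
SUITE_DEFAULTS = dict(
    n_ind_ld=7733, n_var=200, block_size=25, rho=0.9,
    n_exposure=30_000, n_outcome=50_000, case_fraction=0.2,
    maf_range=(0.05, 0.5),
)


@dataclass
class Scenario:
    label: str
    true_causal_effect: float
    exposure_architecture: list[tuple[int, float, str]]  # (index, std effect, cis|trans)
    shared_variant: bool
    seed: int
    outcome_architecture: list[tuple[int, float]] = field(default_factory=list)


def simulate_ld_reference(
    n_ind: int,
    n_var: int,
    block_size: int = 25,
    rho: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 100_000,
    spacing: int = 4000,
    id_prefix: str = "rs",
) -> LDReference:
    """Simulate a block-LD dosage panel.

    Two independent haplotypes per individual are generated from a latent
    first-order autoregressive Gaussian (correlation ``rho`` between adjacent
    variants, independence across blocks) and thresholded at the target
    allele frequency; dosages are the haplotype sums, so Hardy-Weinberg holds
    by construction.  Deterministic given ``seed``.
    """
    if n_ind < 50:
        raise ValueError("n_ind must be >= 50")
    lo, hi = maf_range
    if not (0 < lo < hi < 1):
        raise ValueError("degenerate maf_range")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, n_var)
    thresholds = stats.norm.isf(mafs)

    def haplotypes() -> np.ndarray:
        latent = np.empty((n_ind, n_var))
        innov = rng.standard_normal((n_ind, n_var))
        for j in range(n_var):
            if j % block_size == 0:
                latent[:, j] = innov[:, j]
            else:
                latent[:, j] = rho * latent[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j]
        return (latent > thresholds).astype(np.float64)

    dosages = haplotypes() + haplotypes()
    eaf = dosages.mean(axis=0) / 2.0
    eaf = np.clip(eaf, 1.0 / (4 * n_ind), 1 - 1.0 / (4 * n_ind))
    variants = pd.DataFrame({
        "variant_id": [f"{id_prefix}{i + 1}" for i in range(n_var)],
        "chrom": str(chrom),
        "pos": start_pos + spacing * np.arange(n_var),
        "effect_allele": "A",
        "eaf": eaf,
    })
    return LDReference(variants=variants, dosages=dosages)


def _allele_sd(eaf: np.ndarray) -> np.ndarray:
    return np.sqrt(2.0 * eaf * (1.0 - eaf))


def simulate_gwas(
    ld: LDReference,
    causal: list[tuple[int, float]],
    trait: TraitMeta,
    n: int,
    var_explained_noise: float = 0.0,
    seed: int = 0,
    causal_scale: str = "per_allele",
) -> RegionDataset:
    """Draw one GWAS of the panel's variants from the summary-level model.

    ``causal`` lists (variant index, effect size); ``causal_scale`` says
    whether those effects are per-allele or already standardised.
    ``var_explained_noise`` adds independent N(0, .) perturbations of that
    variance to the true standardised marginal effects (instrument-specific
    heterogeneity).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    m = len(ld.variants)
    eaf = ld.variants["eaf"].to_numpy()
    sig = _allele_sd(eaf)
    beta_std = np.zeros(m)
    for idx, b in causal:
        beta_std[idx] = b * sig[idx] if causal_scale == "per_allele" else b
    R = ld.corr(ld.variants["variant_id"].tolist())
    marg_std = R @ beta_std
    if var_explained_noise > 0:
        marg_std = marg_std + rng.normal(0.0, np.sqrt(var_explained_noise), m)
    n_eff = n * trait.effective_n_factor
    se_std = 1.0 / np.sqrt(n_eff)
    bhat_std = marg_std + rng.normal(0.0, se_std, m)

    beta = bhat_std / sig
    se = np.full(m, se_std) / sig
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    variants = pd.DataFrame({
        "variant_id": ld.variants["variant_id"],
        "chrom": ld.variants["chrom"],
        "pos": ld.variants["pos"].astype(np.int64),
        "effect_allele": ld.variants["effect_allele"],
        "other_allele": "G",
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": np.int64(n),
    })
    return RegionDataset(trait=trait, variants=variants)


def simulate_phenotype(
    ld: LDReference, causal: list[tuple[int, float]], seed: int = 0,
    causal_scale: str = "per_allele",
) -> np.ndarray:
    """Individual-level phenotype for the panel's own individuals (oracle path).

    y = sum_c beta_c * x_c + e with e scaled so var(y) is 1.
    """
    rng = np.random.default_rng(seed)
    eaf = ld.variants["eaf"].to_numpy()
    sig = _allele_sd(eaf)
    g = np.zeros(ld.n_individuals)
    var_g = 0.0
    for idx, b in causal:
        b_pa = b if causal_scale == "per_allele" else b / sig[idx]
        x = ld.dosages[:, idx]
        g += b_pa * x
        var_g = np.var(g)
    noise_var = max(1.0 - var_g, 0.05)
    return g + rng.normal(0.0, np.sqrt(noise_var), ld.n_individuals)


def gwas_from_genotypes(ld: LDReference, y: np.ndarray, trait: TraitMeta) -> RegionDataset:
    """Per-variant OLS marginal associations of y on each panel dosage column."""
    x = ld.dosages
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    resid = np.maximum(syy - beta * sxy, 1e-12)
    se = np.sqrt(resid / (n - 2) / sxx)
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    variants = pd.DataFrame({
        "variant_id": ld.variants["variant_id"],
        "chrom": ld.variants["chrom"],
        "pos": ld.variants["pos"].astype(np.int64),
        "effect_allele": ld.variants["effect_allele"],
        "other_allele": "G",
        "eaf": ld.variants["eaf"],
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": np.int64(n),
    })
    return RegionDataset(trait=trait, variants=variants)


# ---------------------------------------------------------------------------
# scenario suite

#: variant indices used as causal loci (distinct LD blocks at block_size=25)
PRIMARY_CAUSAL = 87
SECONDARY_CAUSAL = 137
MULTI_CAUSAL = (12, 62, 87, 112, 137, 187)

#: standardised effect sizes (fractions of phenotypic s.d. per allele-sd unit)
EXPOSURE_EFFECT = 0.225          # |z| ~ 39 at n = 30,000: a strong cis QTL
REVERSE_OUTCOME_EFFECT = 0.25    # outcome-first architecture
REVERSE_FEEDBACK = 0.5           # exposure effect as a fraction of the outcome's
MULTI_EXPOSURE_EFFECTS = (0.14, 0.26, 0.18, 0.30, 0.16, 0.22)
DISTINCT_OUTCOME_EFFECT = 0.12
HET_NOISE_SD = 0.04              # per-instrument outcome-effect jitter (std scale)
PLEIO_PER_ALLELE = 0.18          # constant directional per-allele pleiotropy
THETA = {"tierA_shared": 0.4, "tierB_shared": 0.27, "tierC_trans": 0.4,
         "heterogeneous": 0.3, "pleiotropic": 0.3}


def _gene_for(label: str) -> GeneRegion:
    chrom = "2" if label == "tierC_trans" else "1"
    return GeneRegion(gene_id="GENE1", chrom=chrom, start=430_000, end=470_000)


def _expectation_for(label: str) -> dict:
    mode = "cis_and_trans" if label == "tierC_trans" else "cis_only"
    table = {
        "tierA_shared": {"tier": ["A"]},
        "tierB_shared": {"tier": ["A", "B"]},
        "tierC_trans": {"tier": ["C"]},
        "distinct_variants": {"coloc_pass": False, "h3_gt_h4": True,
                              "tier": ["fdr_only", "none"]},
        "reverse_causation": {"steiger_pass": False},
        "heterogeneous": {"het_pass": False},
        "pleiotropic": {"pleio_pass": False},
        "null": {"fdr_pass": False, "tier": ["none"]},
    }
    return {"mode": mode, "checks": table[label]}


def build_scenario(
    label: str,
    seed: int,
    **conditions,
) -> tuple[Scenario, RegionDataset, RegionDataset, LDReference, GeneRegion, dict]:
    """Generate one labelled scenario with its expectation record."""
    if label not in SCENARIO_LABELS:
        raise ValueError(f"unknown scenario {label!r}")
    cfg = dict(SUITE_DEFAULTS, **conditions)
    rng = np.random.default_rng(seed)
    ld_seed, exp_seed, out_seed, arch_seed = rng.integers(0, 2**31 - 1, 4)

    ld = simulate_ld_reference(
        n_ind=cfg["n_ind_ld"], n_var=cfg["n_var"], block_size=cfg["block_size"],
        rho=cfg["rho"], maf_range=cfg["maf_range"], seed=int(ld_seed),
    )
    gene = _gene_for(label)
    locality = "trans" if label == "tierC_trans" else "cis"
    theta = THETA.get(label, 0.0)
    arng = np.random.default_rng(int(arch_seed))

    if label in ("tierA_shared", "tierB_shared", "tierC_trans", "null"):
        exp_arch = [(PRIMARY_CAUSAL, EXPOSURE_EFFECT)]
        out_arch = [] if label == "null" else [(PRIMARY_CAUSAL, theta * EXPOSURE_EFFECT)]
        shared = label != "null"
    elif label == "distinct_variants":
        exp_arch = [(PRIMARY_CAUSAL, EXPOSURE_EFFECT)]
        out_arch = [(SECONDARY_CAUSAL, DISTINCT_OUTCOME_EFFECT)]
        shared = False
    elif label == "reverse_causation":
        exp_arch = [(PRIMARY_CAUSAL, REVERSE_FEEDBACK * REVERSE_OUTCOME_EFFECT)]
        out_arch = [(PRIMARY_CAUSAL, REVERSE_OUTCOME_EFFECT)]
        shared = True
        theta = 0.0  # forward effect absent; signal flows outcome -> exposure
    elif label == "heterogeneous":
        exp_arch = list(zip(MULTI_CAUSAL, MULTI_EXPOSURE_EFFECTS))
        out_arch = [
            (i, theta * b + arng.normal(0.0, HET_NOISE_SD))
            for i, b in exp_arch
        ]
        shared = True
    else:  # pleiotropic
        sig = _allele_sd(ld.variants["eaf"].to_numpy())
        exp_arch = list(zip(MULTI_CAUSAL, MULTI_EXPOSURE_EFFECTS))
        out_arch = [
            (i, theta * b + PLEIO_PER_ALLELE * sig[i])
            for i, b in exp_arch
        ]
        shared = True

    exp_trait = TraitMeta(trait_id=f"{label}:exposure", trait_type="quantitative",
                          tissue="blood", qtl_type="pqtl")
    out_trait = TraitMeta(trait_id=f"{label}:outcome", trait_type="case_control",
                          case_fraction=cfg["case_fraction"])
    exposure = simulate_gwas(ld, exp_arch, exp_trait, cfg["n_exposure"],
                             seed=int(exp_seed), causal_scale="std")
    outcome = simulate_gwas(ld, out_arch, out_trait, cfg["n_outcome"],
                            seed=int(out_seed), causal_scale="std")
    scenario = Scenario(
        label=label, true_causal_effect=theta,
        exposure_architecture=[(i, b, locality) for i, b in exp_arch],
        shared_variant=shared, seed=seed,
        outcome_architecture=[(int(i), float(b)) for i, b in out_arch],
    )
    return scenario, exposure, outcome, ld, gene, _expectation_for(label)


def scenario_suite(base_seed: int, **conditions):
    """All eight labelled scenarios with self-describing expectation records."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, len(SCENARIO_LABELS))
    return [
        build_scenario(label, int(s), **conditions)
        for label, s in zip(SCENARIO_LABELS, seeds)
    ]


def write_scenario(out_dir, scenario: Scenario, exposure: RegionDataset,
                   outcome: RegionDataset, ld: LDReference, gene: GeneRegion,
                   expectation: dict) -> None:
    """Serialise one scenario: summary-stat TSVs, LD panel, genes, expectations."""
    from pathlib import Path

    from .gwas_io import write_summary_stats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_summary_stats(exposure, out / "exposure.tsv")
    write_summary_stats(outcome, out / "outcome.tsv")
    ld.save(out / "ld")
    pd.DataFrame([{
        "gene_id": gene.gene_id, "chrom": gene.chrom,
        "start": gene.start, "end": gene.end,
    }]).to_csv(out / "genes.tsv", sep="\t", index=False)
    meta = {
        "label": scenario.label,
        "seed": int(scenario.seed),
        "true_causal_effect": float(scenario.true_causal_effect),
        "shared_variant": bool(scenario.shared_variant),
        "exposure_architecture": [
            [int(i), float(b), str(loc)] for i, b, loc in scenario.exposure_architecture
        ],
        "outcome_architecture": [
            [int(i), float(b)] for i, b in scenario.outcome_architecture
        ],
        "expectation": expectation,
        "exposure_trait": {
            "trait_id": exposure.trait.trait_id, "trait_type": exposure.trait.trait_type,
        },
        "outcome_trait": {
            "trait_id": outcome.trait.trait_id, "trait_type": outcome.trait.trait_type,
            "case_fraction": outcome.trait.case_fraction,
        },
    }
    with open(out / "expectations.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
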