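import numpy as np
import pandas as pd
import pytest

from mrtier.gwas_io import RegionDataset, TraitMeta
from mrtier.ld import LDReference
from mrtier.simulate import simulate_ld_reference


def make_dataset(rows, trait=None, **trait_kwargs):
    """Build a RegionDataset from (id, chrom, pos, ea, oa, eaf, beta, se, n) tuples.

    The p-value is derived from beta/se so rows always satisfy the
    consistency invariant.
    """
    from scipy import stats

    recs = []
    for vid, chrom, pos, ea, oa, eaf, beta, se, n in rows:
        z = abs(beta / se)
        recs.append(dict(
            variant_id=vid, chrom=str(chrom), pos=int(pos), effect_allele=ea,
            other_allele=oa, eaf=eaf, beta=beta, se=se,
            pval=max(2 * stats.norm.sf(z), 1e-300), n=int(n),
        ))
    df = pd.DataFrame(recs)
    trait = trait or TraitMeta(trait_id="t", **trait_kwargs)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return RegionDataset(trait=trait, variants=df)


@pytest.fixture(scope="session")
def small_panel():
    """Block-LD panel: 60 variants, 3 blocks of 20, 1000 individuals."""
    return simulate_ld_reference(n_ind=1000, n_var=60, block_size=20, rho=0.85,
                                 maf_range=(0.1, 0.5), seed=42)


@pytest.fixture(scope="session")
def two_chrom_panel():
    """Panel spanning two chromosomes (cross-chromosome LD is exactly zero)."""
    a = simulate_ld_reference(n_ind=800, n_var=30, block_size=15, rho=0.8,
                              maf_range=(0.1, 0.5), seed=11, chrom="1", id_prefix="a")
    b = simulate_ld_reference(n_ind=800, n_var=30, block_size=15, rho=0.8,
                              maf_range=(0.1, 0.5), seed=12, chrom="2", id_prefix="b")
    variants = pd.concat([a.variants, b.variants], ignore_index=True)
    dosages = np.hstack([a.dosages, b.dosages])
    return LDReference(variants=variants, dosages=dosages)
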