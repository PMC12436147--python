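"""Wakefield-ABF colocalisation, conditional analysis, stepwise selection, PWCoCo."""

import math

import numpy as np
import pytest

from mrtier.benchmarks import coloc_enumeration_error
from mrtier.coloc import (coloc_posteriors, conditional_stats, log_abf, pwcoco,
                          stepwise_select)
from mrtier.errors import EmptyOverlapError
from mrtier.gwas_io import TraitMeta
from mrtier.simulate import gwas_from_genotypes, simulate_gwas, simulate_phenotype

QUANT = TraitMeta("q", "quantitative")


class TestLogABF:
    def test_null_z_gives_negative_log_abf(self):
        assert log_abf(0.0, 0.0004, 0.0225) == pytest.approx(
            0.5 * math.log(0.0004 / 0.0229))
        assert log_abf(0.0, 0.0004, 0.0225) < 0

    def test_strong_z_closed_form(self):
        assert log_abf(5.0, 0.0004, 0.0225) == pytest.approx(10.26, abs=0.01)

    def test_monotone_in_abs_z(self):
        vals = [log_abf(z, 0.001, 0.0225) for z in np.linspace(0, 8, 30)]
        assert np.all(np.diff(vals) > 0)
        assert log_abf(-4.0, 0.001, 0.0225) == log_abf(4.0, 0.001, 0.0225)


class TestPosteriors:
    def test_posteriors_sum_to_one(self, small_panel):
        d1 = simulate_gwas(small_panel, [(10, 0.2)], QUANT, 30_000, seed=1, causal_scale="std")
        d2 = simulate_gwas(small_panel, [(10, 0.1)], QUANT, 30_000, seed=2, causal_scale="std")
        r = coloc_posteriors(d1, d2)
        assert r.posteriors.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_strong_signal_is_h4(self, small_panel):
        d1 = simulate_gwas(small_panel, [(10, 0.25)], QUANT, 30_000, seed=3, causal_scale="std")
        r = coloc_posteriors(d1, d1)
        assert r.pp_h4 > 0.99

    def test_flat_region_is_h0(self, small_panel):
        d1 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=4)
        d2 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=5)
        r = coloc_posteriors(d1, d2)
        assert r.pp_h0 == max(r.posteriors)

    def test_matches_bruteforce_enumeration(self):
        out = coloc_enumeration_error(1234, n_regions=15, max_snps=12)
        assert out["max_abs_error"] < 1e-10

    def test_no_shared_variants_is_an_error(self, small_panel):
        d1 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=6)
        d2 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=7)
        d2.variants["variant_id"] = "x" + d2.variants["variant_id"]
        with pytest.raises(EmptyOverlapError):
            coloc_posteriors(d1, d2)


class TestConditional:
    def test_conditioning_on_uncorrelated_variant_changes_nothing(self, two_chrom_panel):
        y = simulate_phenotype(two_chrom_panel, [(5, 0.1), (40, 0.1)], seed=8)
        ds = gwas_from_genotypes(two_chrom_panel, y, QUANT)
        cond = conditional_stats(ds, two_chrom_panel, ["b11"])  # chrom-2 variant
        merged = cond.variants.merge(ds.variants, on="variant_id", suffixes=("_c", "_m"))
        chr1 = merged[merged["chrom_c"] == "1"]
        np.testing.assert_allclose(chr1["beta_c"], chr1["beta_m"], atol=1e-8)
        np.testing.assert_allclose(chr1["se_c"], chr1["se_m"], atol=1e-8)

    def test_conditioning_on_causal_collapses_tags(self, small_panel):
        causal = 10
        y = simulate_phenotype(small_panel, [(causal, 0.3)], seed=9)
        ds = gwas_from_genotypes(small_panel, y, QUANT)
        vid = small_panel.variants["variant_id"].iloc[causal]
        tag_ids = small_panel.variants["variant_id"].iloc[[8, 9, 11, 12]]
        before = ds.variants.set_index("variant_id")
        cond = conditional_stats(ds, small_panel, [vid]).variants.set_index("variant_id")
        checked = 0
        for t in tag_ids:
            if t not in cond.index:
                continue  # collinear with causal; legitimately omitted
            z_before = abs(before.loc[t, "beta"] / before.loc[t, "se"])
            if z_before < 3:
                continue  # too weak marginally for collapse to be measurable
            z_after = abs(cond.loc[t, "beta"] / cond.loc[t, "se"])
            assert z_after < 0.6 * z_before
            checked += 1
        assert checked >= 1

    def test_conditional_beta_matches_two_variable_regression(self, small_panel):
        # oracle: two-variable least squares on the genotypes themselves
        i, j = 5, 8
        y = simulate_phenotype(small_panel, [(i, 0.1), (j, 0.1)], seed=10)
        ds = gwas_from_genotypes(small_panel, y, QUANT)
        ids = small_panel.variants["variant_id"]
        cond = conditional_stats(ds, small_panel, [ids.iloc[i]]).variants.set_index("variant_id")
        X = np.column_stack([
            np.ones(small_panel.n_individuals),
            small_panel.dosages[:, i], small_panel.dosages[:, j],
        ])
        oracle = np.linalg.lstsq(X, y, rcond=None)[0][2]
        assert cond.loc[ids.iloc[j], "beta"] == pytest.approx(oracle, rel=0.02)


class TestStepwise:
    def test_single_causal_yields_single_signal_at_top_variant(self, small_panel):
        d = simulate_gwas(small_panel, [(30, 0.25)], QUANT, 30_000, seed=11, causal_scale="std")
        sigs = stepwise_select(d, small_panel)
        assert len(sigs) == 1
        top = d.variants.loc[d.variants["pval"].idxmin(), "variant_id"]
        assert sigs[0].lead_variant_id == top

    def test_two_independent_causals_yield_two_signals(self, small_panel):
        hits = 0
        for seed in range(5):
            d = simulate_gwas(small_panel, [(10, 0.25), (50, 0.15)], QUANT, 30_000,
                              seed=100 + seed, causal_scale="std")
            if len(stepwise_select(d, small_panel)) == 2:
                hits += 1
        assert hits >= 4

    def test_no_significant_variant_gives_empty_list(self, small_panel):
        d = simulate_gwas(small_panel, [], QUANT, 5_000, seed=12)
        assert stepwise_select(d, small_panel) == []


class TestPWCoCo:
    def test_single_signal_per_side_equals_plain_coloc(self, small_panel):
        d1 = simulate_gwas(small_panel, [(30, 0.25)], QUANT, 30_000, seed=13, causal_scale="std")
        d2 = simulate_gwas(small_panel, [(30, 0.12)], QUANT, 30_000, seed=14, causal_scale="std")
        res = pwcoco(d1, d2, small_panel)
        plain = coloc_posteriors(d1, d2)
        assert res.max_h4 == pytest.approx(plain.pp_h4, abs=1e-6)

    def test_conditional_pair_rescues_masked_secondary_signal(self, small_panel):
        d1 = simulate_gwas(small_panel, [(10, 0.3), (50, 0.14)], QUANT, 30_000,
                           seed=15, causal_scale="std")
        d2 = simulate_gwas(small_panel, [(50, 0.12)], QUANT, 30_000, seed=16, causal_scale="std")
        res = pwcoco(d1, d2, small_panel)
        marginal_h4 = res.pair_results[0][2].pp_h4
        assert res.max_h4 >= marginal_h4
        assert res.max_h4 > 0.8

    def test_zero_overlap_is_an_error(self, small_panel):
        d1 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=17)
        d2 = simulate_gwas(small_panel, [], QUANT, 5_000, seed=18)
        d2.variants["variant_id"] = "x" + d2.variants["variant_id"]
        with pytest.raises(EmptyOverlapError):
            pwcoco(d1, d2, small_panel)
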