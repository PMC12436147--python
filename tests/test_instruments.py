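"""Instrument selection: clumping, F-statistic, cis/trans and MHC annotation."""

import numpy as np
import pandas as pd
import pytest

from mrtier.gwas_io import RegionDataset
from mrtier.instruments import (GeneRegion, build_instrument_set,
                                classify_locality, clump, f_statistic)
from mrtier.ld import LDReference

from conftest import make_dataset


def _panel_from_dosages(dosages, chroms, pos=None):
    n_var = dosages.shape[1]
    pos = pos if pos is not None else 1000 * (np.arange(n_var) + 1)
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n_var)],
        "chrom": [str(c) for c in chroms],
        "pos": pos,
        "effect_allele": "A",
        "eaf": dosages.mean(axis=0) / 2,
    })
    return LDReference(variants=variants, dosages=dosages)


@pytest.fixture()
def correlated_pair_panel():
    """Two same-chromosome variants with substantial LD plus one independent."""
    rng = np.random.default_rng(3)
    x1 = rng.binomial(2, 0.4, 2000).astype(float)
    x2 = x1.copy()
    resample = rng.random(2000) < 0.3
    x2[resample] = rng.binomial(2, 0.4, resample.sum())
    x3 = rng.binomial(2, 0.4, 2000).astype(float)
    return _panel_from_dosages(np.column_stack([x1, x2, x3]), ["1", "1", "2"])


def _ds_for_panel(panel, zscores, n=20_000):
    rows = []
    for (vid, chrom, pos, f), z in zip(
        panel.variants[["variant_id", "chrom", "pos", "eaf"]].itertuples(index=False),
        zscores,
    ):
        se = 1.0 / np.sqrt(2 * f * (1 - f) * n)
        rows.append((vid, chrom, pos, "A", "G", f, z * se, se, n))
    return make_dataset(rows)


class TestClump:
    def test_correlated_pair_keeps_smaller_p(self, correlated_pair_panel):
        panel = correlated_pair_panel
        assert panel.r2("v0", "v1") > 0.3  # construction sanity
        ds = _ds_for_panel(panel, [7.0, 6.0, 0.5])
        kept = clump(ds, panel, p_threshold=5e-8, r2_threshold=0.001, window_kb=10_000)
        assert [v.variant_id for v in kept] == ["v0"]

    def test_single_significant_variant_retained(self, correlated_pair_panel):
        ds = _ds_for_panel(correlated_pair_panel, [6.0, 0.5, 0.5])
        kept = clump(ds, correlated_pair_panel, 5e-8, 0.001, 10_000)
        assert [v.variant_id for v in kept] == ["v0"]

    def test_different_chromosomes_both_retained(self, correlated_pair_panel):
        ds = _ds_for_panel(correlated_pair_panel, [7.0, 0.5, 6.0])
        kept = clump(ds, correlated_pair_panel, 5e-8, 0.001, 10_000)
        assert sorted(v.variant_id for v in kept) == ["v0", "v2"]

    def test_output_invariant_to_row_order(self, correlated_pair_panel):
        ds = _ds_for_panel(correlated_pair_panel, [7.0, 6.0, 6.5])
        shuffled = RegionDataset(
            trait=ds.trait,
            variants=ds.variants.sample(frac=1, random_state=5).reset_index(drop=True),
        )
        a = clump(ds, correlated_pair_panel, 5e-8, 0.001, 10_000)
        b = clump(shuffled, correlated_pair_panel, 5e-8, 0.001, 10_000)
        assert [v.variant_id for v in a] == [v.variant_id for v in b]

    def test_retained_pairs_below_r2_threshold(self, small_panel):
        rng = np.random.default_rng(9)
        z = rng.uniform(5.6, 9.0, len(small_panel.variants))
        ds = _ds_for_panel(small_panel, z)
        r2_thr = 0.05
        kept = clump(ds, small_panel, 5e-8, r2_thr, 10_000)
        ids = [v.variant_id for v in kept]
        assert len(ids) >= 2
        r2 = small_panel.corr(ids) ** 2
        off = r2[~np.eye(len(ids), dtype=bool)]
        assert np.all(off < r2_thr)

    def test_relaxing_p_threshold_only_adds_candidates(self, small_panel):
        rng = np.random.default_rng(10)
        z = rng.uniform(3.0, 9.0, len(small_panel.variants))
        ds = _ds_for_panel(small_panel, z)
        strict = clump(ds, small_panel, 5e-8, 0.05, 10_000)
        loose_candidates = set(
            ds.variants.loc[ds.variants["pval"] <= 5e-6, "variant_id"]
        )
        assert {v.variant_id for v in strict} <= loose_candidates

    def test_nothing_significant_gives_empty_list(self, small_panel):
        ds = _ds_for_panel(small_panel, np.full(len(small_panel.variants), 1.0))
        assert clump(ds, small_panel, 5e-8, 0.001, 10_000) == []


class TestStrengthAndLocality:
    def test_f_statistic_closed_form(self):
        v = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.01, 1000)]).variant("rs1")
        assert f_statistic(v) == pytest.approx(100.0)

    def test_zero_beta_zero_f(self):
        v = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.0, 0.01, 1000)]).variant("rs1")
        assert f_statistic(v) == 0.0

    def test_weak_instrument_excluded_by_f_gate(self, correlated_pair_panel):
        # z = 3.15 -> F = 9.92 < 10: dropped even though it clears a relaxed
        # p threshold; z = 4 -> F = 16 is kept
        gene = GeneRegion("G1", "1", 500, 5000)
        ds = _ds_for_panel(correlated_pair_panel, [3.15, 0.5, 4.0])
        iset = build_instrument_set(ds, gene, correlated_pair_panel, "cis_and_trans",
                                    thresholds={"p_threshold": 0.01})
        fs = {i.variant.variant_id: i.f_stat for i in iset.instruments}
        assert "v0" not in fs and fs["v2"] == pytest.approx(16.0, rel=1e-6)

    def test_cis_within_one_megabase(self):
        gene = GeneRegion("G1", "1", 1_000_000, 1_100_000)
        v = make_dataset([("rs1", "1", 1_600_000, "A", "G", 0.3, 0.1, 0.02, 1000)]).variant("rs1")
        assert classify_locality(v, gene)[0] == "cis"  # 500 kb downstream of gene end

    def test_trans_on_other_chromosome(self):
        gene = GeneRegion("G1", "1", 1_000_000, 1_100_000)
        v = make_dataset([("rs1", "2", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1000)]).variant("rs1")
        assert classify_locality(v, gene)[0] == "trans"

    def test_mhc_interval_flag(self):
        gene = GeneRegion("G1", "6", 26_000_000, 26_050_000)
        v = make_dataset([("rs1", "6", 26_000_000, "A", "G", 0.3, 0.1, 0.02, 1000)]).variant("rs1")
        locality, mhc = classify_locality(v, gene)
        assert mhc and locality == "cis"


class TestBuildInstrumentSet:
    def test_cis_only_mode_excludes_trans(self, correlated_pair_panel):
        # v0/v1 on chrom 1 (cis to gene), v2 on chrom 2 (trans)
        gene = GeneRegion("G1", "1", 500, 5000)
        ds = _ds_for_panel(correlated_pair_panel, [7.0, 0.5, 20.0])
        cis_set = build_instrument_set(ds, gene, correlated_pair_panel, "cis_only")
        assert cis_set.variant_ids == ["v0"] and cis_set.all_cis
        both = build_instrument_set(ds, gene, correlated_pair_panel, "cis_and_trans")
        assert sorted(both.variant_ids) == ["v0", "v2"] and not both.all_cis

    def test_only_trans_available_cis_only_is_empty(self, correlated_pair_panel):
        gene = GeneRegion("G1", "9", 500, 5000)
        ds = _ds_for_panel(correlated_pair_panel, [7.0, 0.5, 0.5])
        iset = build_instrument_set(ds, gene, correlated_pair_panel, "cis_only")
        assert iset.empty
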