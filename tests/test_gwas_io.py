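"""Reading, validation, windowing and harmonisation of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from mrtier.errors import EmptyDatasetError, EmptyOverlapError, FormatError
from mrtier.gwas_io import (DEFAULT_DIALECT, TraitMeta, extract_region,
                            harmonise_pair, read_summary_stats,
                            write_summary_stats)

from conftest import make_dataset

TRAIT = TraitMeta(trait_id="exp")


def _write_tsv(path, rows, drop_cols=()):
    df = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF",
                                     "BETA", "SE", "P", "N"])
    df = df.drop(columns=list(drop_cols))
    df.to_csv(path, sep="\t", index=False)
    return path


GOOD_ROWS = [
    ["rs3", "1", 300, "A", "G", 0.3, 0.10, 0.02, 5.7330314e-07, 1000],
    ["rs1", "1", 100, "C", "T", 0.2, 0.05, 0.02, 1.2419331e-02, 1000],
    ["rs2", "1", 200, "G", "A", 0.4, -0.08, 0.02, 6.3342484e-05, 1000],
]


def test_read_valid_rows_sorted_by_position(tmp_path):
    path = _write_tsv(tmp_path / "x.tsv", GOOD_ROWS)
    ds = read_summary_stats(path, trait=TRAIT)
    assert len(ds) == 3 and ds.n_dropped == 0
    assert list(ds.variants["variant_id"]) == ["rs1", "rs2", "rs3"]
    assert list(ds.variants["pos"]) == [100, 200, 300]


@pytest.mark.parametrize("mutate, reason", [
    (lambda r: r.__setitem__(7, 0.0), "nonpositive_se"),
    (lambda r: r.__setitem__(8, 0.0), "pval_out_of_range"),
    (lambda r: r.__setitem__(4, "A"), "identical_alleles"),
    (lambda r: r.__setitem__(5, 1.2), "eaf_out_of_range"),
    (lambda r: r.__setitem__(8, 0.5), "pval_inconsistent"),
])
def test_invalid_rows_dropped_with_reason(tmp_path, mutate, reason):
    rows = [list(r) for r in GOOD_ROWS]
    mutate(rows[0])
    ds = read_summary_stats(_write_tsv(tmp_path / "x.tsv", rows), trait=TRAIT)
    assert len(ds) == 2
    assert ds.n_dropped == 1 and ds.drop_log == [("rs3", reason)]


def test_missing_eaf_column_marks_absent(tmp_path):
    path = _write_tsv(tmp_path / "x.tsv", GOOD_ROWS, drop_cols=["EAF"])
    ds = read_summary_stats(path, trait=TRAIT)
    assert ds.variants["eaf"].isna().all() and len(ds) == 3


def test_missing_required_column_raises_format_error(tmp_path):
    path = _write_tsv(tmp_path / "x.tsv", GOOD_ROWS, drop_cols=["BETA"])
    with pytest.raises(FormatError, match="BETA"):
        read_summary_stats(path, trait=TRAIT)


def test_empty_file_raises(tmp_path):
    path = _write_tsv(tmp_path / "x.tsv", [])
    with pytest.raises(EmptyDatasetError):
        read_summary_stats(path, trait=TRAIT)


def test_write_read_round_trip(tmp_path):
    ds = make_dataset([("rs%d" % i, "1", 100 * i, "A", "G", 0.25, 0.01 * i, 0.02, 5000)
                       for i in range(1, 6)])
    write_summary_stats(ds, tmp_path / "w.tsv")
    back = read_summary_stats(tmp_path / "w.tsv", trait=ds.trait)
    for col in ("beta", "se", "pval", "eaf"):
        np.testing.assert_allclose(back.variants[col], ds.variants[col], rtol=1e-8)
    assert list(back.ids) == list(ds.ids)


class TestExtractRegion:
    def setup_method(self):
        self.ds = make_dataset([
            ("a", "1", 500_000, "A", "G", 0.3, 0.1, 0.02, 1000),
            ("b", "1", 1_500_000, "A", "G", 0.3, 0.1, 0.02, 1000),
            ("c", "1", 1_500_001, "A", "G", 0.3, 0.1, 0.02, 1000),
            ("d", "2", 1_000_000, "A", "G", 0.3, 0.1, 0.02, 1000),
        ])

    def test_closed_window_boundaries(self):
        sub = extract_region(self.ds, "1", 1_000_000, 500_000)
        assert list(sub.ids) == ["a", "b"]
        assert sub.window == ("1", 500_000, 1_500_000)

    def test_zero_half_width_keeps_only_center(self):
        sub = extract_region(self.ds, "1", 500_000, 0)
        assert list(sub.ids) == ["a"]

    def test_absent_chromosome_yields_flagged_empty(self):
        sub = extract_region(self.ds, "9", 1_000_000, 500_000)
        assert len(sub) == 0 and sub.empty_window

    def test_idempotent(self):
        once = extract_region(self.ds, "1", 1_000_000, 500_000)
        twice = extract_region(once, "1", 1_000_000, 500_000)
        pd.testing.assert_frame_equal(once.variants, twice.variants)


class TestHarmonise:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000)])
        out = make_dataset([("rs1", "1", 100, "G", "A", 0.7, 0.05, 0.02, 1000)])
        pair = harmonise_pair(exp, out)
        row = pair.outcome.variants.iloc[0]
        assert row["effect_allele"] == "A"
        assert row["beta"] == pytest.approx(-0.05)
        assert row["eaf"] == pytest.approx(0.3)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_dataset([("rs1", "1", 100, "A", "T", 0.50, 0.10, 0.02, 1000),
                            ("rs2", "1", 200, "A", "G", 0.30, 0.10, 0.02, 1000)])
        out = make_dataset([("rs1", "1", 100, "A", "T", 0.50, 0.05, 0.02, 1000),
                            ("rs2", "1", 200, "A", "G", 0.30, 0.05, 0.02, 1000)])
        pair = harmonise_pair(exp, out, palindrome_eaf_limit=0.42)
        assert ("rs1", "ambiguous palindrome") in pair.dropped
        assert list(pair.exposure.ids) == ["rs2"]

    def test_unambiguous_palindrome_kept(self):
        exp = make_dataset([("rs1", "1", 100, "A", "T", 0.10, 0.10, 0.02, 1000),
                            ("rs2", "1", 200, "A", "G", 0.30, 0.10, 0.02, 1000)])
        out = make_dataset([("rs1", "1", 100, "A", "T", 0.12, 0.05, 0.02, 1000),
                            ("rs2", "1", 200, "A", "G", 0.30, 0.05, 0.02, 1000)])
        pair = harmonise_pair(exp, out)
        assert list(pair.exposure.ids) == ["rs1", "rs2"]

    def test_identical_records_unchanged_and_idempotent(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000),
                            ("rs2", "1", 200, "C", "T", 0.2, -0.04, 0.01, 1000)])
        out = make_dataset([("rs1", "1", 100, "A", "G", 0.31, 0.05, 0.02, 900),
                            ("rs2", "1", 200, "C", "T", 0.21, 0.02, 0.01, 900)])
        pair = harmonise_pair(exp, out)
        again = harmonise_pair(pair.exposure, pair.outcome)
        pd.testing.assert_frame_equal(pair.exposure.variants, again.exposure.variants)
        pd.testing.assert_frame_equal(pair.outcome.variants, again.outcome.variants)

    def test_double_flip_of_outcome_is_invisible(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000),
                            ("rs2", "1", 200, "A", "T", 0.2, -0.04, 0.01, 1000)])
        out = make_dataset([("rs1", "1", 100, "A", "G", 0.31, 0.05, 0.02, 900),
                            ("rs2", "1", 200, "A", "T", 0.21, 0.02, 0.01, 900)])
        flipped = out.copy()
        v = flipped.variants
        v[["effect_allele", "other_allele"]] = v[["other_allele", "effect_allele"]].to_numpy()
        v["beta"] = -v["beta"]
        v["eaf"] = 1 - v["eaf"]
        a = harmonise_pair(exp, out)
        b = harmonise_pair(exp, flipped)
        pd.testing.assert_frame_equal(a.outcome.variants, b.outcome.variants)

    def test_zero_overlap_raises(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000)])
        out = make_dataset([("rs9", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000)])
        with pytest.raises(EmptyOverlapError):
            harmonise_pair(exp, out)

    def test_allele_mismatch_dropped(self):
        exp = make_dataset([("rs1", "1", 100, "A", "G", 0.3, 0.10, 0.02, 1000),
                            ("rs2", "1", 200, "C", "T", 0.2, 0.04, 0.01, 1000)])
        out = make_dataset([("rs1", "1", 100, "A", "C", 0.3, 0.05, 0.02, 900),
                            ("rs2", "1", 200, "C", "T", 0.2, 0.02, 0.01, 900)])
        pair = harmonise_pair(exp, out)
        assert ("rs1", "allele_mismatch") in pair.dropped
        assert list(pair.exposure.ids) == ["rs2"]
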