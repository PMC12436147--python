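"""Reading, validation, windowing and allele harmonisation of GWAS summary statistics.

All downstream stages operate on :class:`RegionDataset` objects: a validated,
position-sorted table of per-variant associations for one trait, optionally
restricted to a contiguous genomic window.  Effect sizes are per effect-allele
(log-odds for case-control traits); harmonisation re-orients outcome effects
onto the exposure's effect allele so that exposure and outcome betas are
directly comparable variant by variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDatasetError, EmptyOverlapError, FormatError

#: canonical column order of the in-memory variant table
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: default field -> file-column mapping of the summary-stat TSV dialect
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA", "eaf": "EAF",
    "beta": "BETA", "se": "SE", "pval": "P", "n": "N",
}

_PALINDROMES = ({"A", "T"}, {"C", "G"})

#: relative tolerance for the p-value vs |beta/se| consistency check
PVAL_RTOL = 0.10


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait (exposure or outcome)."""

    trait_id: str
    trait_type: str = "quantitative"  # or "case_control"
    case_fraction: float | None = None
    tissue: str = "other"  # blood | brain | other
    qtl_type: str = "none"  # pqtl | eqtl | none

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "case_control":
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise ValueError("case_control traits require case_fraction in (0,1)")
        elif self.case_fraction is not None:
            raise ValueError("case_fraction only valid for case_control traits")

    @property
    def effective_n_factor(self) -> float:
        """Scaling applied to n for case-control traits (cf*(1-cf); 1 otherwise)."""
        if self.trait_type == "case_control":
            return self.case_fraction * (1.0 - self.case_fraction)
        return 1.0


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's summary association for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    @classmethod
    def from_row(cls, row) -> "VariantAssoc":
        eaf = getattr(row, "eaf", None)
        if eaf is not None and not np.isfinite(eaf):
            eaf = None
        return cls(
            variant_id=row.variant_id, chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=row.effect_allele, other_allele=row.other_allele,
            eaf=eaf, beta=float(row.beta), se=float(row.se),
            pval=float(row.pval), n=int(row.n),
        )


@dataclass
class RegionDataset:
    """All variant associations for one trait, sorted by (chrom, pos)."""

    trait: TraitMeta
    variants: pd.DataFrame
    window: tuple[str, int, int] | None = None
    empty_window: bool = False
    n_dropped: int = 0
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def ids(self) -> pd.Series:
        return self.variants["variant_id"]

    def variant(self, variant_id: str) -> VariantAssoc:
        sub = self.variants[self.variants["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return VariantAssoc.from_row(next(sub.itertuples(index=False)))

    def subset(self, variant_ids: Sequence[str]) -> "RegionDataset":
        keep = self.variants[self.variants["variant_id"].isin(set(variant_ids))]
        return replace(self, variants=keep.copy(), n_dropped=0, drop_log=[])

    def copy(self) -> "RegionDataset":
        return replace(self, variants=self.variants.copy(), drop_log=list(self.drop_log))


@dataclass
class HarmonisedPair:
    """Exposure and outcome datasets restricted to shared, allele-aligned variants."""

    exposure: RegionDataset
    outcome: RegionDataset
    dropped: list[tuple[str, str]] = field(default_factory=list)


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMES


def validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop rows violating the per-variant invariants; return (clean, drop log)."""
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper()
    drops: list[tuple[str, str]] = []

    def flag(mask: pd.Series, reason: str) -> None:
        for vid in df.loc[mask, "variant_id"]:
            drops.append((str(vid), reason))

    num = df[["pos", "beta", "se", "pval", "n"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(num).all(axis=1)
    flag(bad, "non_numeric")
    df, num = df[~bad].copy(), num[~bad]
    df[["pos", "beta", "se", "pval", "n"]] = num

    checks = [
        (df["se"] <= 0, "nonpositive_se"),
        ((df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range"),
        (df["n"] <= 0, "nonpositive_n"),
        (df["effect_allele"] == df["other_allele"], "identical_alleles"),
    ]
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    has_eaf = eaf.notna()
    checks.append((has_eaf & ~((eaf > 0) & (eaf < 1)), "eaf_out_of_range"))

    bad = pd.Series(False, index=df.index)
    for mask, reason in checks:
        newly = mask & ~bad
        flag(newly, reason)
        bad |= mask

    df = df[~bad].copy()
    df["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")

    # p-value must agree with the two-sided normal tail of |beta/se|
    z = np.abs(df["beta"] / df["se"])
    with np.errstate(divide="ignore"):
        logp_implied = np.log(2.0) + stats.norm.logsf(z)
        logp = np.log(df["pval"].to_numpy(dtype=float))
    checkable = logp_implied > np.log(1e-290)
    incons = checkable & (np.abs(logp - logp_implied) > np.log1p(PVAL_RTOL))
    incons = pd.Series(incons, index=df.index)
    flag(incons, "pval_inconsistent")
    df = df[~incons]

    df = df.astype({"pos": np.int64, "n": np.int64})
    df = df.sort_values(["chrom", "pos", "variant_id"], kind="mergesort")
    return df[COLUMNS].reset_index(drop=True), drops


def read_summary_stats(
    path, dialect: Mapping[str, str] | None = None, trait: TraitMeta | None = None
) -> RegionDataset:
    """Read a summary-statistic TSV, validate rows, and return a RegionDataset.

    ``dialect`` maps canonical field names to file column names; fields other
    than ``eaf`` are required.  Rows violating the per-variant invariants are
    dropped and recorded in ``drop_log``.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path, sep="\t", dtype={dialect["chrom"]: str})
    for fld in COLUMNS:
        col = dialect[fld]
        if col not in raw.columns:
            if fld == "eaf":
                raw[col] = np.nan
                continue
            raise FormatError(f"missing required column {col!r} (field {fld!r})")
    if raw.empty:
        raise EmptyDatasetError(f"no rows in {path}")
    df = raw[[dialect[f] for f in COLUMNS]].copy()
    df.columns = COLUMNS
    clean, drops = validate_frame(df)
    if trait is None:
        trait = TraitMeta(trait_id=str(path))
    return RegionDataset(trait=trait, variants=clean, n_dropped=len(drops), drop_log=drops)


def write_summary_stats(ds: RegionDataset, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a RegionDataset in the summary-stat TSV dialect (inverse of reading)."""
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    out = ds.variants[COLUMNS].copy()
    out.columns = [dialect[f] for f in COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_drop_log(drops: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(drops, columns=["variant_id", "reason"]).to_csv(path, sep="\t", index=False)


def extract_region(ds: RegionDataset, chrom: str, center: int, half_width: int) -> RegionDataset:
    """Restrict to variants with pos in [center-half_width, center+half_width] (closed)."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    lo, hi = center - half_width, center + half_width
    mask = (ds.variants["chrom"] == str(chrom)) & ds.variants["pos"].between(lo, hi)
    sub = ds.variants[mask].copy()
    return RegionDataset(
        trait=ds.trait, variants=sub, window=(str(chrom), lo, hi),
        empty_window=sub.empty,
    )


def harmonise_pair(
    exposure: RegionDataset,
    outcome: RegionDataset,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonisedPair:
    """Align outcome effects onto the exposure's effect allele, variant by variant.

    Variants are matched by id.  Swapped alleles flip the outcome beta's sign
    and replace eaf by 1-eaf.  Palindromic (A/T, C/G) variants are kept only if
    both allele frequencies fall on the same side of 0.5 and outside the
    ambiguity band [limit, 1-limit]; everything else is dropped with a reason.
    """
    ex = exposure.variants.set_index("variant_id", drop=False)
    ou = outcome.variants.set_index("variant_id", drop=False)
    ex.index.name = ou.index.name = None
    dropped: list[tuple[str, str]] = []

    shared = ex.index.intersection(ou.index)
    for vid in ex.index.difference(ou.index):
        dropped.append((vid, "missing_in_outcome"))
    for vid in ou.index.difference(ex.index):
        dropped.append((vid, "missing_in_exposure"))

    ex, ou = ex.loc[shared], ou.loc[shared].copy()

    same = (ou["effect_allele"] == ex["effect_allele"]) & (ou["other_allele"] == ex["other_allele"])
    swap = (ou["effect_allele"] == ex["other_allele"]) & (ou["other_allele"] == ex["effect_allele"])
    pal = pd.Series(
        [_is_palindromic(a, b) for a, b in zip(ex["effect_allele"], ex["other_allele"])],
        index=ex.index,
    )

    keep = same | swap
    for vid in ex.index[~keep]:
        dropped.append((vid, "allele_mismatch"))

    flip = swap & ~same
    ou.loc[flip, "beta"] = -ou.loc[flip, "beta"]
    ou.loc[flip, "eaf"] = 1.0 - ou.loc[flip, "eaf"]
    ou.loc[flip, ["effect_allele", "other_allele"]] = ex.loc[flip, ["effect_allele", "other_allele"]].to_numpy()

    # palindrome ambiguity: after letter alignment, frequencies must agree in
    # orientation and be informative (outside the band around 0.5)
    f_ex, f_ou = ex["eaf"], ou["eaf"]
    lim = palindrome_eaf_limit
    informative = (
        f_ex.notna() & f_ou.notna()
        & (((f_ex < 0.5) & (f_ou < 0.5)) | ((f_ex > 0.5) & (f_ou > 0.5)))
        & ((f_ex < lim) | (f_ex > 1 - lim))
        & ((f_ou < lim) | (f_ou > 1 - lim))
    )
    ambiguous = pal & keep & ~informative
    for vid in ex.index[ambiguous]:
        dropped.append((vid, "ambiguous palindrome"))
    keep &= ~ambiguous

    ex, ou = ex[keep], ou[keep]
    if ex.empty:
        raise EmptyOverlapError("zero shared variants after harmonisation")

    order = ex.sort_values(["chrom", "pos", "variant_id"], kind="mergesort").index
    ex, ou = ex.loc[order], ou.loc[order]
    exp_ds = RegionDataset(trait=exposure.trait, variants=ex.reset_index(drop=True),
                           window=exposure.window)
    out_ds = RegionDataset(trait=outcome.trait, variants=ou.reset_index(drop=True),
                           window=outcome.window)
    return HarmonisedPair(exposure=exp_ds, outcome=out_ds, dropped=dropped)
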