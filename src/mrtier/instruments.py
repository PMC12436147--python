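"""Instrument selection: LD clumping, instrument strength, cis/trans locality.

Instruments are genome-wide-significant variants (p <= 5e-8) thinned to
mutual independence (r^2 < 0.001 within 10,000 kb) and required to have
per-variant F >= 10.  A variant is cis when it lies within +/-1 Mb of the
annotated gene body of the exposure's encoding gene, trans otherwise; variants
in the MHC (chr6:25-34 Mb) are flagged for cautious interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_io import RegionDataset, VariantAssoc
from .ld import LDReference

#: default selection thresholds
DEFAULT_THRESHOLDS = {
    "p_threshold": 5e-8,
    "clump_r2": 0.001,
    "clump_window_kb": 10_000,
    "f_min": 10.0,
    "cis_half_width_bp": 1_000_000,
    "mhc_chrom": "6",
    "mhc_interval": (25_000_000, 34_000_000),
}


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")


@dataclass(frozen=True)
class Instrument:
    variant: VariantAssoc
    f_stat: float
    locality: str  # cis | trans
    mhc_flag: bool


@dataclass
class InstrumentSet:
    exposure_id: str
    gene: GeneRegion
    instruments: list[Instrument] = field(default_factory=list)
    selection_mode: str = "cis_only"  # or cis_and_trans

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def empty(self) -> bool:
        return not self.instruments

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant.variant_id for i in self.instruments]

    @property
    def all_cis(self) -> bool:
        return bool(self.instruments) and all(i.locality == "cis" for i in self.instruments)

    @property
    def any_mhc(self) -> bool:
        return any(i.mhc_flag for i in self.instruments)


def f_statistic(v) -> float:
    """Single-variant instrument strength F = (beta/se)^2."""
    return float((v.beta / v.se) ** 2)


def classify_locality(
    v,
    gene: GeneRegion,
    cis_half_width: int = DEFAULT_THRESHOLDS["cis_half_width_bp"],
    mhc_chrom: str = DEFAULT_THRESHOLDS["mhc_chrom"],
    mhc_interval: tuple[int, int] = DEFAULT_THRESHOLDS["mhc_interval"],
) -> tuple[str, bool]:
    """Return (cis|trans, mhc_flag) for a variant relative to a gene region."""
    cis = (
        str(v.chrom) == str(gene.chrom)
        and gene.start - cis_half_width <= v.pos <= gene.end + cis_half_width
    )
    mhc = str(v.chrom) == str(mhc_chrom) and mhc_interval[0] <= v.pos <= mhc_interval[1]
    return ("cis" if cis else "trans", mhc)


def clump(
    ds: RegionDataset,
    ld: LDReference,
    p_threshold: float = DEFAULT_THRESHOLDS["p_threshold"],
    r2_threshold: float = DEFAULT_THRESHOLDS["clump_r2"],
    window_kb: int = DEFAULT_THRESHOLDS["clump_window_kb"],
) -> list[VariantAssoc]:
    """Greedy LD clumping of significant variants.

    Candidates with p <= p_threshold are visited by ascending p (ties by
    chrom, pos); each retained index variant removes remaining candidates
    within window_kb whose r^2 with it is >= r2_threshold.  Candidates absent
    from the LD panel are dropped with a warning.
    """
    cand = ds.variants[ds.variants["pval"] <= p_threshold].copy()
    present = cand["variant_id"].map(lambda v: v in ld)
    if (~present).any():
        warnings.warn(
            f"{int((~present).sum())} candidate variant(s) absent from LD reference; dropped"
        )
        cand = cand[present]
    if cand.empty:
        return []
    cand = cand.sort_values(["pval", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ids = cand["variant_id"].tolist()
    r2 = ld.corr(ids) ** 2
    pos = cand["pos"].to_numpy()
    chrom = cand["chrom"].to_numpy()
    window_bp = int(window_kb) * 1000

    alive = np.ones(len(cand), dtype=bool)
    kept: list[int] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept.append(i)
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        alive &= ~(near & (r2[i] >= r2_threshold))
        alive[i] = False
    rows = cand.iloc[kept].sort_values(["chrom", "pos"], kind="mergesort")
    return [VariantAssoc.from_row(r) for r in rows.itertuples(index=False)]


def build_instrument_set(
    ds: RegionDataset,
    gene: GeneRegion,
    ld: LDReference,
    mode: str = "cis_only",
    thresholds: dict | None = None,
) -> InstrumentSet:
    """Clump, F-filter and annotate instruments for one exposure.

    In cis_only mode trans variants are excluded before clumping; in
    cis_and_trans mode all candidates are clumped jointly.
    """
    if mode not in ("cis_only", "cis_and_trans"):
        raise ValueError(f"unknown selection mode {mode!r}")
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    work = ds
    if mode == "cis_only":
        keep = [
            classify_locality(v, gene, th["cis_half_width_bp"], th["mhc_chrom"], th["mhc_interval"])[0] == "cis"
            for v in ds.variants.itertuples(index=False)
        ]
        work = RegionDataset(trait=ds.trait, variants=ds.variants[keep].copy(), window=ds.window)
    selected = clump(work, ld, th["p_threshold"], th["clump_r2"], th["clump_window_kb"])
    out: list[Instrument] = []
    for v in selected:
        f = f_statistic(v)
        if f < th["f_min"]:
            continue
        locality, mhc = classify_locality(
            v, gene, th["cis_half_width_bp"], th["mhc_chrom"], th["mhc_interval"]
        )
        out.append(Instrument(variant=v, f_stat=f, locality=locality, mhc_flag=mhc))
    return InstrumentSet(
        exposure_id=ds.trait.trait_id, gene=gene, instruments=out, selection_mode=mode
    )


def read_gene_regions(path) -> dict[str, GeneRegion]:
    """Read a gene annotation TSV (gene_id, chrom, start, end; 1-based inclusive)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        r.gene_id: GeneRegion(r.gene_id, str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }
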