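"""LD reference panel: genotype dosages plus variant metadata.

Pairwise correlations and covariances are computed from the dosage matrix on
demand.  Variants on different chromosomes are treated as exactly independent
(r = 0) regardless of the empirical noise correlation in the panel, matching
how LD is defined operationally in clumping and conditional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LD_VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "eaf"]


@dataclass
class LDReference:
    """Dosage matrix (n_individuals x n_variants) with per-variant metadata."""

    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.variants["chrom"] = self.variants["chrom"].astype(str)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant table rows")
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def indices(self, variant_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[v] for v in variant_ids], dtype=int)

    def freqs(self, variant_ids: Sequence[str]) -> np.ndarray:
        return self.variants["eaf"].to_numpy()[self.indices(variant_ids)]

    def _chrom_mask(self, variant_ids: Sequence[str]) -> np.ndarray:
        chroms = self.variants["chrom"].to_numpy()[self.indices(variant_ids)]
        return chroms[:, None] == chroms[None, :]

    def cov(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Empirical dosage covariance (ddof=0); zero across chromosomes."""
        sub = self.dosages[:, self.indices(variant_ids)]
        c = np.cov(sub, rowvar=False, ddof=0)
        c = np.atleast_2d(c)
        same = self._chrom_mask(variant_ids)
        return np.where(same, c, 0.0)

    def corr(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Empirical dosage correlation; zero across chromosomes, NaN-safe."""
        c = self.cov(variant_ids)
        sd = np.sqrt(np.clip(np.diag(c), 1e-12, None))
        r = c / np.outer(sd, sd)
        np.fill_diagonal(r, 1.0)
        return np.clip(np.nan_to_num(r), -1.0, 1.0)

    def r2(self, id1: str, id2: str) -> float:
        return float(self.corr([id1, id2])[0, 1] ** 2)

    def save(self, prefix) -> None:
        """Write variant table (<prefix>.variants.tsv) and dosages (<prefix>.dosages.tsv)."""
        prefix = Path(prefix)
        self.variants[LD_VARIANT_COLUMNS].to_csv(
            prefix.with_suffix(".variants.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        np.savetxt(prefix.with_suffix(".dosages.tsv"), self.dosages, fmt="%g", delimiter="\t")

    @classmethod
    def load(cls, prefix) -> "LDReference":
        prefix = Path(prefix)
        variants = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t", dtype={"chrom": str})
        dosages = np.loadtxt(prefix.with_suffix(".dosages.tsv"), delimiter="\t", ndmin=2)
        return cls(variants=variants, dosages=dosages)
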