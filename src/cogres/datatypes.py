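"""Core in-memory containers shared across the pipeline.

Genotypes live in a :class:`GenotypeDataset` (dense dosage matrix plus a
variant metadata frame); everything downstream (summary statistics, LD
scores, locus tables) is a plain :class:`pandas.DataFrame` with documented
column conventions:

* summary statistics — ``SNP CHR BP A1 A2 FRQ BETA SE Z P N`` (GenomicSEM
  style; ``A1`` is the effect allele, ``FRQ`` its frequency),
* munged statistics — ``SNP A1 A2 Z N`` (plus ``FRQ`` when available),
* LD scores — ``CHR SNP BP L2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order for written summary-statistics tables
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FRQ", "BETA", "SE", "Z", "P", "N"]

#: variant metadata columns carried by GenotypeDataset.variants
VARIANT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "INFO"]


@dataclass
class GenotypeDataset:
    """Dense dosage matrix with aligned variant and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` array of ALT-allele (A1) dosages in
        ``{0, 1, 2}``; ``NaN`` marks a missing genotype.
    variants
        Frame with columns ``SNP CHR BP A1 A2 INFO`` (``A1`` = ALT = counted
        allele, ``A2`` = REF), one row per dosage column.
    samples
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x variants) array")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage matrix "
                f"has {self.dosages.shape[1]} columns"
            )
        if self.samples is None or len(self.samples) == 0:
            self.samples = [f"id_{i + 1}" for i in range(self.dosages.shape[0])]
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list length does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)
        if "INFO" not in self.variants.columns:
            self.variants = self.variants.assign(INFO=1.0)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed A1 (ALT) allele frequency per variant, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, index) -> "GenotypeDataset":
        """New dataset restricted to the given variant positions (boolean mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
        )

    def variant_index(self) -> pd.Series:
        """Map from variant id to column position."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["SNP"].to_numpy())

    def standardized_dosages(self) -> np.ndarray:
        """Mean-zero, unit-variance dosages (missing values mean-imputed)."""
        g = self.dosages.copy()
        mu = np.nanmean(g, axis=0)
        nan_mask = np.isnan(g)
        if nan_mask.any():
            g[nan_mask] = np.broadcast_to(mu, g.shape)[nan_mask]
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return (g - mu) / sd
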