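"""Preparation of the paired 16S amplicon taxon table.

Raw OTU read counts are rescaled to proportions times the minimum
library size, paired with flow-cytometric total cell densities to give
absolute abundances (cells/ml), filtered at the cytometric detection
limit (10^3 cells/ml — below that a taxon cannot contribute a visible
population to the fingerprint), and thresholded at 1% relative abundance
for presence/absence labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaxonTable",
    "DensitySeries",
    "rescale_counts",
    "absolute_abundance",
    "detection_filter",
    "presence_labels",
    "top_taxa",
    "DETECTION_LIMIT",
    "PRESENCE_CUTOFF",
]

DETECTION_LIMIT = 1e3   # cells/ml; cytometric quantification limit x10 dilution
PRESENCE_CUTOFF = 0.01  # relative abundance defining "present"


@dataclass
class TaxonTable:
    """Samples x taxa abundances (rescaled counts + relative fractions).

    ``relative`` rows sum to 1 as produced by :func:`rescale_counts`; after
    :func:`detection_filter` they may sum to less than 1 (rows are
    deliberately not re-closed, so surviving entries keep their values).
    """

    counts: pd.DataFrame
    relative: pd.DataFrame
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.relative.index):
            raise ValueError("counts and relative must share sample ids")
        if not self.counts.columns.equals(self.relative.columns):
            raise ValueError("counts and relative must share taxon ids")
        rowsum = self.relative.to_numpy().sum(axis=1)
        if np.any(rowsum > 1 + 1e-9):
            raise ValueError("relative abundance rows must sum to at most 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DensitySeries:
    """Total bacterial density (cells/ml) per sample."""

    density: pd.Series

    def __post_init__(self) -> None:
        d = self.density.astype(float)
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("densities must be finite and > 0")
        self.density = d

    @property
    def sample_ids(self) -> list[str]:
        return list(self.density.index)

    def aligned_to(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.density.index]
        if missing:
            raise KeyError(f"no density for samples: {missing}")
        return self.density.loc[list(sample_ids)].to_numpy()


def rescale_counts(raw_counts: pd.DataFrame, taxonomy: dict | None = None) -> TaxonTable:
    """Proportions times the minimum library size in the dataset.

    This puts every sample on the depth of the shallowest one without
    discarding reads (the fractional analogue of rarefying).
    """
    raw = raw_counts.astype(float)
    totals = raw.to_numpy().sum(axis=1)
    zero = [sid for sid, t in zip(raw.index, totals) if t <= 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    relative = raw.div(totals, axis=0)
    rescaled = relative * totals.min()
    return TaxonTable(counts=rescaled, relative=relative, taxonomy=taxonomy or {})


def absolute_abundance(table: TaxonTable, densities: DensitySeries) -> pd.DataFrame:
    """Relative abundance times total cell density, in cells/ml."""
    d = densities.aligned_to(table.sample_ids)
    return table.relative.mul(d, axis=0)


def detection_filter(
    table: TaxonTable,
    densities: DensitySeries,
    limit: float = DETECTION_LIMIT,
) -> TaxonTable:
    """Zero relative abundances whose absolute abundance is below *limit*.

    Entries with relative x density < limit cells/ml are set to 0; rows
    are not re-closed.  Idempotent.
    """
    if limit < 0:
        raise ValueError("detection limit must be >= 0")
    absolute = absolute_abundance(table, densities)
    relative = table.relative.where(absolute.to_numpy() >= limit, 0.0)
    return TaxonTable(counts=table.counts.copy(), relative=relative, taxonomy=dict(table.taxonomy))


def presence_labels(
    table: TaxonTable, taxon_id: str, cutoff: float = PRESENCE_CUTOFF
) -> pd.Series:
    """Boolean presence per sample: relative abundance >= cutoff.

    The 1% default absorbs sequencing-depth jitter around very low
    abundances; equality counts as present.
    """
    if taxon_id not in table.relative.columns:
        raise KeyError(f"unknown taxon {taxon_id!r}")
    return table.relative[taxon_id] >= cutoff


def top_taxa(table: TaxonTable, n: int) -> list[str]:
    """Taxa ranked by mean relative abundance (descending, id tie-break)."""
    if n > len(table.taxon_ids):
        raise ValueError(f"asked for top {n} of {len(table.taxon_ids)} taxa")
    means = table.relative.mean(axis=0)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    return order[:n]
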