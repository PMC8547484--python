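"""In silico sample combination against zero-inflated abundance targets.

Per-taxon relative abundances from amplicon surveys are dominated by
zeros and near-zeros, which starves the regression stage of informative
high-abundance examples.  Mixing two measured communities physically
(at equal cell density) yields fingerprints and taxon abundances that
are convex combinations of the sources, so synthetic training rows are
generated the same way: draw a pair of training samples and a weight
``w ~ Uniform(0, 1)``, and take ``w * a + (1 - w) * b`` in
relative-composition space for both the fingerprint and the taxon
target.  When source densities differ, the optional density-weighted
mode rescales the mixing weight by the source cell densities.

Augmentation must happen strictly inside a training fold; the
provenance of every synthetic row is recorded and can be audited
against a validation set (see :func:`audit_provenance`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprint import clr
from .taxa import DensitySeries

__all__ = ["AugmentedSet", "combine_samples", "audit_provenance"]


@dataclass
class AugmentedSet:
    """Original plus synthetic rows for one taxon's training fold."""

    features: pd.DataFrame          # rows x K, clr space
    targets: np.ndarray             # relative abundance of the focal taxon
    provenance: list[dict]          # per row: {"sources": [...], "weight": w}
    n_original: int
    n_synthetic: int

    def __post_init__(self) -> None:
        n = self.n_original + self.n_synthetic
        if not (len(self.features) == len(self.targets) == len(self.provenance) == n):
            raise ValueError("inconsistent augmented-set sizes")


def combine_samples(
    fingerprints_rel: pd.DataFrame,
    taxon_rel: pd.Series,
    densities: DensitySeries | None = None,
    n_new: int | None = None,
    seed: int = 0,
    weight_mode: str = "equal",
) -> AugmentedSet:
    """Append *n_new* pairwise convex combinations of training samples.

    Parameters
    ----------
    fingerprints_rel
        Training-fold fingerprint rows in relative-composition space
        (strictly positive, rows sum to 1).
    taxon_rel
        The focal taxon's relative abundance per training sample.
    densities
        Required for ``weight_mode="density"``: the mixture of two
        communities with densities ``d_a, d_b`` at volume fraction ``w``
        has composition weights proportional to ``w d_a`` and
        ``(1 - w) d_b``.
    n_new
        Number of synthetic rows; defaults to the number of original
        rows (dataset doubling).
    """
    ids = list(fingerprints_rel.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 training samples to combine")
    if not fingerprints_rel.index.equals(taxon_rel.index):
        raise ValueError("fingerprints and taxon targets must share sample ids")
    if weight_mode not in ("equal", "density"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if weight_mode == "density" and densities is None:
        raise ValueError("density weighting requires a DensitySeries")
    if n_new is None:
        n_new = len(ids)

    rng = np.random.default_rng(seed)
    F = fingerprints_rel.to_numpy()
    t = taxon_rel.to_numpy(dtype=float)
    d = densities.aligned_to(ids) if weight_mode == "density" else None

    rows, targets, prov = [], [], []
    for _ in range(n_new):
        a, b = rng.choice(len(ids), size=2, replace=True)
        w = float(rng.uniform())
        if weight_mode == "density":
            wa = w * d[a]
            w = wa / (wa + (1 - w) * d[b])
        rows.append(w * F[a] + (1 - w) * F[b])
        targets.append(w * t[a] + (1 - w) * t[b])
        prov.append({"sources": [ids[a], ids[b]], "weight": w})

    synth = np.asarray(rows) if rows else np.empty((0, F.shape[1]))
    all_rel = np.vstack([F, synth]) if len(rows) else F
    features = pd.DataFrame(
        clr(all_rel),
        index=ids + [f"synthetic_{i:04d}" for i in range(len(rows))],
        columns=fingerprints_rel.columns,
    )
    provenance = [{"sources": [sid], "weight": 1.0} for sid in ids] + prov
    return AugmentedSet(
        features=features,
        targets=np.concatenate([t, np.asarray(targets)]) if rows else t,
        provenance=provenance,
        n_original=len(ids),
        n_synthetic=len(rows),
    )


def audit_provenance(augmented: AugmentedSet, validation_ids) -> None:
    """Raise if any row traces back to a validation sample (leakage)."""
    forbidden = set(validation_ids)
    leaks = [
        (i, p)
        for i, p in enumerate(augmented.provenance)
        if forbidden.intersection(p["sources"])
    ]
    if leaks:
        raise RuntimeError(
            f"augmentation leakage: {len(leaks)} rows reference validation "
            f"samples, first: {leaks[0]}"
        )
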