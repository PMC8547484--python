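"""Gaussian-mixture fingerprinting of preprocessed cytometry data.

A single Gaussian mixture model ("mask") is fitted on events pooled from
all samples (equal subsampling per sample, so no sample dominates), with
the number of components chosen by BIC over a candidate grid.  Every
cell of every sample is then hard-assigned to its maximum-posterior
component, giving a per-sample vector of cluster counts — the cytometric
fingerprint.  Counts are closed to relative abundances (with a
pseudocount so no cluster is exactly zero) and mapped out of the simplex
with the centered log-ratio (clr) transform:

    clr(x)_j = ln( x_j / g(x) ),   g(x) = (prod_j x_j)^(1/K)

clr rows sum to zero and are invariant to rescaling the composition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .fcm_io import EventMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GMMMask",
    "FingerprintTable",
    "subsample_events",
    "fit_mask",
    "assign_counts",
    "build_fingerprints",
    "clr",
    "fingerprint_samples",
]

DEFAULT_CHANNELS = ["FSC-A", "SSC-A", "FL1-A", "FL3-A"]
DEFAULT_K_GRID = (5, 10, 20, 40, 80, 128)


def clr(relative: np.ndarray) -> np.ndarray:
    """Centered log-ratio of strictly positive compositions (rows)."""
    rel = np.asarray(relative, dtype=float)
    if np.any(rel <= 0):
        raise ValueError("clr requires strictly positive parts; add a pseudocount")
    log = np.log(rel)
    return log - log.mean(axis=-1, keepdims=True)


@dataclass
class GMMMask:
    """A fitted dataset-level Gaussian mixture used to discretize samples."""

    model: GaussianMixture
    channels: list[str]
    bic_trace: dict[int, float]
    seed: int

    @property
    def n_components(self) -> int:
        return int(self.model.n_components)

    @property
    def component_means(self) -> np.ndarray:
        return self.model.means_

    @property
    def component_covariances(self) -> np.ndarray:
        return self.model.covariances_

    @property
    def component_weights(self) -> np.ndarray:
        return self.model.weights_

    @property
    def cluster_ids(self) -> list[str]:
        return [f"c{i:03d}" for i in range(self.n_components)]

    def __post_init__(self) -> None:
        w = self.model.weights_
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights do not sum to 1")
        if self.bic_trace:
            best = min(self.bic_trace, key=self.bic_trace.get)
            if best != self.n_components:
                raise ValueError(
                    f"mask has K={self.n_components} but BIC minimum is at K={best}"
                )


@dataclass
class FingerprintTable:
    """Per-sample cluster occupancy: counts, closed relative values, clr."""

    counts: pd.DataFrame       # samples x K, integer
    relative: pd.DataFrame     # rows sum to 1 (pseudocount-closed)
    clr_values: pd.DataFrame   # rows sum to 0

    def __post_init__(self) -> None:
        rowsum = self.relative.to_numpy().sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("relative rows must sum to 1")
        clrsum = self.clr_values.to_numpy().sum(axis=1)
        if not np.allclose(clrsum, 0.0, atol=1e-6):
            raise ValueError("clr rows must sum to 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path) -> None:
        self.clr_values.to_csv(path, sep="\t", index_label="sample_id")


def subsample_events(
    samples: list[EventMatrix], n_per_sample: int, seed: int
) -> EventMatrix:
    """Pool an equal-depth random draw (without replacement) from each sample.

    Samples shallower than *n_per_sample* contribute everything they have
    (with a logged warning) — the pool is then slightly unbalanced but no
    events are fabricated.
    """
    if not samples:
        raise ValueError("no samples to subsample")
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    channels = samples[0].channels
    for s in samples:
        if s.channels != channels:
            raise ValueError(f"sample {s.sample_id!r} has mismatched channels")
        if s.n_events == 0:
            raise ValueError(f"sample {s.sample_id!r} has no events")
        if s.n_events < n_per_sample:
            logger.warning(
                "sample %s has only %d events (< %d); using all of them",
                s.sample_id, s.n_events, n_per_sample,
            )
            parts.append(s.values)
        else:
            idx = rng.choice(s.n_events, size=n_per_sample, replace=False)
            parts.append(s.values[np.sort(idx)])
    return EventMatrix("pooled", list(channels), np.vstack(parts))


def fit_mask(
    pooled: EventMatrix,
    k_grid: list[int] | tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
) -> GMMMask:
    """Fit mixtures for each candidate K and keep the BIC-minimal one.

    Full covariances; deterministic under the seed.  Candidates whose fit
    degenerates are skipped with a warning; if every candidate fails an
    error is raised.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or min(k_grid) < 1:
        raise ValueError("k_grid must contain positive integers")
    X = pooled.values
    bic_trace: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_grid:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=seed,
            n_init=1,
            reg_covar=1e-6,
            max_iter=200,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            if not gm.converged_ and k > 1:
                logger.warning("GMM with K=%d did not converge; keeping fit anyway", k)
            bic = float(gm.bic(X))
            if not np.isfinite(bic):
                raise ValueError("non-finite BIC")
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("skipping K=%d: degenerate fit (%s)", k, exc)
            continue
        bic_trace[k] = bic
        fits[k] = gm
    if not fits:
        raise RuntimeError("every candidate K produced a degenerate mixture fit")
    best = min(bic_trace, key=bic_trace.get)
    logger.info("selected K=%d by BIC (trace over %s)", best, sorted(bic_trace))
    return GMMMask(fits[best], list(pooled.channels), bic_trace, seed)


def assign_counts(mask: GMMMask, events: EventMatrix) -> np.ndarray:
    """Hard-assign each event to its maximum-posterior component; return counts."""
    if events.channels != mask.channels:
        raise ValueError(
            f"sample {events.sample_id!r} channels {events.channels} do not match "
            f"mask channels {mask.channels}"
        )
    k = mask.n_components
    if events.n_events == 0:
        return np.zeros(k, dtype=int)
    labels = mask.model.predict(events.values)
    return np.bincount(labels, minlength=k).astype(int)


def build_fingerprints(
    mask: GMMMask,
    samples: list[EventMatrix],
    pseudocount: float = 1.0,
) -> FingerprintTable:
    """Counts -> pseudocount-closed relative abundances -> clr, per sample."""
    if not samples:
        raise ValueError("no samples")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rows = []
    ids = []
    for s in samples:
        if s.n_events == 0:
            raise ValueError(f"sample {s.sample_id!r} has zero gated events")
        rows.append(assign_counts(mask, s))
        ids.append(s.sample_id)
    counts = np.asarray(rows)
    shifted = counts + pseudocount
    if np.any(shifted.sum(axis=1) <= 0) or (pseudocount == 0 and np.any(counts == 0)):
        raise ValueError(
            "zero cluster counts with pseudocount=0; clr would be undefined"
        )
    relative = shifted / shifted.sum(axis=1, keepdims=True)
    cols = mask.cluster_ids
    return FingerprintTable(
        counts=pd.DataFrame(counts, index=ids, columns=cols),
        relative=pd.DataFrame(relative, index=ids, columns=cols),
        clr_values=pd.DataFrame(clr(relative), index=ids, columns=cols),
    )


def fingerprint_samples(
    samples: list[EventMatrix],
    gate,
    target_channel: str = "FL1-A",
    k_grid: list[int] | tuple[int, ...] = DEFAULT_K_GRID,
    n_per_sample: int = 5000,
    pseudocount: float = 1.0,
    seed: int = 0,
):
    """Full preprocessing chain: gate, normalize, fit mask, fingerprint.

    *samples* must already be arcsinh-transformed.  Returns
    ``(mask, norm_constant, FingerprintTable)``.
    """
    from .fcm_io import apply_gate, compute_norm_constant, normalize

    gated = [apply_gate(s, gate) for s in samples] if gate is not None else list(samples)
    empty = [s.sample_id for s in gated if s.n_events == 0]
    if empty:
        raise ValueError(f"samples with no events after gating: {empty}")
    norm_constant = compute_norm_constant(gated, target_channel)
    normed = [normalize(s, norm_constant, target_channel) for s in gated]
    pooled = subsample_events(normed, n_per_sample, seed)
    mask = fit_mask(pooled, k_grid, seed)
    table = build_fingerprints(mask, normed, pseudocount)
    return mask, norm_constant, table
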