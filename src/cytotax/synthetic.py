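"""Paired synthetic cytometry + amplicon datasets with known ground truth.

Each taxon gets a Gaussian "signature" in the 4-channel transformed
measurement space (FSC, SSC, FL1 527/32, FL3 700/54) — the synthetic
counterpart of the observation that individual taxa occupy specific
regions of the cytometric fingerprint.  A sample is simulated by

1. drawing a true community composition — either a zero-inflated
   Dirichlet-style draw with AR(1) temporal correlation within each
   replicate "tank", or a deterministic simplex grid (the mock-community
   scenario);
2. drawing a total cell density from a log-normal law;
3. allocating cytometer events multinomially to taxa and sampling each
   event from its taxon's signature (plus a low-fluorescence background
   population that the gate is meant to remove);
4. drawing sequencing counts multinomially from the same composition.

Everything is deterministic under the scenario seed, and the true
compositions and signatures are returned so recovery can be tested.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .fcm_io import EventMatrix, PolygonGate, write_fcs
from .fingerprint import DEFAULT_CHANNELS, GMMMask, assign_counts
from .taxa import DensitySeries

__all__ = [
    "TaxonSignature",
    "ScenarioConfig",
    "SimulatedDataset",
    "make_signatures",
    "simulate_dataset",
    "mock3_scenario",
    "default_gate",
    "truth_regions",
    "write_dataset",
]

# channel-space geometry (arcsinh-transformed units)
_CENTER = np.array([6.5, 6.5, 7.0, 5.0])
_BASE_SD = 0.3
_BACKGROUND_MEAN = np.array([2.0, 2.0, 1.0, 1.0])
_BACKGROUND_SD = 0.6


@dataclass
class TaxonSignature:
    """Mixture-of-Gaussians signature of one taxon in transformed space."""

    taxon_id: str
    components: list[tuple[np.ndarray, np.ndarray, float]]  # (mean, cov, weight)

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("signature component weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            return np.empty((0, len(self.components[0][0])))
        weights = np.array([c[2] for c in self.components])
        counts = rng.multinomial(n, weights)
        parts = [
            rng.multivariate_normal(mean, cov, size=k)
            for (mean, cov, _), k in zip(self.components, counts)
            if k
        ]
        return np.vstack(parts)


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated dataset."""

    n_taxa: int = 10
    n_samples: int = 100
    n_groups: int = 5                  # replicate tanks
    events_per_sample: int = 5000
    seq_depth: int = 10000
    density_log_mean: float = math.log(1e6)   # cells/ml
    density_log_sd: float = 0.5
    abundance_alpha: float = 0.7       # Dirichlet-style concentration
    zero_inflation: float = 0.4        # per taxon-sample P(true abundance = 0)
    separation: float = 4.0            # signature spacing in units of within-cluster sd
    temporal_autocorrelation: float = 0.6
    background_fraction: float = 0.05
    abundance_mode: str = "dirichlet"  # or "simplex_grid"
    overdispersion: float | None = None  # Dirichlet-multinomial scale for seq counts
    seed: int = 0
    channels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_samples < 1 or self.n_groups < 1:
            raise ValueError("counts must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0 <= self.temporal_autocorrelation < 1:
            raise ValueError("temporal_autocorrelation must be in [0, 1)")


@dataclass
class SimulatedDataset:
    """Simulated events, sequencing counts, densities and the ground truth."""

    events: list[EventMatrix]          # arcsinh-transformed space, ungated
    raw_counts: pd.DataFrame           # samples x taxa sequencing counts
    densities: DensitySeries
    true_relative: pd.DataFrame        # ground-truth compositions
    signatures: list[TaxonSignature]
    groups: dict[str, str]             # sample id -> tank id
    config: ScenarioConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw_counts.index)


def make_signatures(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[TaxonSignature]:
    """Taxon means on a jittered 4-D lattice scaled by ``separation``.

    The lattice spacing is ``separation`` times the within-cluster sd, so
    ``separation`` directly controls how resolvable taxa are; at 0 all
    signatures coincide.
    """
    rng = rng or np.random.default_rng(config.seed)
    d = len(config.channels)
    spacing = config.separation * _BASE_SD
    side = max(2, math.ceil(config.n_taxa ** (1.0 / d)))
    lattice = np.array(list(itertools.product(range(side), repeat=d)), dtype=float)
    lattice -= (side - 1) / 2.0
    order = rng.permutation(len(lattice))[: config.n_taxa]
    signatures = []
    for i, li in enumerate(order):
        jitter = rng.uniform(-0.25, 0.25, size=d) * spacing
        mean = _CENTER + lattice[li] * spacing + jitter
        sd = _BASE_SD * rng.uniform(0.8, 1.2, size=d)
        cov = np.diag(sd ** 2)
        signatures.append(TaxonSignature(f"taxon_{i:02d}", [(mean, cov, 1.0)]))
    return signatures


def _simplex_grid(n_taxa: int, n_points: int) -> np.ndarray:
    """Smallest regular simplex grid with at least *n_points* compositions."""
    for denom in itertools.count(1):
        pts = [
            np.array(c) / denom
            for c in itertools.product(range(denom + 1), repeat=n_taxa)
            if sum(c) == denom
        ]
        if len(pts) >= n_points:
            return np.array(pts)


def _dirichlet_compositions(
    config: ScenarioConfig, group_sizes: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Zero-inflated Dirichlet-style draws, AR(1)-correlated within a tank.

    A Gaussian copula carries the temporal correlation: each taxon's
    latent series follows AR(1) within a group, is mapped through the
    normal CDF, and becomes a Gamma(alpha) variate; zeroing then masks
    taxa independently and the survivors are closed to a composition.
    """
    rho = config.temporal_autocorrelation
    rows = []
    for size in group_sizes:
        z = np.zeros((size, config.n_taxa))
        z[0] = rng.standard_normal(config.n_taxa)
        for t in range(1, size):
            z[t] = rho * z[t - 1] + math.sqrt(1 - rho ** 2) * rng.standard_normal(
                config.n_taxa
            )
        u = stats.norm.cdf(z)
        g = stats.gamma.ppf(u, a=config.abundance_alpha)
        keep = rng.uniform(size=g.shape) >= config.zero_inflation
        for t in range(size):
            if not keep[t].any():           # never produce an empty community
                keep[t, int(np.argmax(g[t]))] = True
        g = np.where(keep, g, 0.0)
        g = np.where(keep & (g <= 0), 1e-12, g)
        rows.append(g / g.sum(axis=1, keepdims=True))
    return np.vstack(rows)


def simulate_dataset(
    config: ScenarioConfig, signatures: list[TaxonSignature] | None = None
) -> SimulatedDataset:
    """Generate one paired dataset under *config* (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    if signatures is None:
        signatures = make_signatures(config, rng)
    if len(signatures) != config.n_taxa:
        raise ValueError("signature count does not match n_taxa")

    base = config.n_samples // config.n_groups
    group_sizes = [
        base + (1 if g < config.n_samples % config.n_groups else 0)
        for g in range(config.n_groups)
    ]

    if config.abundance_mode == "simplex_grid":
        grid = _simplex_grid(config.n_taxa, config.n_samples)
        comp = grid[rng.permutation(len(grid))[: config.n_samples]]
    elif config.abundance_mode == "dirichlet":
        comp = _dirichlet_compositions(config, group_sizes, rng)
    else:
        raise ValueError(f"unknown abundance_mode {config.abundance_mode!r}")

    sample_ids, groups = [], {}
    i = 0
    for g, size in enumerate(group_sizes):
        for t in range(size):
            sid = f"tank{g + 1}_t{t:03d}"
            sample_ids.append(sid)
            groups[sid] = f"tank{g + 1}"
            i += 1

    density = np.exp(
        rng.normal(config.density_log_mean, config.density_log_sd, size=config.n_samples)
    )

    channels = list(config.channels)
    n_bg = int(round(config.events_per_sample * config.background_fraction))
    n_signal = config.events_per_sample - n_bg
    events = []
    seq_rows = []
    for s in range(config.n_samples):
        taxon_counts = rng.multinomial(n_signal, comp[s])
        parts = [
            sig.sample(k, rng) for sig, k in zip(signatures, taxon_counts) if k
        ]
        if n_bg:
            parts.append(
                rng.normal(
                    _BACKGROUND_MEAN, _BACKGROUND_SD, size=(n_bg, len(channels))
                )
            )
        values = np.vstack(parts)
        values = values[rng.permutation(len(values))]
        events.append(EventMatrix(sample_ids[s], channels, values))

        p = comp[s]
        if config.overdispersion is not None:
            alpha = p * config.overdispersion
            alpha = np.where(p > 0, alpha, 0.0)
            draw = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
            p = draw / draw.sum()
        seq_rows.append(rng.multinomial(config.seq_depth, p))

    taxon_ids = [sig.taxon_id for sig in signatures]
    return SimulatedDataset(
        events=events,
        raw_counts=pd.DataFrame(seq_rows, index=sample_ids, columns=taxon_ids),
        densities=DensitySeries(pd.Series(density, index=sample_ids, name="cells_per_ml")),
        true_relative=pd.DataFrame(comp, index=sample_ids, columns=taxon_ids),
        signatures=signatures,
        groups=groups,
        config=config,
    )


def mock3_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The packaged three-strain mock-community analogue.

    Three well-separated taxa, 60 samples on a regular simplex grid of
    compositions — the simplest community on which the full pipeline
    should perform near-perfectly.
    """
    cfg = ScenarioConfig(
        n_taxa=3,
        n_samples=60,
        n_groups=3,
        events_per_sample=5000,
        seq_depth=5000,
        separation=8.0,
        abundance_mode="simplex_grid",
        zero_inflation=0.0,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_gate() -> PolygonGate:
    """Rectangular gate on the fluorescence plane excluding the background.

    Drawn in arcsinh-transformed coordinates on FL1 x FL3; the synthetic
    background population sits at low fluorescence, well outside.
    """
    return PolygonGate.rectangle("FL1-A", "FL3-A", 3.0, 13.0, 2.0, 13.0)


def truth_regions(
    mask: GMMMask,
    signatures: list[TaxonSignature],
    norm_constant: float,
    n_events: int = 2000,
    min_fraction: float = 0.10,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Mask clusters that each taxon's signature actually populates.

    Samples events from each signature, pushes them through the same
    normalization, and keeps clusters receiving at least *min_fraction*
    of the events — the ground-truth localization used to validate
    feature importances.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sig in signatures:
        ev = EventMatrix(sig.taxon_id, list(mask.channels), sig.sample(n_events, rng) / norm_constant)
        counts = assign_counts(mask, ev)
        frac = counts / counts.sum()
        region = {cid for cid, f in zip(mask.cluster_ids, frac) if f >= min_fraction}
        if not region:
            region = {mask.cluster_ids[int(np.argmax(frac))]}
        out[sig.taxon_id] = region
    return out


def hurdle_stress_dataset(
    n_samples: int = 150,
    n_clusters: int = 8,
    presence_rate: float = 0.5,
    signal: float = 2.0,
    noise_sd: float = 0.8,
    abundance_range: tuple[float, float] = (0.12, 0.5),
    seq_depth: int = 10000,
    fingerprint_depth: int = 5000,
    seed: int = 0,
):
    """A regime where raw regression false-positives are rampant.

    One focal taxon is absent in about half the samples but *abundant
    whenever present* (a bloomer: at least 12% by default).  Its presence
    modulates the intensity of one fingerprint cluster noisily, so the
    classifier is good but not perfect, while its abundance when present
    is drawn independently of every feature.  Because the smallest
    nonzero abundance is large, the zero replacement (one-tenth of it)
    lands above the 1% presence criterion, so the raw regression cannot
    express "below 1%" at all: truly-absent samples are called present
    en masse until the classifier is superimposed.

    Returns ``(PairedDataset, focal_taxon_id)``.
    """
    from .evaluate import PairedDataset
    from .fingerprint import FingerprintTable, clr as _clr
    from .taxa import rescale_counts

    rng = np.random.default_rng(seed)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    present = rng.uniform(size=n_samples) < presence_rate
    abundance = np.where(
        present,
        np.exp(
            rng.uniform(
                math.log(abundance_range[0]),
                math.log(abundance_range[1]),
                size=n_samples,
            )
        ),
        0.0,
    )

    # fingerprint: one presence-responsive cluster among noise clusters
    intensity = np.column_stack(
        [
            np.exp(
                signal * present + rng.normal(0.0, noise_sd, size=n_samples)
            )
        ]
        + [
            rng.gamma(2.0, size=n_samples) for _ in range(n_clusters - 1)
        ]
    )
    comp = intensity / intensity.sum(axis=1, keepdims=True)
    fp_counts = np.array([rng.multinomial(fingerprint_depth, c) for c in comp])
    shifted = fp_counts + 1.0
    fp_rel = shifted / shifted.sum(axis=1, keepdims=True)
    cols = [f"c{i:03d}" for i in range(n_clusters)]
    fingerprints = FingerprintTable(
        counts=pd.DataFrame(fp_counts, index=ids, columns=cols),
        relative=pd.DataFrame(fp_rel, index=ids, columns=cols),
        clr_values=pd.DataFrame(_clr(fp_rel), index=ids, columns=cols),
    )

    taxa_comp = np.column_stack([abundance, 1.0 - abundance])
    seq = np.array([rng.multinomial(seq_depth, p) for p in taxa_comp])
    table = rescale_counts(
        pd.DataFrame(seq, index=ids, columns=["focal", "background"])
    )
    dens = DensitySeries(
        pd.Series(np.exp(rng.normal(math.log(1e6), 0.3, size=n_samples)), index=ids)
    )
    return PairedDataset(fingerprints, table, dens, None), "focal"


def write_dataset(dataset: SimulatedDataset, directory: str | os.PathLike) -> None:
    """Write FCS files (raw intensities), count/density tables, manifest."""
    directory = os.fspath(directory)
    fcs_dir = os.path.join(directory, "fcs")
    os.makedirs(fcs_dir, exist_ok=True)
    for ev in dataset.events:
        raw = EventMatrix(ev.sample_id, list(ev.channels), np.sinh(ev.values))
        write_fcs(os.path.join(fcs_dir, f"{ev.sample_id}.fcs"), raw)
    dataset.raw_counts.to_csv(
        os.path.join(directory, "taxon_counts.tsv"), sep="\t", index_label="sample_id"
    )
    dataset.densities.density.to_frame("cells_per_ml").to_csv(
        os.path.join(directory, "densities.tsv"), sep="\t", index_label="sample_id"
    )
    dataset.true_relative.to_csv(
        os.path.join(directory, "true_relative.tsv"), sep="\t", index_label="sample_id"
    )
    manifest = {
        "groups": dataset.groups,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(dataset.config).items()
        },
        "signature_means": {
            sig.taxon_id: [list(map(float, c[0])) for c in sig.components]
            for sig in dataset.signatures
        },
    }
    with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
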