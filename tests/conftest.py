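"""Shared fixtures.

The heavy end-to-end analyses (mock-community nested CV, superimposition
stress regime, importance localization, learning curves) are
session-scoped so the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cytotax as ct


@pytest.fixture(scope="session")
def mock3_pipeline():
    """Simulated 3-strain mock community pushed through the full preprocessing."""
    cfg = ct.mock3_scenario()
    ds = ct.simulate_dataset(cfg)
    mask, norm_constant, table = ct.fingerprint_samples(
        ds.events,
        ct.default_gate(),
        k_grid=range(1, 9),
        n_per_sample=2000,
        seed=cfg.seed,
    )
    taxa = ct.detection_filter(ct.rescale_counts(ds.raw_counts), ds.densities)
    paired = ct.PairedDataset(table, taxa, ds.densities, ds.groups)
    return {
        "sim": ds,
        "mask": mask,
        "norm_constant": norm_constant,
        "fingerprints": table,
        "taxa": taxa,
        "dataset": paired,
    }


@pytest.fixture(scope="session")
def mock3_reports(mock3_pipeline):
    """Nested-CV metric reports for every mock-community taxon."""
    dataset = mock3_pipeline["dataset"]
    return {
        taxon: ct.nested_cv(dataset, taxon, ct.CVScheme(seed=0))
        for taxon in mock3_pipeline["taxa"].taxon_ids
    }


@pytest.fixture(scope="session")
def stress_report():
    """Nested CV on the bloomer regime built to flood raw regression FPs."""
    dataset, taxon = ct.hurdle_stress_dataset(seed=0)
    return ct.nested_cv(dataset, taxon, ct.CVScheme(seed=0))


@pytest.fixture(scope="session")
def localization_result():
    """Ten separable taxa: trained models vs their generating regions."""
    cfg = ct.ScenarioConfig(
        n_taxa=10,
        n_samples=120,
        n_groups=5,
        events_per_sample=3000,
        separation=6.0,
        zero_inflation=0.3,
        seed=0,
    )
    ds = ct.simulate_dataset(cfg)
    mask, norm_constant, table = ct.fingerprint_samples(
        ds.events, ct.default_gate(), k_grid=(8, 12, 16, 24), n_per_sample=1000, seed=0
    )
    taxa = ct.detection_filter(ct.rescale_counts(ds.raw_counts), ds.densities)
    paired = ct.PairedDataset(table, taxa, ds.densities, ds.groups)
    models = ct.train_full_models(paired, params=ct.ModelParams(n_trees=200), seed=0)
    regions = ct.truth_regions(mask, ds.signatures, norm_constant, seed=0)
    return ct.importance_localization(list(models.values()), mask, regions)


@pytest.fixture(scope="session")
def mock3_learning_curves(mock3_pipeline):
    """Accuracy/R2 at 20% vs 80% of the mock dataset, 5 subsample repeats."""
    return ct.learning_curve(
        mock3_pipeline["dataset"],
        "taxon_00",
        fractions=(0.2, 0.8),
        repeats=5,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
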