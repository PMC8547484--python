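"""Validation machinery: nested cross-validation, metrics, learning curves.

The outer loop holds out 20% of the samples (stratified by presence
label) for validation and is repeated three times with different
splits; all tuning happens in the inner 5-fold loop, and in-silico
augmentation is performed strictly inside each outer training fold so
no validation information leaks into training.  Metrics are reported
both for the raw regression output and after classifier
superimposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .augment import audit_provenance, combine_samples
from .fingerprint import FingerprintTable, GMMMask
from .models import (
    ModelParams,
    TaxonModel,
    compute_zero_replacement,
    predict_taxon,
    train_taxon_model,
)
from .taxa import DensitySeries, TaxonTable, presence_labels

logger = logging.getLogger(__name__)

__all__ = [
    "PairedDataset",
    "CVScheme",
    "MetricReport",
    "nested_cv",
    "group_holdout_eval",
    "learning_curve",
    "importance_localization",
]


@dataclass
class PairedDataset:
    """Aligned fingerprints, taxon table, densities and optional tank map."""

    fingerprints: FingerprintTable
    taxa: TaxonTable
    densities: DensitySeries | None = None
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.fingerprints.sample_ids != self.taxa.sample_ids:
            raise ValueError("fingerprint and taxon-table sample ids do not align")

    @property
    def sample_ids(self) -> list[str]:
        return self.fingerprints.sample_ids

    def subset(self, sample_ids: list[str]) -> "PairedDataset":
        ids = list(sample_ids)
        fp = FingerprintTable(
            counts=self.fingerprints.counts.loc[ids],
            relative=self.fingerprints.relative.loc[ids],
            clr_values=self.fingerprints.clr_values.loc[ids],
        )
        tx = TaxonTable(
            counts=self.taxa.counts.loc[ids],
            relative=self.taxa.relative.loc[ids],
            taxonomy=dict(self.taxa.taxonomy),
        )
        dens = (
            DensitySeries(self.densities.density.loc[ids])
            if self.densities is not None
            else None
        )
        groups = {s: self.groups[s] for s in ids} if self.groups else None
        return PairedDataset(fp, tx, dens, groups)


@dataclass
class CVScheme:
    """Outer 20% holdout repeated 3x; inner 5-fold tuning."""

    outer_fraction: float = 0.2
    outer_repeats: int = 3
    inner_folds: int = 5
    seed: int = 0
    grouping: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.outer_fraction < 1:
            raise ValueError("outer_fraction must be in (0, 1)")


@dataclass
class MetricReport:
    """Per-repeat and aggregate validation metrics for one taxon.

    Accuracy in percent; MAE in percentage points of relative abundance;
    false-positive/negative counts normalized per 100 validation samples
    at the 1% presence criterion.  R^2 is 1 - SS_res/SS_tot on the
    validation data, floored at 0 for reporting.
    """

    taxon_id: str
    repeats: list[dict] = field(default_factory=list)

    _KEYS = (
        "accuracy", "auc", "r2_raw", "r2", "mae_raw", "mae",
        "fp_raw_per100", "fp_per100", "fn_raw_per100", "fn_per100",
    )

    def mean(self, key: str) -> float:
        vals = [r[key] for r in self.repeats if np.isfinite(r.get(key, np.nan))]
        return float(np.mean(vals)) if vals else float("nan")

    def sd(self, key: str) -> float:
        vals = [r[key] for r in self.repeats if np.isfinite(r.get(key, np.nan))]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict:
        return {
            key: {"mean": self.mean(key), "sd": self.sd(key)} for key in self._KEYS
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.repeats)


def _floor_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return max(r2, 0.0)


def compute_metrics(
    true_rel: np.ndarray,
    predictions: pd.DataFrame,
    presence_cutoff: float,
) -> dict:
    """Classification + regression metrics against the true abundances."""
    y_true = true_rel >= presence_cutoff
    presence = predictions["presence"].to_numpy()
    prob = predictions["presence_prob"].to_numpy()
    rel_raw = predictions["rel_raw"].to_numpy()
    rel = predictions["rel_abundance"].to_numpy()
    n = len(y_true)

    accuracy = 100.0 * float(np.mean(presence == y_true))
    if len(np.unique(y_true)) < 2:
        logger.warning("validation fold has a single presence class; AUC undefined")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, prob))

    pred_pos_raw = rel_raw >= presence_cutoff
    pred_pos = rel >= presence_cutoff
    per100 = 100.0 / n
    return {
        "n_validation": n,
        "accuracy": accuracy,
        "auc": auc,
        "r2_raw": _floor_r2(true_rel, rel_raw),
        "r2": _floor_r2(true_rel, rel),
        "mae_raw": 100.0 * float(np.mean(np.abs(true_rel - rel_raw))),
        "mae": 100.0 * float(np.mean(np.abs(true_rel - rel))),
        "fp_raw_per100": per100 * float(np.sum(pred_pos_raw & ~y_true)),
        "fp_per100": per100 * float(np.sum(pred_pos & ~y_true)),
        "fn_raw_per100": per100 * float(np.sum(~pred_pos_raw & y_true)),
        "fn_per100": per100 * float(np.sum(~pred_pos & y_true)),
    }


def _run_split(
    dataset: PairedDataset,
    taxon_id: str,
    train_ids: list[str],
    val_ids: list[str],
    params: ModelParams,
    seed: int,
    augment_n: int | None,
) -> tuple[dict, TaxonModel]:
    rel = dataset.taxa.relative[taxon_id]
    dens_train = (
        DensitySeries(dataset.densities.density.loc[train_ids])
        if dataset.densities is not None
        else None
    )
    augmented = combine_samples(
        dataset.fingerprints.relative.loc[train_ids],
        rel.loc[train_ids],
        dens_train,
        n_new=augment_n,
        seed=seed,
    )
    audit_provenance(augmented, val_ids)
    model = train_taxon_model(
        augmented.features,
        augmented.targets,
        taxon_id,
        params,
        seed,
        zero_replacement=compute_zero_replacement(rel.loc[train_ids].to_numpy()),
    )
    preds = predict_taxon(model, dataset.fingerprints.clr_values.loc[val_ids])
    metrics = compute_metrics(
        rel.loc[val_ids].to_numpy(), preds, params.presence_cutoff
    )
    metrics["train_ids"] = list(train_ids)
    metrics["val_ids"] = list(val_ids)
    metrics["n_synthetic"] = augmented.n_synthetic
    metrics["provenance_sources"] = sorted(
        {s for p in augmented.provenance for s in p["sources"]}
    )
    return metrics, model


def nested_cv(
    dataset: PairedDataset,
    taxon_id: str,
    scheme: CVScheme | None = None,
    params: ModelParams | None = None,
    augment_n: int | None = None,
) -> MetricReport:
    """Repeated stratified outer holdout around the full training pipeline.

    Each repeat: split 80/20 stratified by the presence label, augment the
    training fold, select features, tune and train both stages by inner
    CV, predict the untouched validation fold.
    """
    scheme = scheme or CVScheme()
    params = params or ModelParams()
    params.inner_folds = scheme.inner_folds
    y_all = presence_labels(dataset.taxa, taxon_id, params.presence_cutoff)
    if y_all.nunique() < 2:
        raise ValueError(
            f"taxon {taxon_id!r} is never/always present at the cutoff; "
            "nested CV needs both classes"
        )
    ids = np.array(dataset.sample_ids)
    splitter = StratifiedShuffleSplit(
        n_splits=scheme.outer_repeats,
        test_size=scheme.outer_fraction,
        random_state=scheme.seed,
    )
    seeds = np.random.SeedSequence(scheme.seed).generate_state(scheme.outer_repeats)
    report = MetricReport(taxon_id=taxon_id)
    for repeat, (tr, va) in enumerate(splitter.split(ids, y_all.to_numpy())):
        metrics, _ = _run_split(
            dataset,
            taxon_id,
            list(ids[tr]),
            list(ids[va]),
            params,
            int(seeds[repeat] % (2 ** 31)),
            augment_n,
        )
        metrics["repeat"] = repeat
        report.repeats.append(metrics)
    return report


def group_holdout_eval(
    dataset: PairedDataset,
    taxon_id: str,
    held_group: str,
    params: ModelParams | None = None,
    seed: int = 0,
    augment_n: int | None = None,
) -> MetricReport:
    """Train on all tanks but one, validate on the held-out tank.

    Contrasting this with a random split measures how much performance
    relies on tank-specific co-occurrence rather than the taxon's own
    cytometric signal.
    """
    if not dataset.groups:
        raise ValueError("dataset has no group (tank) mapping")
    groups = set(dataset.groups.values())
    if held_group not in groups:
        raise KeyError(f"unknown group {held_group!r}; available: {sorted(groups)}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a holdout")
    val_ids = [s for s in dataset.sample_ids if dataset.groups[s] == held_group]
    train_ids = [s for s in dataset.sample_ids if dataset.groups[s] != held_group]
    params = params or ModelParams()
    metrics, _ = _run_split(dataset, taxon_id, train_ids, val_ids, params, seed, augment_n)
    metrics["repeat"] = 0
    metrics["held_group"] = held_group
    report = MetricReport(taxon_id=taxon_id)
    report.repeats.append(metrics)
    return report


def learning_curve(
    dataset: PairedDataset,
    taxon_id: str,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    repeats: int = 5,
    seed: int = 0,
    params: ModelParams | None = None,
    augment_n: int | None = None,
) -> dict[float, MetricReport]:
    """Performance as a function of dataset size.

    For each fraction, subsample that share of the samples (stratified
    by presence, without replacement) and run a single-repeat nested CV;
    repeat with different subsamples and aggregate.
    """
    y_all = presence_labels(dataset.taxa, taxon_id)
    ids = np.array(dataset.sample_ids)
    rng = np.random.default_rng(seed)
    out: dict[float, MetricReport] = {}
    for frac in fractions:
        report = MetricReport(taxon_id=taxon_id)
        for rep in range(repeats):
            n_sub = int(round(frac * len(ids)))
            sub_seed = int(rng.integers(2 ** 31))
            try:
                splitter = StratifiedShuffleSplit(
                    n_splits=1, train_size=n_sub, random_state=sub_seed
                )
                (sub_idx, _), = splitter.split(ids, y_all.to_numpy())
                sub = dataset.subset(list(ids[np.sort(sub_idx)]))
                rep_report = nested_cv(
                    sub,
                    taxon_id,
                    CVScheme(outer_repeats=1, seed=sub_seed),
                    params=params,
                    augment_n=augment_n,
                )
            except ValueError as exc:
                logger.warning(
                    "fraction %.2f repeat %d skipped: %s", frac, rep, exc
                )
                continue
            for m in rep_report.repeats:
                m["repeat"] = rep
                report.repeats.append(m)
        if report.repeats:
            out[frac] = report
    return out


def train_full_models(
    dataset: PairedDataset,
    taxon_ids: list[str] | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
    augment_n: int | None = None,
) -> dict[str, TaxonModel]:
    """Final deployment models: augment the whole dataset and train per taxon.

    Taxa that are never or always present at the cutoff are skipped with
    a warning (they have no two-class training signal).
    """
    params = params or ModelParams()
    taxon_ids = taxon_ids or dataset.taxa.taxon_ids
    seeds = np.random.SeedSequence(seed).generate_state(len(taxon_ids))
    models: dict[str, TaxonModel] = {}
    for taxon_id, tseed in zip(taxon_ids, seeds):
        labels = presence_labels(dataset.taxa, taxon_id, params.presence_cutoff)
        if labels.nunique() < 2:
            logger.warning(
                "skipping %s: never/always present at the %g cutoff",
                taxon_id, params.presence_cutoff,
            )
            continue
        augmented = combine_samples(
            dataset.fingerprints.relative,
            dataset.taxa.relative[taxon_id],
            dataset.densities,
            n_new=augment_n,
            seed=int(tseed % (2 ** 31)),
        )
        models[taxon_id] = train_taxon_model(
            augmented.features,
            augmented.targets,
            taxon_id,
            params,
            int(tseed % (2 ** 31)),
            zero_replacement=compute_zero_replacement(
                dataset.taxa.relative[taxon_id].to_numpy()
            ),
        )
    return models


def importance_localization(
    models: list[TaxonModel],
    mask: GMMMask,
    truth_regions: dict[str, set[str]],
) -> dict:
    """Does each taxon's top-importance cluster fall in its true region?

    The top cluster is the argmax of the mean normalized importance
    across the three submodels.  Returns per-taxon hits and the overall
    hit rate.
    """
    hits = {}
    top = {}
    for model in models:
        region = truth_regions.get(model.taxon_id)
        if not region:
            raise ValueError(f"empty truth region for taxon {model.taxon_id!r}")
        agg = pd.DataFrame(model.importances).mean(axis=1)
        top_cluster = agg.idxmax()
        top[model.taxon_id] = top_cluster
        hits[model.taxon_id] = top_cluster in region
    return {
        "hits": hits,
        "top_cluster": top,
        "hit_rate": float(np.mean(list(hits.values()))) if hits else float("nan"),
    }
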