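"""Per-taxon hurdle-style predictor on cytometric fingerprints.

For each taxon two models are trained on the clr fingerprint features:

* a random-forest presence/absence classifier (present = relative
  abundance >= 1%), preceded by recursive feature elimination so the
  classifier leans on the clusters genuinely associated with the taxon
  rather than correlated bystander clusters;
* a regression ensemble for relative abundance — a gradient-boosting
  regressor and a polynomial-kernel support-vector regressor combined by
  a linear stack fitted on out-of-fold base predictions.  Targets are
  logit-transformed (zeros first replaced by one-tenth of the smallest
  nonzero training abundance) so the inverse transform bounds
  predictions to [0, 1].  The regression uses the full cluster
  fingerprint: a single cluster's clr value is confounded by the rest of
  the composition (the geometric-mean denominator), so restricting the
  regressor to the classifier's selected clusters degrades it badly.

The final prediction superimposes the classifier on the regression:
wherever the classifier says "absent" the predicted abundance is zeroed;
elsewhere the regression output stands.  This trades a small increase in
false negatives for a large reduction in false positives.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit as _logit
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
    cross_val_predict,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from statsmodels.nonparametric.smoothers_lowess import lowess

from .taxa import PRESENCE_CUTOFF

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "TaxonModel",
    "StackedRegressor",
    "select_features",
    "train_classifier",
    "train_regressor",
    "train_taxon_model",
    "predict_taxon",
    "feature_importance",
    "compute_zero_replacement",
    "logit_forward",
    "logit_inverse",
    "save_model",
    "load_model",
]


@dataclass
class ModelParams:
    """Hyperparameters of the per-taxon pipeline.

    Defaults are sized for datasets of a few hundred samples and a few
    dozen fingerprint clusters.  ``rfe_trees`` keeps the 25-iteration
    elimination profile cheap; the final classifier uses ``n_trees``.
    """

    n_trees: int = 500
    rfe_trees: int = 100
    rfe_iterations: int = 25
    rfe_tolerance: float = 0.5          # percentage points off max accuracy
    decision_threshold: float = 0.5
    presence_cutoff: float = PRESENCE_CUTOFF
    inner_folds: int = 5
    rf_grid: dict = field(
        default_factory=lambda: {"max_features": ["sqrt", None]}
    )
    gbr_grid: dict = field(
        default_factory=lambda: {"max_depth": [2, 3], "learning_rate": [0.05, 0.1]}
    )
    gbr_trees: int = 200
    svr_grid: dict = field(
        default_factory=lambda: {"svr__C": [0.1, 1.0, 10.0], "svr__degree": [2, 3]}
    )
    importance_shuffles: int = 5


@dataclass
class StackedRegressor:
    """Linear combination of base regressors, weights fit on out-of-fold preds."""

    bases: dict
    combiner: LinearRegression

    def predict(self, X: np.ndarray) -> np.ndarray:
        cols = np.column_stack([m.predict(X) for m in self.bases.values()])
        return self.combiner.predict(cols)


@dataclass
class TaxonModel:
    """Everything needed to predict one taxon from fingerprints."""

    taxon_id: str
    classifier: RandomForestClassifier
    selected_features: list[str]
    all_features: list[str]
    regressor: StackedRegressor
    zero_replacement: float
    decision_threshold: float
    seed: int
    norm_constant: float | None = None
    mask_ref: str | None = None
    importances: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Transforms


def compute_zero_replacement(targets: np.ndarray) -> float:
    """One-tenth of the smallest nonzero training abundance."""
    t = np.asarray(targets, dtype=float)
    nonzero = t[t > 0]
    if nonzero.size == 0:
        raise ValueError("all training abundances are zero")
    return float(nonzero.min() / 10.0)


def logit_forward(targets: np.ndarray, zero_replacement: float) -> np.ndarray:
    """ln(x / (1 - x)) with zeros replaced by *zero_replacement*."""
    t = np.asarray(targets, dtype=float)
    if np.any(t >= 1.0):
        raise ValueError("relative abundances must be < 1 for the logit transform")
    if np.any(t < 0):
        raise ValueError("relative abundances must be >= 0")
    if not 0 < zero_replacement < 1:
        raise ValueError("zero_replacement must be in (0, 1)")
    return _logit(np.where(t == 0, zero_replacement, t))


def logit_inverse(values: np.ndarray) -> np.ndarray:
    """expit; maps any real prediction back into (0, 1)."""
    return expit(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Feature selection


def _ranked_features(X: pd.DataFrame, y: np.ndarray, n_trees: int, seed: int) -> list[str]:
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y)
    imp = rf.feature_importances_
    # descending importance; ties broken by cluster id for determinism
    order = sorted(range(len(imp)), key=lambda j: (-imp[j], X.columns[j]))
    return [X.columns[j] for j in order]


def _subset_sizes(n_features: int) -> list[int]:
    sizes = []
    s = 1
    while s < n_features:
        sizes.append(s)
        s *= 2
    sizes.append(n_features)
    return sizes


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    params: ModelParams | None = None,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination with an accuracy-tolerance pick.

    Over ``rfe_iterations`` stratified 75/25 resamples: rank features by
    forest importance on the training part, evaluate nested subsets of
    increasing size on the held-out part, average the accuracy profile,
    and keep the smallest subset whose mean accuracy is within
    ``rfe_tolerance`` percentage points of the profile maximum.  The
    returned features come from a final ranking on all data.
    """
    params = params or ModelParams()
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            "taxon is never/always present at the cutoff in the training data; "
            "cannot select features for a single-class problem"
        )
    if X.shape[1] < 2:
        return list(X.columns)

    sizes = _subset_sizes(X.shape[1])
    splitter = StratifiedShuffleSplit(
        n_splits=params.rfe_iterations, test_size=0.25, random_state=seed
    )
    acc = np.zeros((params.rfe_iterations, len(sizes)))
    Xv = X.to_numpy()
    for it, (tr, te) in enumerate(splitter.split(Xv, y)):
        ranking = _ranked_features(X.iloc[tr], y[tr], params.rfe_trees, seed + it)
        for si, s in enumerate(sizes):
            cols = [X.columns.get_loc(f) for f in ranking[:s]]
            rf = RandomForestClassifier(
                n_estimators=params.rfe_trees, random_state=seed + it, n_jobs=1
            )
            rf.fit(Xv[np.ix_(tr, cols)], y[tr])
            acc[it, si] = rf.score(Xv[np.ix_(te, cols)], y[te])

    profile = acc.mean(axis=0) * 100.0
    best = profile.max()
    chosen = next(s for s, a in zip(sizes, profile) if a >= best - params.rfe_tolerance)
    final_ranking = _ranked_features(X, y, params.rfe_trees, seed)
    selected = final_ranking[:chosen]
    logger.info(
        "rfe: accuracy profile %s over sizes %s -> %d features",
        np.round(profile, 2).tolist(), sizes, chosen,
    )
    return selected


# ---------------------------------------------------------------------------
# Training


def _inner_cv(y: np.ndarray | None, folds: int, seed: int):
    if y is not None:
        counts = np.bincount(y.astype(int))
        k = min(folds, counts.min()) if counts.min() >= 2 else 2
        return StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=seed)
    return KFold(n_splits=folds, shuffle=True, random_state=seed)


def train_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    params: ModelParams | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Random forest tuned by inner stratified CV over a small grid."""
    params = params or ModelParams()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("cannot train a classifier on a single-class target")
    rf = RandomForestClassifier(n_estimators=params.n_trees, random_state=seed, n_jobs=1)
    search = GridSearchCV(
        rf,
        params.rf_grid,
        cv=_inner_cv(y, params.inner_folds, seed),
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X.to_numpy(), y)
    return search.best_estimator_


def train_regressor(
    X: pd.DataFrame,
    t_logit: np.ndarray,
    params: ModelParams | None = None,
    seed: int = 0,
) -> StackedRegressor:
    """Gradient boosting + polynomial SVR, linearly stacked.

    Each base learner is tuned by inner k-fold CV; the linear combiner
    is then fit on out-of-fold predictions of the tuned bases so the
    stack weights are not estimated on resubstitution predictions.
    """
    params = params or ModelParams()
    t = np.asarray(t_logit, dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("constant regression target")
    Xv = X.to_numpy()
    cv = KFold(n_splits=params.inner_folds, shuffle=True, random_state=seed)

    gbr = GradientBoostingRegressor(n_estimators=params.gbr_trees, random_state=seed)
    gbr_search = GridSearchCV(
        gbr, params.gbr_grid, cv=cv, scoring="neg_mean_squared_error", n_jobs=1
    )
    gbr_search.fit(Xv, t)

    svr = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="poly"))])
    svr_search = GridSearchCV(
        svr, params.svr_grid, cv=cv, scoring="neg_mean_squared_error", n_jobs=1
    )
    svr_search.fit(Xv, t)

    oof = np.column_stack(
        [
            cross_val_predict(clone(gbr_search.best_estimator_), Xv, t, cv=cv, n_jobs=1),
            cross_val_predict(clone(svr_search.best_estimator_), Xv, t, cv=cv, n_jobs=1),
        ]
    )
    combiner = LinearRegression().fit(oof, t)
    return StackedRegressor(
        bases={"gbm": gbr_search.best_estimator_, "svr": svr_search.best_estimator_},
        combiner=combiner,
    )


def train_taxon_model(
    X: pd.DataFrame,
    taxon_rel: np.ndarray,
    taxon_id: str = "taxon",
    params: ModelParams | None = None,
    seed: int = 0,
    norm_constant: float | None = None,
    mask_ref: str | None = None,
    zero_replacement: float | None = None,
) -> TaxonModel:
    """Full per-taxon training: select features, fit both stages, importances.

    ``X`` is the clr fingerprint matrix of the training fold (possibly
    augmented); ``taxon_rel`` the matching relative abundances.  The
    classifier sees only the RFE-selected clusters; the regression
    ensemble sees the full fingerprint and is trained on all rows,
    absent samples entering at their replaced-zero value.

    ``zero_replacement`` should be one-tenth of the smallest nonzero
    *measured* training abundance.  Pass it explicitly when ``X``
    contains augmented rows: synthetic convex combinations can carry
    arbitrarily small nonzero targets (a mixing-weight artifact), which
    would otherwise drag the replacement constant toward zero.
    """
    params = params or ModelParams()
    t = np.asarray(taxon_rel, dtype=float)
    y = t >= params.presence_cutoff
    selected = select_features(X, y, params, seed)
    classifier = train_classifier(X[selected], y, params, seed)
    if zero_replacement is None:
        zero_replacement = compute_zero_replacement(t)
    # mono-dominant samples (abundance exactly 1, e.g. pure strains) would
    # make the logit infinite; mirror the zero replacement at the top end
    t_logit = logit_forward(np.minimum(t, 1.0 - zero_replacement), zero_replacement)
    regressor = train_regressor(X, t_logit, params, seed)
    model = TaxonModel(
        taxon_id=taxon_id,
        classifier=classifier,
        selected_features=selected,
        all_features=list(X.columns),
        regressor=regressor,
        zero_replacement=zero_replacement,
        decision_threshold=params.decision_threshold,
        seed=seed,
        norm_constant=norm_constant,
        mask_ref=mask_ref,
    )
    model.importances = _compute_importances(model, X, y, t_logit, params, seed)
    return model


# ---------------------------------------------------------------------------
# Prediction


def _presence_prob(classifier: RandomForestClassifier, Xv: np.ndarray) -> np.ndarray:
    proba = classifier.predict_proba(Xv)
    idx = list(classifier.classes_).index(True)
    return proba[:, idx]


def predict_taxon(
    model: TaxonModel,
    X: pd.DataFrame,
    densities=None,
) -> pd.DataFrame:
    """Predict presence and abundance; superimpose the classifier.

    Returns a frame indexed by sample with columns ``presence_prob``,
    ``presence``, ``rel_raw`` (regression output before superimposition),
    ``rel_abundance`` and, when *densities* is given, ``abs_abundance``
    in cells/ml.
    """
    missing = [f for f in model.all_features if f not in X.columns]
    if missing:
        raise ValueError(
            f"feature mismatch with the model's mask: missing {missing}"
        )
    prob = _presence_prob(model.classifier, X[model.selected_features].to_numpy())
    presence = prob >= model.decision_threshold
    rel_raw = logit_inverse(model.regressor.predict(X[model.all_features].to_numpy()))
    rel = np.where(presence, rel_raw, 0.0)
    out = pd.DataFrame(
        {
            "presence_prob": prob,
            "presence": presence,
            "rel_raw": rel_raw,
            "rel_abundance": rel,
        },
        index=X.index,
    )
    if densities is not None:
        out["abs_abundance"] = rel * densities.aligned_to(list(X.index))
    return out


# ---------------------------------------------------------------------------
# Feature importance


def _permutation_importance(estimator, Xv, y, kind, n_shuffles, rng) -> np.ndarray:
    """Mean increase in error when one feature is shuffled, clipped at 0."""
    if kind == "classifier":
        base_err = 1.0 - estimator.score(Xv, y)
    else:
        base_err = float(np.mean((estimator.predict(Xv) - y) ** 2))
    out = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        errs = []
        for _ in range(n_shuffles):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            if kind == "classifier":
                errs.append(1.0 - estimator.score(Xp, y))
            else:
                errs.append(float(np.mean((estimator.predict(Xp) - y) ** 2)))
        out[j] = max(float(np.mean(errs)) - base_err, 0.0)
    return out


def _loess_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a loess fit of y on x against the intercept-only model."""
    if np.unique(x).size < 3:
        return 0.0
    fit = lowess(y, x, frac=2.0 / 3.0, return_sorted=False)
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(1.0 - ss_res / ss_tot, 0.0)


def _normalize(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else v


def _compute_importances(
    model: TaxonModel,
    X: pd.DataFrame,
    y: np.ndarray,
    t_logit: np.ndarray,
    params: ModelParams,
    seed: int,
) -> dict:
    rng = np.random.default_rng(seed)
    Xsel = X[model.selected_features].to_numpy()
    Xall = X[model.all_features].to_numpy()
    per_sub = {
        "classifier": (
            model.selected_features,
            _normalize(
                _permutation_importance(
                    model.classifier, Xsel, y, "classifier",
                    params.importance_shuffles, rng,
                )
            ),
        ),
        "gbm": (
            model.all_features,
            _normalize(
                _permutation_importance(
                    model.regressor.bases["gbm"], Xall, t_logit, "regressor",
                    params.importance_shuffles, rng,
                )
            ),
        ),
        "svr": (
            model.all_features,
            _normalize(
                np.array(
                    [_loess_r2(Xall[:, j], t_logit) for j in range(Xall.shape[1])]
                )
            ),
        ),
    }
    out = {}
    for sub, (cols, vals) in per_sub.items():
        full = {f: 0.0 for f in model.all_features}
        full.update({f: float(v) for f, v in zip(cols, vals)})
        out[sub] = full
    return out


def feature_importance(model: TaxonModel) -> dict:
    """Per-cluster importance per submodel, normalized to [0, 1].

    Tree submodels (forest classifier, gradient boosting) use
    permutation importance — the normalized mean increase in error when
    a feature is shuffled.  The support-vector submodel uses the R^2 of
    a per-feature loess fit against the intercept-only null.  Clusters
    the elimination step dropped report exactly 0 in the classifier
    submodel (the regression submodels see the full fingerprint).
    """
    if not model.importances:
        raise ValueError("model has no stored importances; retrain")
    return model.importances


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: TaxonModel, directory: str | os.PathLike) -> None:
    """Bundle = structured-text metadata + binary submodel artifacts."""
    os.makedirs(directory, exist_ok=True)
    meta = {
        "taxon_id": model.taxon_id,
        "selected_features": model.selected_features,
        "all_features": model.all_features,
        "zero_replacement": model.zero_replacement,
        "decision_threshold": model.decision_threshold,
        "seed": model.seed,
        "norm_constant": model.norm_constant,
        "mask_ref": model.mask_ref,
        "importances": {
            sub: {k: float(v) for k, v in vals.items()}
            for sub, vals in model.importances.items()
        },
    }
    with open(os.path.join(directory, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    joblib.dump(
        {"classifier": model.classifier, "regressor": model.regressor},
        os.path.join(directory, "submodels.joblib"),
    )


def load_model(directory: str | os.PathLike) -> TaxonModel:
    with open(os.path.join(directory, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    sub = joblib.load(os.path.join(directory, "submodels.joblib"))
    return TaxonModel(
        taxon_id=meta["taxon_id"],
        classifier=sub["classifier"],
        selected_features=meta["selected_features"],
        all_features=meta["all_features"],
        regressor=sub["regressor"],
        zero_replacement=meta["zero_replacement"],
        decision_threshold=meta["decision_threshold"],
        seed=meta["seed"],
        norm_constant=meta.get("norm_constant"),
        mask_ref=meta.get("mask_ref"),
        importances=meta.get("importances", {}),
    )
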