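"""Multiclass and ordinal localization classifiers over feature vectors.

Two modes share one boosted-tree learner contract (fit / predict_proba /
feature importances; xgboost by default, injectable):

* ``multiclass`` — one softmax learner over the three locations, optionally
  fed SMOTE-balanced training rows (the class ratio is ~1:1:10
  extracellular:periplasmic:cytoplasmic, so the minority classes benefit).
* ``ordinal`` — the locations are ordered cytoplasmic < periplasmic <
  extracellular (a gradient of export), so N classes are decomposed into
  N-1 = 2 binary learners: L1 separates cytoplasmic from exported
  (periplasmic+extracellular) on all rows; L2 separates periplasmic from
  extracellular on the exported subset only.  Because L2 is trained
  conditionally, class probabilities recombine by the chain rule
  (see :func:`combine_ordinal`) and are non-negative by construction.

Predictions below a confidence threshold tau are reported as
"unclassified" rather than forced into a class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .descriptors import N_FEATURES, feature_names

CLASS_NAMES = {1: "cytoplasmic", 2: "periplasmic", 3: "extracellular"}
UNCLASSIFIED = "unclassified"


def _default_learner_factory(params: dict, seed: int):
    from xgboost import XGBClassifier
    return XGBClassifier(
        tree_method="hist", n_jobs=1, random_state=seed, verbosity=0,
        **params)


@dataclass
class ModelConfig:
    """Hyperparameters and training policy."""

    max_depth: int = 6
    learning_rate: float = 0.1
    n_estimators: int = 500
    subsample: float = 1.0
    patience: int = 20          # early-stopping rounds on held-out log-loss
    smote: bool | None = None   # None -> on for multiclass, off for ordinal
    smote_k: int = 5
    tau: float = 0.5
    combination: str = "chain"  # or "frank_hall"
    learner_factory: Callable = field(default=_default_learner_factory,
                                      repr=False, compare=False)

    def learner_params(self, objective_extra: dict) -> dict:
        return {
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "n_estimators": self.n_estimators,
            "subsample": self.subsample,
            **objective_extra,
        }


# Default cross-validation grid (depth x learning rate x subsample).
DEFAULT_GRID = [
    {"max_depth": d, "learning_rate": lr, "subsample": s}
    for d in (4, 6, 8) for lr in (0.05, 0.1, 0.3) for s in (0.8, 1.0)
]


@dataclass
class TrainedModel:
    mode: str                       # "multiclass" | "ordinal"
    learners: list                  # 1 (multiclass) or 2 (ordinal) learners
    n_features: int
    feature_names: list[str]
    tau: float
    combination: str
    manifest: dict

    def __post_init__(self):
        if self.mode == "ordinal" and len(self.learners) != 2:
            raise ValueError("ordinal mode requires exactly 2 binary learners")
        if self.mode == "multiclass" and len(self.learners) != 1:
            raise ValueError("multiclass mode requires exactly 1 learner")


def _check_X(X: np.ndarray, n_features: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != n_features:
        raise ValueError(
            f"feature layout mismatch: got {X.shape[1] if X.ndim == 2 else '?'}"
            f" columns, model expects {n_features}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _early_stop_split(X, y, seed):
    from sklearn.model_selection import train_test_split
    return train_test_split(X, y, test_size=0.1, stratify=y,
                            random_state=seed)


def train_classifier(X: np.ndarray, y: np.ndarray, mode: str = "multiclass",
                     config: ModelConfig | None = None, seed: int = 42,
                     eval_set: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> TrainedModel:
    """Fit a localization classifier.

    ``y`` uses the ordinal codes {1, 2, 3}.  Early stopping monitors
    log-loss on ``eval_set`` when given, else on an internal stratified 10%
    carve-out of the training rows.  SMOTE (when active) is applied to the
    training rows only, never to the early-stopping set.
    """
    if config is None:
        config = ModelConfig()
    X = _check_X(X, np.asarray(X).shape[1])
    y = np.asarray(y, dtype=int)
    missing = {1, 2, 3} - set(np.unique(y))
    if missing:
        raise ValueError(f"training data lacks class(es) {sorted(missing)}")
    use_smote = config.smote if config.smote is not None else (mode == "multiclass")

    if eval_set is None:
        X_tr, X_es, y_tr, y_es = _early_stop_split(X, y, seed)
    else:
        X_tr, y_tr = X, y
        X_es, y_es = np.asarray(eval_set[0], dtype=float), np.asarray(eval_set[1], dtype=int)

    smote_applied = False
    if use_smote:
        from .dataset import smote_oversample
        X_tr, y_tr = smote_oversample(X_tr, y_tr, k=config.smote_k, seed=seed)
        smote_applied = True

    def fit_binary(Xb, yb, Xe, ye, tag):
        params = config.learner_params(
            {"objective": "binary:logistic", "eval_metric": "logloss",
             "early_stopping_rounds": config.patience})
        learner = config.learner_factory(params, seed)
        learner.fit(Xb, yb, eval_set=[(Xe, ye)], verbose=False)
        return learner

    if mode == "multiclass":
        params = config.learner_params(
            {"objective": "multi:softprob", "num_class": 3,
             "eval_metric": "mlogloss",
             "early_stopping_rounds": config.patience})
        learner = config.learner_factory(params, seed)
        learner.fit(X_tr, y_tr - 1, eval_set=[(X_es, y_es - 1)], verbose=False)
        learners = [learner]
    elif mode == "ordinal":
        l1 = fit_binary(X_tr, (y_tr > 1).astype(int),
                        X_es, (y_es > 1).astype(int), "L1")
        sub = y_tr > 1
        sub_es = y_es > 1
        if sub_es.sum() == 0:
            raise ValueError("early-stopping set has no exported proteins for L2")
        l2 = fit_binary(X_tr[sub], (y_tr[sub] == 3).astype(int),
                        X_es[sub_es], (y_es[sub_es] == 3).astype(int), "L2")
        learners = [l1, l2]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    manifest = {
        "mode": mode, "seed": seed, "smote": smote_applied,
        "hyperparameters": {
            "max_depth": config.max_depth,
            "learning_rate": config.learning_rate,
            "n_estimators": config.n_estimators,
            "subsample": config.subsample,
            "patience": config.patience,
        },
        "class_counts": {CLASS_NAMES[c]: int((y == c).sum()) for c in (1, 2, 3)},
        "tau": config.tau, "combination": config.combination,
    }
    n_feat = X.shape[1]
    names = feature_names() if n_feat == N_FEATURES else [
        f"f{i}" for i in range(n_feat)]
    return TrainedModel(mode=mode, learners=learners, n_features=n_feat,
                        feature_names=names, tau=config.tau,
                        combination=config.combination, manifest=manifest)


def combine_ordinal(p1, p2, rule: str = "chain"):
    """Combine the two binary-learner probabilities into class probabilities.

    ``p1`` = P(exported), ``p2`` = P(extracellular | exported).  The chain
    rule gives P_cyto = 1-p1, P_peri = p1*(1-p2), P_extr = p1*p2 — summing
    to 1 and non-negative with no clamping.  The Frank–Hall subtraction
    variant (treating p2 as the unconditional P(extracellular)) is available
    for comparison but can need clipping.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if rule == "chain":
        p_cyto = 1.0 - p1
        p_extr = p1 * p2
        p_peri = p1 * (1.0 - p2)
    elif rule == "frank_hall":
        p_cyto = 1.0 - p1
        p_extr = np.minimum(p1, p2)
        p_peri = np.clip(p1 - p_extr, 0.0, None)
        total = p_cyto + p_peri + p_extr
        p_cyto, p_peri, p_extr = p_cyto / total, p_peri / total, p_extr / total
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return np.stack([p_cyto, p_peri, p_extr], axis=-1)


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """(n, 3) class probabilities in order cyto, peri, extr."""
    X = _check_X(X, model.n_features)
    if model.mode == "multiclass":
        return model.learners[0].predict_proba(X)
    p1 = model.learners[0].predict_proba(X)[:, 1]
    p2 = model.learners[1].predict_proba(X)[:, 1]
    return combine_ordinal(p1, p2, model.combination)


def predict_with_threshold(model: TrainedModel, X: np.ndarray,
                           tau: float | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Class calls and probabilities; the call is the argmax class when its
    probability reaches tau, else "unclassified"."""
    if tau is None:
        tau = model.tau
    probs = predict_proba(model, X)
    best = probs.argmax(axis=1)
    calls = np.array([CLASS_NAMES[b + 1] for b in best], dtype=object)
    calls[probs.max(axis=1) < tau] = UNCLASSIFIED
    return calls, probs


def grid_search_cv(X: np.ndarray, y: np.ndarray, grid: list[dict],
                   fold_assignment, mode: str = "multiclass",
                   seed: int = 42, base_config: ModelConfig | None = None
                   ) -> tuple[dict, pd.DataFrame]:
    """Cross-validated grid search scored by k-category MCC.

    Folds come from the homology-aware partitioner, so no grid point is ever
    scored on near-duplicates of its training data.  Ties keep the first
    grid point in declaration order.
    """
    from .evaluate import confusion_and_prf, mcc_gorodkin

    if not grid:
        raise ValueError("empty hyperparameter grid")
    if base_config is None:
        base_config = ModelConfig()
    y = np.asarray(y, dtype=int)
    ids_order = list(fold_assignment.folds)
    fold_of = np.array([fold_assignment.folds[i] for i in ids_order])
    if len(fold_of) != len(y):
        raise ValueError("fold assignment does not cover the data")
    rows = []
    for gi, point in enumerate(grid):
        scores = []
        for f in range(fold_assignment.n_folds):
            tr, va = fold_of != f, fold_of == f
            if len(np.unique(y[tr])) < 3 or va.sum() == 0:
                continue
            cfg = ModelConfig(**{**_config_dict(base_config), **point})
            m = train_classifier(X[tr], y[tr], mode=mode, config=cfg,
                                 seed=seed)
            calls, _ = predict_with_threshold(m, X[va], tau=0.0)
            truth = np.array([CLASS_NAMES[c] for c in y[va]])
            cm, _ = confusion_and_prf(truth, calls)
            scores.append(mcc_gorodkin(cm.counts))
        rows.append({"grid_index": gi, **point,
                     "mean_mcc": float(np.mean(scores)),
                     "n_folds": len(scores)})
    table = pd.DataFrame(rows)
    best = int(table["mean_mcc"].idxmax())  # idxmax keeps first on ties
    return grid[best], table


def _config_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d.pop("learner_factory", None)
    return d


# ---------------------------------------------------------------------------
# Persistence

def save_model(model: TrainedModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, learner in enumerate(model.learners):
        fname = f"learner_{i}.json"
        # persist at booster level: robust to sklearn-wrapper API drift
        learner.get_booster().save_model(outdir / fname)
        files.append(fname)
    meta = {
        "mode": model.mode, "n_features": model.n_features,
        "tau": model.tau, "combination": model.combination,
        "learner_files": files, "manifest": model.manifest,
        "feature_names": model.feature_names,
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(outdir: str | Path) -> TrainedModel:
    import xgboost
    from xgboost import XGBClassifier
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    learners = []
    for i, fname in enumerate(meta["learner_files"]):
        if meta["mode"] == "multiclass":
            learner = XGBClassifier(objective="multi:softprob", num_class=3)
            learner.n_classes_ = 3
        else:
            learner = XGBClassifier(objective="binary:logistic")
            learner.n_classes_ = 2
        booster = xgboost.Booster()
        booster.load_model(outdir / fname)
        learner._Booster = booster
        learners.append(learner)
    return TrainedModel(mode=meta["mode"], learners=learners,
                        n_features=meta["n_features"],
                        feature_names=meta["feature_names"],
                        tau=meta["tau"], combination=meta["combination"],
                        manifest=meta["manifest"])
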