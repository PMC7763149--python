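"""Training protocol: event-level split, minority up-sampling, repeated
cross-validated tuning, and an eight-way classifier comparison.

The unit of the train/test split is the behaviour *event*, not the
epoch: all epochs of one event land on the same side, so temporally
adjacent (highly correlated) windows can never straddle the split.
Class imbalance is handled by up-sampling minority classes with
replacement to the majority count — inside each cross-validation
training fold (so duplicated rows never straddle a fold boundary) and
once more on the full training set for the final refit.  The held-out
test events are never resampled.

Eight classifier types are compared: a single classification tree
(CART), five ensemble learners (RF, SVM with an RBF kernel, XGB, a
boosted-trees stand-in for C5.0, stochastic GBM) and two neural
networks (a single-hidden-layer perceptron and an average of five such
networks).  C5.0 has no canonical implementation in this ecosystem; the
registry maps it to a histogram-boosted-trees configuration and flags
the result ``approximate`` in every report.  Hyperparameters are tuned
by grid search scored by mean cross-validation accuracy (Cohen's kappa
is reported alongside); features are standardised (training-set
mean/SD) for the SVM and the neural networks only.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (GradientBoostingClassifier,
                              HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .epochs import FEATURE_NAMES
from .metrics import ConfusionMatrix, class_metrics

logger = logging.getLogger(__name__)

MODEL_NAMES = ("CART", "RF", "SVM", "XGB", "C50", "GBM", "NNET", "AVNNET")

EVENT_KEY = ("session", "event_id")


# ---------------------------------------------------------------------------
# splitting and resampling

@dataclass(frozen=True)
class SplitConfig:
    """Event-level stratified train/test split settings."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def _event_keys(table: pd.DataFrame) -> pd.Series:
    cols = [c for c in EVENT_KEY if c in table.columns]
    if not cols:
        raise ValueError("table must carry an event_id column")
    if len(cols) == 1:
        return table[cols[0]].astype(str)
    return table[cols[0]].astype(str) + ":" + table[cols[1]].astype(str)


def split_events(table: pd.DataFrame, config: SplitConfig = SplitConfig(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition whole events into train and test tables, stratified by label.

    Per class, the event count splits as close to the configured
    fraction as integer rounding allows, with at least one event on
    each side whenever the class has two or more; a single-event class
    goes entirely to train (with a warning).
    """
    keys = _event_keys(table)
    rng = np.random.default_rng(config.seed)
    event_label = (pd.DataFrame({"key": keys, "label": table["label"]})
                   .drop_duplicates("key"))
    train_keys: set[str] = set()
    for label in sorted(event_label["label"].unique()):
        ev = sorted(event_label.loc[event_label["label"] == label, "key"])
        if len(ev) < 2:
            logger.warning("class %r has %d event(s); placing it entirely in train",
                           label, len(ev))
            train_keys.update(ev)
            continue
        n_train = int(np.clip(round(config.train_fraction * len(ev)), 1, len(ev) - 1))
        order = rng.permutation(len(ev))
        train_keys.update(ev[i] for i in order[:n_train])
    in_train = keys.isin(train_keys)
    return (table[in_train].reset_index(drop=True),
            table[~in_train].reset_index(drop=True))


def upsample_minority(table: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Up-sample every minority class with replacement to the majority count.

    All original rows are retained; added rows are exact duplicates of
    rows of the same class.
    """
    counts = table["label"].value_counts()
    if len(counts) < 2:
        logger.warning("up-sampling skipped: only %d class present", len(counts))
        return table.copy()
    majority = int(counts.max())
    rng = np.random.default_rng(seed)
    parts = [table]
    for label in sorted(counts.index):
        deficit = majority - int(counts[label])
        if deficit > 0:
            pool = np.flatnonzero((table["label"] == label).to_numpy())
            parts.append(table.iloc[rng.choice(pool, size=deficit, replace=True)])
    return pd.concat(parts, ignore_index=True)


def _upsample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices implementing up-sampling on an integer label vector."""
    labels, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    idx = [np.arange(len(y))]
    for label, c in zip(labels, counts):
        if c < majority:
            pool = np.flatnonzero(y == label)
            idx.append(rng.choice(pool, size=majority - c, replace=True))
    return np.concatenate(idx)


# ---------------------------------------------------------------------------
# the model registry

class AveragedMLP(BaseEstimator, ClassifierMixin):
    """Average of several single-hidden-layer perceptrons.

    The committee members differ only in their initialisation seed; the
    prediction is the class with the highest mean predicted probability.
    """

    def __init__(self, hidden: int = 8, decay: float = 1e-2, n_networks: int = 5,
                 max_iter: int = 200, random_state: int | None = None):
        self.hidden = hidden
        self.decay = decay
        self.n_networks = n_networks
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        base = 0 if self.random_state is None else self.random_state
        self.members_ = []
        for k in range(self.n_networks):
            net = MLPClassifier(hidden_layer_sizes=(self.hidden,), alpha=self.decay,
                                max_iter=self.max_iter, random_state=base + k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                net.fit(X, y)
            self.members_.append(net)
        self.classes_ = self.members_[0].classes_
        return self

    def predict_proba(self, X):
        return np.mean([m.predict_proba(X) for m in self.members_], axis=0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _build_estimator(name: str, params: dict, seed: int):
    if name == "CART":
        return DecisionTreeClassifier(ccp_alpha=params["cp"], random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=params.get("trees", 500),
                                      max_features=params["mtry"],
                                      random_state=seed, n_jobs=1)
    if name == "SVM":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                   random_state=seed)
    if name == "XGB":
        return XGBClassifier(max_depth=params["depth"],
                             learning_rate=params["learning_rate"],
                             n_estimators=params["rounds"],
                             tree_method="hist", random_state=seed,
                             n_jobs=1, verbosity=0)
    if name == "C50":
        return HistGradientBoostingClassifier(max_iter=params["rounds"],
                                              learning_rate=params["learning_rate"],
                                              early_stopping=False,
                                              random_state=seed)
    if name == "GBM":
        return GradientBoostingClassifier(max_depth=params["depth"],
                                          learning_rate=params["learning_rate"],
                                          n_estimators=params["rounds"],
                                          subsample=0.7, random_state=seed)
    if name == "NNET":
        return MLPClassifier(hidden_layer_sizes=(params["size"],),
                             alpha=params["decay"], max_iter=200,
                             random_state=seed)
    if name == "AVNNET":
        return AveragedMLP(hidden=params["size"], decay=params["decay"],
                           n_networks=5, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


_STANDARDIZED = {"SVM", "NNET", "AVNNET"}
_APPROXIMATE = {"C50"}

_DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "CART": {"cp": [0.001, 0.01, 0.05]},
    "RF": {"trees": [500], "mtry": [4, 8, 16, 32]},
    "SVM": {"C": [0.25, 0.5, 1, 2, 4], "gamma_scale": [0.5, 1.0, 2.0]},
    "XGB": {"depth": [2, 4, 6], "learning_rate": [0.05, 0.1, 0.3],
            "rounds": [50, 150]},
    "C50": {"rounds": [50, 150], "learning_rate": [0.1, 0.3]},
    "GBM": {"depth": [2, 4, 6], "learning_rate": [0.05, 0.1, 0.3],
            "rounds": [50, 150]},
    "NNET": {"size": [4, 8, 16], "decay": [1e-4, 1e-2]},
    "AVNNET": {"size": [4, 8, 16], "decay": [1e-4, 1e-2]},
}

#: Reduced tuning profile used by the examples and the bundled
#: demonstration pipeline: one to three configurations per model and a
#: single repeat of 10-fold CV.
_FAST_GRIDS: dict[str, dict[str, list]] = {
    "CART": {"cp": [0.001, 0.01]},
    "RF": {"trees": [300], "mtry": [8]},
    "SVM": {"C": [0.5, 1, 2], "gamma_scale": [1.0]},
    "XGB": {"depth": [3], "learning_rate": [0.1, 0.3], "rounds": [100]},
    "C50": {"rounds": [100], "learning_rate": [0.1]},
    "GBM": {"depth": [2], "learning_rate": [0.1], "rounds": [100]},
    "NNET": {"size": [8], "decay": [1e-2]},
    "AVNNET": {"size": [8], "decay": [1e-2]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier type with its tuning grid and CV protocol."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 10
    cv_repeats: int = 5
    tuning_metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid:
            object.__setattr__(self, "grid", _DEFAULT_GRIDS[self.name])

    @property
    def standardize(self) -> bool:
        return self.name in _STANDARDIZED

    @property
    def approximate(self) -> bool:
        return self.name in _APPROXIMATE


def default_specs(names=MODEL_NAMES) -> list[ModelSpec]:
    """The full documented tuning protocol (10-fold CV × 5 repeats)."""
    return [ModelSpec(name=n) for n in names]


def fast_specs(names=MODEL_NAMES) -> list[ModelSpec]:
    """The reduced demonstration protocol (small grids, 10-fold CV × 1)."""
    return [ModelSpec(name=n, grid=_FAST_GRIDS[n], cv_repeats=1) for n in names]


# ---------------------------------------------------------------------------
# tuning

def _median_gamma(X: np.ndarray, rng: np.random.Generator,
                  max_rows: int = 400) -> float:
    """RBF kernel-width median heuristic, 1 / median squared distance."""
    if len(X) > max_rows:
        X = X[rng.choice(len(X), size=max_rows, replace=False)]
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    med = float(np.median(d2[np.triu_indices(len(X), k=1)]))
    return 1.0 / max(med, 1e-12)


def _expand_grid(spec: ModelSpec, X: np.ndarray,
                 rng: np.random.Generator) -> list[dict]:
    grid = dict(spec.grid)
    if "gamma_scale" in grid:
        Xs = StandardScaler().fit_transform(X)
        g0 = _median_gamma(Xs, rng)
        grid["gamma"] = [s * g0 for s in grid.pop("gamma_scale")]
    keys = sorted(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass
class TunedModel:
    """A grid-search-tuned, refit classifier."""

    spec: ModelSpec
    best_params: dict
    cv_results: pd.DataFrame
    estimator: object
    classes_: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def approximate(self) -> bool:
        return self.spec.approximate

    @property
    def cv_accuracy(self) -> float:
        return float(self.cv_results["mean_accuracy"].max())

    @property
    def cv_kappa(self) -> float:
        best = self.cv_results["mean_accuracy"].idxmax()
        return float(self.cv_results.loc[best, "mean_kappa"])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.feature_names)].to_numpy(float)
        return self.classes_[np.asarray(self.estimator.predict(X), int)]


def tune_and_fit(spec: ModelSpec, train_table: pd.DataFrame, seed: int = 0,
                 feature_names=None) -> TunedModel:
    """Grid-search ``spec`` with repeated stratified CV and refit the winner.

    Within each CV training fold the minority classes are up-sampled to
    the majority count before fitting; validation folds keep their
    natural class balance.  Configurations are scored by mean fold
    accuracy (kappa reported alongside); ties break toward the earliest
    configuration in deterministic grid order.  The winning
    configuration is refit on the up-sampled full training set.
    """
    feature_names = tuple(FEATURE_NAMES if feature_names is None else feature_names)
    X = train_table[list(feature_names)].to_numpy(float)
    classes, y = np.unique(train_table["label"].to_numpy(), return_inverse=True)
    counts = np.bincount(y)
    thin = counts < spec.cv_folds
    if np.any(thin):
        raise ValueError(
            f"stratified {spec.cv_folds}-fold CV impossible: class(es) "
            f"{[str(c) for c in classes[thin]]} have fewer rows than folds")

    ss = np.random.SeedSequence(seed)
    fold_seed, upsample_ss, gamma_ss, fit_ss = ss.spawn(4)
    splitter = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats,
        random_state=int(fold_seed.generate_state(1)[0] % (2**31)))
    folds = list(splitter.split(X, y))
    up_rng = np.random.default_rng(upsample_ss)
    balanced = [(tr[_upsample_indices(y[tr], up_rng)], va) for tr, va in folds]

    configs = _expand_grid(spec, X, np.random.default_rng(gamma_ss))
    fit_seed = int(fit_ss.generate_state(1)[0] % (2**31))
    results = []
    for params in configs:
        accs, kappas = [], []
        for bal_tr, va in balanced:
            est = _wrap(spec, _build_estimator(spec.name, params, fit_seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X[bal_tr], y[bal_tr])
            pred = np.asarray(est.predict(X[va]), int)
            accs.append(float(np.mean(pred == y[va])))
            kappas.append(cohen_kappa_score(y[va], pred))
        results.append({**{f"param_{k}": v for k, v in params.items()},
                        "mean_accuracy": float(np.mean(accs)),
                        "mean_kappa": float(np.nanmean(kappas))})
    cv_results = pd.DataFrame(results)
    best_i = int(cv_results["mean_accuracy"].idxmax())
    best_params = configs[best_i]
    logger.info("%s: best %s (CV accuracy %.3f)", spec.name, best_params,
                cv_results.loc[best_i, "mean_accuracy"])

    final_idx = _upsample_indices(y, np.random.default_rng(upsample_ss))
    final = _wrap(spec, _build_estimator(spec.name, best_params, fit_seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(X[final_idx], y[final_idx])
    return TunedModel(spec=spec, best_params=best_params, cv_results=cv_results,
                      estimator=final, classes_=classes,
                      feature_names=feature_names)


def _wrap(spec: ModelSpec, est):
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


# ---------------------------------------------------------------------------
# the full comparison experiment

@dataclass
class ModelResult:
    tuned: TunedModel
    confusion: ConfusionMatrix
    metrics: object  # ClassMetrics


@dataclass
class ExperimentResult:
    results: dict[tuple[str, int], ModelResult]
    comparison: pd.DataFrame


def run_experiment(tables: dict[int, pd.DataFrame], specs: list[ModelSpec],
                   split: SplitConfig = SplitConfig(), seed: int = 0,
                   ) -> ExperimentResult:
    """Train and evaluate every model on every epoch-length table.

    Each table is split at the event level with the same split seed,
    every spec is tuned and refit on the training side, and the test
    side is scored once per model.  The comparison table carries one
    row per model × epoch, sorted by descending test accuracy within
    each epoch block.
    """
    ss = np.random.SeedSequence(seed)
    epoch_children = dict(zip(sorted(tables), ss.spawn(len(tables))))
    results: dict[tuple[str, int], ModelResult] = {}
    rows = []
    for epoch_s in sorted(tables):
        table = tables[epoch_s]
        train, test = split_events(table, split)
        train_ev, test_ev = set(_event_keys(train)), set(_event_keys(test))
        if train_ev & test_ev:  # leakage guard
            raise AssertionError(f"events {sorted(train_ev & test_ev)[:5]} appear "
                                 "on both sides of the split")
        classes = sorted(set(table["label"]))
        model_children = epoch_children[epoch_s].spawn(len(specs))
        for spec, child in zip(specs, model_children):
            model_seed = int(child.generate_state(1)[0] % (2**31))
            tuned = tune_and_fit(spec, train, seed=model_seed)
            pred = tuned.predict(test)
            cm = ConfusionMatrix.from_labels(pred, test["label"], classes)
            m = class_metrics(cm)
            results[(spec.name, epoch_s)] = ModelResult(tuned=tuned, confusion=cm,
                                                        metrics=m)
            rows.append({"epoch_s": epoch_s, "model": spec.name,
                         "approximate": spec.approximate,
                         "cv_accuracy": 100 * tuned.cv_accuracy,
                         "cv_kappa": tuned.cv_kappa,
                         "test_accuracy": m.accuracy,
                         "macro_f": m.macro_f, "kappa": m.kappa})
    comparison = (pd.DataFrame(rows)
                  .sort_values(["epoch_s", "test_accuracy"],
                               ascending=[True, False], kind="mergesort")
                  .reset_index(drop=True))
    return ExperimentResult(results=results, comparison=comparison)
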