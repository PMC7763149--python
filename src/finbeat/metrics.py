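"""Confusion-matrix performance metrics and permutation importance.

Confusion matrices are stored with **rows = predicted class, columns =
observed class**.  Per-class reduction for class *i*:

    TPi = counts[i, i]
    FNi = column-i sum − TPi      (observed i, predicted elsewhere)
    FPi = row-i sum − TPi         (predicted i, observed elsewhere)
    TNi = total − TPi − FNi − FPi

Per-class sensitivity, specificity and precision follow the usual
ratios; the F-measure is computed as TP / (TP + ½(FP + FN)), the
harmonic mean of precision and sensitivity.  Class-level metrics,
accuracy and macro-F are reported as percentages (matching how such
results are conventionally tabulated); Cohen's kappa is the unitless
chance-corrected agreement (po − pe)/(1 − pe).

A class absent from both predictions and observations has undefined
metrics; it is reported as missing (NaN) and excluded from the macro-F
average rather than silently counted as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts; rows = predicted, columns = observed."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError(f"counts shape {counts.shape} does not match "
                             f"{len(self.classes)} classes")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))
        object.__setattr__(self, "classes", tuple(self.classes))

    @classmethod
    def from_labels(cls, predicted, observed, classes) -> "ConfusionMatrix":
        predicted = list(predicted)
        observed = list(observed)
        if len(predicted) != len(observed):
            raise ValueError("predicted and observed must have equal length")
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), int)
        for p, o in zip(predicted, observed):
            if p not in index:
                raise ValueError(f"unknown predicted label {p!r}")
            if o not in index:
                raise ValueError(f"unknown observed label {o!r}")
            counts[index[p], index[o]] += 1
        return cls(classes=tuple(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.classes, name="predicted"),
                            columns=pd.Index(self.classes, name="observed"))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class and overall metrics of one confusion matrix.

    ``per_class`` columns (percent): sensitivity, specificity,
    precision, f_measure.  ``accuracy`` and ``macro_f`` are percent;
    ``kappa`` is in [−1, 1].
    """

    per_class: pd.DataFrame
    accuracy: float
    macro_f: float
    kappa: float


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """All per-class and overall metrics of a confusion matrix."""
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows: list[dict] = []
    f_values: list[float] = []
    for i, cls_name in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[:, i].sum() - tp
        fp = counts[i, :].sum() - tp
        tn = total - tp - fn - fp
        if fn + fp + tp == 0:
            logger.warning("class %r absent from predictions and observations; "
                           "its metrics are undefined and excluded from macro-F",
                           cls_name)
            rows.append({"class": cls_name, "sensitivity": np.nan,
                         "specificity": np.nan, "precision": np.nan,
                         "f_measure": np.nan})
            continue
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (fp + tn) if fp + tn > 0 else np.nan
        prec = tp / (tp + fp) if tp + fp > 0 else np.nan
        f = tp / (tp + 0.5 * (fp + fn))
        f_values.append(100 * f)
        rows.append({"class": cls_name, "sensitivity": 100 * sens,
                     "specificity": 100 * spec, "precision": 100 * prec,
                     "f_measure": 100 * f})
    per_class = pd.DataFrame(rows).set_index("class")
    accuracy = 100 * np.trace(counts) / total
    pe = float(np.sum(counts.sum(axis=1) * counts.sum(axis=0))) / total**2
    po = np.trace(counts) / total
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    if not f_values:
        raise ValueError("no class has a defined F-measure")
    return ClassMetrics(per_class=per_class, accuracy=float(accuracy),
                        macro_f=float(np.mean(f_values)), kappa=float(kappa))


def macro_f(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the defined per-class F-measures, percent."""
    return class_metrics(cm).macro_f


def permutation_importance(model, test_table: pd.DataFrame, repeats: int = 10,
                           seed: int | None = None) -> pd.DataFrame:
    """Model-agnostic feature importance on held-out epochs.

    Importance of a feature is the mean drop in test accuracy over
    ``repeats`` independent within-column permutations.  Works with any
    fitted model exposing ``predict(table) -> labels`` and
    ``feature_names``; returns one row per feature, sorted by descending
    mean drop, with the raw per-repeat drops in ``drop_0..drop_{r-1}``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = test_table["label"].to_numpy()
    baseline = float(np.mean(model.predict(test_table) == y))
    records = []
    for feat in model.feature_names:
        drops = np.empty(repeats)
        for r in range(repeats):
            shuffled = test_table.copy()
            shuffled[feat] = rng.permutation(shuffled[feat].to_numpy())
            acc = float(np.mean(model.predict(shuffled) == y))
            drops[r] = baseline - acc
        rec = {"feature": feat, "importance": float(drops.mean())}
        rec.update({f"drop_{r}": float(d) for r, d in enumerate(drops)})
        records.append(rec)
    out = pd.DataFrame(records).sort_values("importance", ascending=False,
                                            kind="mergesort")
    return out.reset_index(drop=True)
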