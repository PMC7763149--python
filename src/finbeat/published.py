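"""Reference test-set confusion matrices from the published captive study.

The validation study that motivates this pipeline reported test-set
confusion matrices for its three best classifiers (SVM, RF, XGB) at
both epoch lengths on four shark behaviours.  The raw accelerometer
data were never deposited, but the printed counts are sufficient to
recompute every reported class metric, so they ship here as fixtures:
the evaluation layer can be pinned to the published numbers with no
external data.

Counts are stored rows = predicted, columns = observed (the reading
consistent with the published sensitivity/precision values), class
order ``chew, rest, swim, vertical_swim``; each matrix totals 82 test
epochs.
"""

from __future__ import annotations

import pandas as pd

from .behaviours import MODEL_LABELS
from .metrics import ClassMetrics, ConfusionMatrix, class_metrics

#: (model name, epoch seconds) -> ConfusionMatrix
PUBLISHED_CONFUSION_MATRICES: dict[tuple[str, int], ConfusionMatrix] = {
    (model, epoch): ConfusionMatrix(classes=MODEL_LABELS, counts=counts)
    for (model, epoch), counts in {
        ("SVM", 2): [[13, 0, 1, 0], [2, 20, 2, 0], [4, 0, 32, 0], [0, 0, 0, 8]],
        ("SVM", 1): [[8, 2, 4, 0], [3, 19, 2, 0], [8, 0, 28, 0], [0, 0, 0, 8]],
        ("RF", 2): [[10, 0, 4, 0], [1, 21, 2, 0], [2, 0, 34, 0], [0, 0, 0, 8]],
        ("RF", 1): [[7, 2, 5, 0], [1, 21, 2, 0], [2, 0, 34, 0], [0, 0, 0, 8]],
        ("XGB", 2): [[11, 0, 3, 0], [1, 21, 2, 0], [4, 0, 32, 0], [0, 0, 0, 8]],
        ("XGB", 1): [[5, 1, 8, 0], [0, 21, 3, 0], [4, 1, 31, 0], [0, 0, 0, 8]],
    }.items()
}


def published_metrics(model: str, epoch_seconds: int) -> ClassMetrics:
    """Recompute the metric set of one published confusion matrix."""
    return class_metrics(PUBLISHED_CONFUSION_MATRICES[(model, epoch_seconds)])


def published_metric_table() -> pd.DataFrame:
    """Long-form table of recomputed metrics for all published matrices."""
    rows = []
    for (model, epoch), cm in sorted(PUBLISHED_CONFUSION_MATRICES.items()):
        m = class_metrics(cm)
        for cls_name, r in m.per_class.iterrows():
            rows.append({"model": model, "epoch_s": epoch, "class": cls_name,
                         **r.to_dict()})
        rows.append({"model": model, "epoch_s": epoch, "class": "overall",
                     "accuracy": m.accuracy, "macro_f": m.macro_f,
                     "kappa": m.kappa})
    return pd.DataFrame(rows)
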