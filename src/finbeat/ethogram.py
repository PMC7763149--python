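"""Ethogram management: the swim-merge test and label filtering.

Swimming in the water column and swimming on the floor are
biomechanically similar; whether they stay separate classes is decided
by Welch two-sample t-tests on four epoch-level dynamic-body-
acceleration features (mean and SD of ODBA, SD and max of VeDBA).  The
two classes merge into a single ``swim`` class only when *none* of the
four tests is significant at ``alpha`` — i.e. when the data give no
evidence the classes differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .behaviours import EXCLUDED_LABELS, MERGED_SWIM

logger = logging.getLogger(__name__)

#: Epoch features compared between the two swim classes.
COMPARISON_FEATURES = ("odba_mean", "odba_sd", "vedba_sd", "vedba_max")


@dataclass(frozen=True)
class MergeReport:
    """Result of the swim-class comparison."""

    tests: dict[str, tuple[float, float, float]]  # feature -> (t, df, p)
    decision: str  # "merge" | "keep_separate"
    alpha: float
    missing_class: bool = False
    group_labels: tuple[str, str] = ("swim_column", "swim_floor")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "t": t, "df": df_, "p": p}
                for f, (t, df_, p) in self.tests.items()]
        out = pd.DataFrame(rows, columns=["feature", "t", "df", "p"])
        out["decision"] = self.decision
        return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, degrees of freedom and two-sided p-value."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: constant groups; decided by the mean difference
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf, float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_swim_classes(feature_table: pd.DataFrame, alpha: float = 0.05,
                         group_labels: tuple[str, str] = ("swim_column", "swim_floor"),
                         ) -> MergeReport:
    """Welch-test the two swim classes on the four comparison features.

    Decision: ``merge`` iff every p-value is >= ``alpha`` (no feature
    shows a significant mean difference); ``keep_separate`` otherwise,
    or when either class has fewer than two epochs.
    """
    la, lb = group_labels
    a_rows = feature_table[feature_table["label"] == la]
    b_rows = feature_table[feature_table["label"] == lb]
    if len(a_rows) < 2 or len(b_rows) < 2:
        logger.warning("swim-merge test: class missing or too small "
                       "(%s: %d rows, %s: %d rows); keeping classes separate",
                       la, len(a_rows), lb, len(b_rows))
        return MergeReport(tests={}, decision="keep_separate", alpha=alpha,
                           missing_class=True, group_labels=group_labels)
    tests: dict[str, tuple[float, float, float]] = {}
    for feat in COMPARISON_FEATURES:
        tests[feat] = _welch(a_rows[feat].to_numpy(float),
                             b_rows[feat].to_numpy(float))
    decision = "merge" if all(p >= alpha for *_, p in tests.values()) else "keep_separate"
    return MergeReport(tests=tests, decision=decision, alpha=alpha,
                       group_labels=group_labels)


def apply_ethogram(feature_table: pd.DataFrame,
                   merge_report: MergeReport | str) -> pd.DataFrame:
    """Drop excluded labels and apply the merge decision.

    Feature values are never altered; only row membership and labels
    change.  Raises if the filtered table is empty.
    """
    decision = merge_report if isinstance(merge_report, str) else merge_report.decision
    if decision not in ("merge", "keep_separate"):
        raise ValueError(f"unknown merge decision {decision!r}")
    group_labels = (merge_report.group_labels
                    if isinstance(merge_report, MergeReport)
                    else ("swim_column", "swim_floor"))
    out = feature_table[~feature_table["label"].isin(EXCLUDED_LABELS)].copy()
    if decision == "merge":
        out.loc[out["label"].isin(group_labels), "label"] = MERGED_SWIM
    if out.empty:
        raise ValueError("ethogram filtering removed every epoch; nothing to model")
    return out.reset_index(drop=True)
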