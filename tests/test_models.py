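"""Event-level splitting, up-sampling and the tuning harness."""

import numpy as np
import pandas as pd
import pytest

from finbeat import (ModelSpec, SplitConfig, split_events, tune_and_fit,
                     upsample_minority)
from finbeat.models import MODEL_NAMES, _event_keys, fast_specs
from tests.conftest import make_gaussian_table


def _event_table(events_per_class, rows_per_event=3, classes=("rest", "swim"),
                 seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    eid = 0
    for cls in classes:
        for _ in range(events_per_class):
            for _ in range(rows_per_event):
                rows.append({"f": rng.normal(), "label": cls, "event_id": eid,
                             "session": "s0"})
            eid += 1
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_80_20_per_class(self):
        t = _event_table(10)
        train, test = split_events(t, SplitConfig(seed=0))
        for cls in ("rest", "swim"):
            assert train[train.label == cls]["event_id"].nunique() == 8
            assert test[test.label == cls]["event_id"].nunique() == 2

    def test_events_never_straddle_the_split(self):
        t = _event_table(7, rows_per_event=4)
        train, test = split_events(t, SplitConfig(seed=1))
        assert not (set(_event_keys(train)) & set(_event_keys(test)))
        assert len(train) + len(test) == len(t)

    def test_same_seed_same_partition(self):
        t = _event_table(9)
        a = split_events(t, SplitConfig(seed=5))
        b = split_events(t, SplitConfig(seed=5))
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_single_event_class_goes_to_train(self, caplog):
        chew = _event_table(1, classes=("chew",), seed=9)
        chew["event_id"] += 1000  # keep event keys distinct across classes
        t = pd.concat([_event_table(5), chew], ignore_index=True)
        with caplog.at_level("WARNING", logger="finbeat.models"):
            train, test = split_events(t, SplitConfig(seed=0))
        assert "chew" in caplog.text
        assert (test.label != "chew").all()
        assert (train.label == "chew").any()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitConfig(train_fraction=1.0)


class TestUpsample:
    def test_counts_equal_majority(self):
        parts = []
        for cls, n in {"rest": 100, "swim": 150, "chew": 12,
                       "vertical_swim": 9}.items():
            block = make_gaussian_table(n, [cls], seed=hashable_seed(cls))
            parts.append(block)
        t = pd.concat(parts, ignore_index=True)
        out = upsample_minority(t, seed=0)
        assert out["label"].value_counts().unique().tolist() == [150]

    def test_originals_retained_and_duplicates_genuine(self):
        t = pd.concat([make_gaussian_table(30, ["rest"], seed=1),
                       make_gaussian_table(7, ["chew"], seed=2)],
                      ignore_index=True)
        out = upsample_minority(t, seed=3)
        # all original rows present
        assert out.head(len(t)).equals(t)
        # every added row is bit-identical to an original row of its class
        added = out.iloc[len(t):]
        originals = {tuple(r) for r in t[t.label == "chew"].itertuples(index=False)}
        for r in added.itertuples(index=False):
            assert r.label == "chew" and tuple(r) in originals

    def test_balanced_input_is_noop(self):
        t = pd.concat([make_gaussian_table(20, ["rest"], seed=4),
                       make_gaussian_table(20, ["swim"], seed=5)],
                      ignore_index=True)
        assert upsample_minority(t, seed=0).equals(t)

    def test_single_class_unchanged_with_warning(self, caplog):
        t = make_gaussian_table(10, ["rest"], seed=6)
        with caplog.at_level("WARNING", logger="finbeat.models"):
            out = upsample_minority(t, seed=0)
        assert out.equals(t) and "skipped" in caplog.text


def hashable_seed(s):
    return sum(map(ord, s))


class TestTuning:
    @pytest.mark.parametrize("name", ["CART", "SVM"])
    def test_separable_classes_reach_high_cv_accuracy(self, name):
        t = make_gaussian_table(50, ["a", "b"], separation=8.0, seed=0,
                                informative=("odba_mean", "vedba_q90", "odba_sd",
                                             "vedba_mean", "x_sd", "y_sd"))
        spec = ModelSpec(name=name, grid=fast_specs((name,))[0].grid,
                         cv_repeats=1)
        tuned = tune_and_fit(spec, t, seed=1)
        assert tuned.cv_accuracy >= 0.99

    def test_permuted_labels_score_at_chance(self):
        t = make_gaussian_table(60, ["a", "b", "c", "d"], separation=6.0, seed=1)
        rng = np.random.default_rng(2)
        t["label"] = rng.permutation(t["label"].to_numpy())
        spec = ModelSpec(name="CART", grid={"cp": [0.01]}, cv_repeats=1)
        tuned = tune_and_fit(spec, t, seed=3)
        assert abs(tuned.cv_accuracy - 0.25) < 0.08

    def test_same_seed_selects_same_configuration(self):
        t = make_gaussian_table(25, ["a", "b"], separation=1.0, seed=4)
        spec = ModelSpec(name="CART", cv_repeats=1)
        a = tune_and_fit(spec, t, seed=7)
        b = tune_and_fit(spec, t, seed=7)
        assert a.best_params == b.best_params
        assert a.cv_results.equals(b.cv_results)

    def test_thin_class_raises_naming_it(self):
        t = pd.concat([make_gaussian_table(30, ["rest"], seed=5),
                       make_gaussian_table(4, ["chew"], seed=6)],
                      ignore_index=True)
        with pytest.raises(ValueError, match="chew"):
            tune_and_fit(ModelSpec(name="CART", cv_repeats=1), t, seed=0)

    def test_cv_summary_covers_grid(self):
        t = make_gaussian_table(20, ["a", "b"], separation=3.0, seed=7)
        spec = ModelSpec(name="CART", grid={"cp": [0.001, 0.01, 0.05]},
                         cv_folds=5, cv_repeats=2)
        tuned = tune_and_fit(spec, t, seed=0)
        assert len(tuned.cv_results) == 3
        assert {"mean_accuracy", "mean_kappa"} <= set(tuned.cv_results.columns)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec(name="LSTM")

    def test_registry_covers_eight_models(self):
        assert len(MODEL_NAMES) == 8
        assert [s.name for s in fast_specs()] == list(MODEL_NAMES)
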