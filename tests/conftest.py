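"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from finbeat import GeneratorConfig, build_feature_table, simulate_session
from finbeat.epochs import FEATURE_NAMES
from finbeat.simulate import session_seeds


@pytest.fixture(scope="session")
def small_sessions():
    """Two 180 s sessions at the default generator settings."""
    return [(f"s{i}", *simulate_session(GeneratorConfig(seed=s, session_length=180.0)))
            for i, s in enumerate(session_seeds(42, 2))]


@pytest.fixture(scope="session")
def table_2s(small_sessions):
    return build_feature_table(small_sessions, 2)


@pytest.fixture(scope="session")
def table_1s(small_sessions):
    return build_feature_table(small_sessions, 1)


def make_gaussian_table(n_per_class, classes, separation=0.0, seed=0,
                        informative=("odba_mean", "vedba_q90")):
    """A feature table of Gaussian noise in all 66 columns, with class
    means shifted by ``separation`` SDs on the ``informative`` columns.

    Every row is its own event, so event splitting degenerates to row
    splitting.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for c, cls in enumerate(classes):
        block = pd.DataFrame(rng.normal(size=(n_per_class, len(FEATURE_NAMES))),
                             columns=list(FEATURE_NAMES))
        for col in informative:
            block[col] += c * separation
        block["label"] = cls
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["event_id"] = np.arange(len(out))
    out["session"] = "g0"
    return out
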