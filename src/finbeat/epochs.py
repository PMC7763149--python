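"""Fixed-length single-behaviour epochs and their 66 summary statistics.

Each labelled event is tiled with consecutive non-overlapping windows of
``epoch_seconds`` (10 or 20 samples at 10 Hz); the trailing remainder is
discarded and no window crosses an event boundary, so every epoch holds
data from exactly one behaviour.  Per epoch, six moment statistics
(mean, SD, min, max, skewness, kurtosis) are computed for each of the
nine channels, plus the 10th and 90th percentiles for the six derived
channels — 9×6 + 6×2 = 66 features.

Conventions (configurable where noted): SD uses the n−1 denominator;
skewness is the moment coefficient m3/m2^1.5 and kurtosis the excess
m4/m2² − 3; both are defined as 0 for a constant channel; percentiles
interpolate linearly between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviours import EXCLUDED_LABELS
from .signals import CHANNELS, AccelStream, derive_channels
from .simulate import BehaviourEvent

logger = logging.getLogger(__name__)

MOMENT_STATS = ("mean", "sd", "min", "max", "skew", "kurt")
QUANTILE_CHANNELS = ("odba", "vedba", "movvar", "energy", "pitch", "roll")

#: The 66 feature column names, canonical order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ch}_{st}" for ch in CHANNELS for st in MOMENT_STATS]
    + [f"{ch}_{q}" for ch in QUANTILE_CHANNELS for q in ("q10", "q90")]
)

META_COLUMNS = ("label", "event_id", "session")


@dataclass(frozen=True)
class Epoch:
    event_id: int
    label: str
    start_index: int
    n_samples: int


def _epoch_samples(epoch_seconds: float, sampling_rate: float) -> int:
    n = epoch_seconds * sampling_rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"epoch_seconds × sampling_rate must be integral, "
                         f"got {epoch_seconds} × {sampling_rate} = {n}")
    return int(round(n))


def segment_epochs(derived: pd.DataFrame, events: list[BehaviourEvent],
                   epoch_seconds: float, sampling_rate: float,
                   stride: int | None = None) -> list[Epoch]:
    """Cut single-behaviour epochs from the derived-channel table.

    Windows are anchored at each event's start and advance by ``stride``
    samples (default: the epoch length, i.e. disjoint tiling).  Events
    labelled ``other``/``out_of_camera`` are excluded; events shorter
    than one epoch contribute none.
    """
    n_epoch = _epoch_samples(epoch_seconds, sampling_rate)
    stride = n_epoch if stride is None else int(stride)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n_total = len(derived)
    epochs: list[Epoch] = []
    too_short = 0
    for ev in events:
        if ev.label in EXCLUDED_LABELS:
            continue
        i0 = int(round(ev.start * sampling_rate))
        i1 = min(int(round(ev.end * sampling_rate)), n_total)
        if i1 - i0 < n_epoch:
            too_short += 1
            continue
        start = i0
        while start + n_epoch <= i1:
            epochs.append(Epoch(event_id=ev.event_id, label=ev.label,
                                start_index=start, n_samples=n_epoch))
            start += stride
    if too_short:
        logger.info("%d events shorter than one %.0f-sample epoch produced no epochs",
                    too_short, n_epoch)
    return epochs


def _moments(v: np.ndarray) -> tuple[float, float, float, float, float, float]:
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:  # constant channel: sd/skew/kurt defined as exactly 0
        return lo, 0.0, lo, hi, 0.0, 0.0
    mean = float(v.mean())
    d = v - mean
    m2 = float(np.mean(d**2))
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if m2 <= 1e-300:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2 - 3.0
    return mean, sd, lo, hi, skew, kurt


def summarize_epoch(epoch: Epoch, derived: pd.DataFrame) -> dict[str, float]:
    """The 66 named summary statistics of one epoch, plus its metadata."""
    seg = derived.iloc[epoch.start_index:epoch.start_index + epoch.n_samples]
    if len(seg) != epoch.n_samples:
        raise ValueError(f"epoch at index {epoch.start_index} extends past the stream")
    out: dict[str, float] = {}
    for ch in CHANNELS:
        v = seg[ch].to_numpy(float)
        for st, val in zip(MOMENT_STATS, _moments(v)):
            out[f"{ch}_{st}"] = val
    for ch in QUANTILE_CHANNELS:
        v = seg[ch].to_numpy(float)
        q10, q90 = np.quantile(v, [0.1, 0.9])  # linear interpolation
        out[f"{ch}_q10"] = float(q10)
        out[f"{ch}_q90"] = float(q90)
    out["label"] = epoch.label
    out["event_id"] = epoch.event_id
    return out


def build_feature_table(sessions, epoch_seconds: float, window: int = 5,
                        energy_form: str = "magnitude",
                        stride: int | None = None) -> pd.DataFrame:
    """One row of 66 features (+ label, event_id, session) per epoch.

    ``sessions`` is an iterable of ``(session_id, AccelStream, events)``.
    Spans not covered by any event are simply never segmented (they are
    logged as uncovered, equivalent to an out-of-camera exclusion).
    """
    rows: list[dict] = []
    for session_id, stream, events in sessions:
        derived = derive_channels(stream, window=window, energy_form=energy_form)
        covered = sum(ev.duration for ev in events)
        span = len(stream) / stream.sampling_rate
        if span - covered > 1.0 / stream.sampling_rate:
            logger.info("session %s: %.1f s not covered by the label track (excluded)",
                        session_id, span - covered)
        for ep in segment_epochs(derived, events, epoch_seconds,
                                 stream.sampling_rate, stride=stride):
            row = summarize_epoch(ep, derived)
            row["session"] = session_id
            rows.append(row)
    cols = list(FEATURE_NAMES) + list(META_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]
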