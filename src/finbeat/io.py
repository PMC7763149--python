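"""CSV dialects for streams, label tracks and session manifests.

Accelerometer CSV: header ``time,x,y,z``; time in seconds (3 decimals),
axes in g (6 decimals).  Label CSV: header ``event_id,label,start,end``.
Manifest: one ``accel_file,label_file`` pair per line, paths relative to
the manifest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import AccelStream
from .simulate import BehaviourEvent


def write_accel_csv(stream: AccelStream, path) -> None:
    df = stream.data.copy()
    df["time"] = df["time"].map(lambda v: f"{v:.3f}")
    for ax in ("x", "y", "z"):
        df[ax] = df[ax].map(lambda v: f"{v:.6f}")
    df[["time", "x", "y", "z"]].to_csv(path, index=False)


def read_accel_csv(path, sampling_rate: float | None = None) -> AccelStream:
    """Read an accelerometer CSV; the rate is inferred from the median
    time step unless given."""
    df = pd.read_csv(path)
    if sampling_rate is None:
        if len(df) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from "
                             f"{len(df)} samples; pass sampling_rate")
        sampling_rate = 1.0 / float(np.median(np.diff(df["time"].to_numpy(float))))
    return AccelStream(sampling_rate=round(sampling_rate, 6), data=df)


def write_labels_csv(events: list[BehaviourEvent], path) -> None:
    rows = [{"event_id": e.event_id, "label": e.label,
             "start": f"{e.start:.3f}", "end": f"{e.end:.3f}"} for e in events]
    pd.DataFrame(rows, columns=["event_id", "label", "start", "end"]).to_csv(
        path, index=False)


def read_labels_csv(path) -> list[BehaviourEvent]:
    df = pd.read_csv(path)
    return [BehaviourEvent(event_id=int(r.event_id), label=str(r.label),
                           start=float(r.start), end=float(r.end))
            for r in df.itertuples()]


def load_sessions(manifest_path):
    """Yield ``(session_id, AccelStream, events)`` for each manifest line."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    sessions = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        accel_name, label_name = (s.strip() for s in line.split(","))
        session_id = Path(accel_name).stem.replace("_accel", "")
        sessions.append((session_id,
                         read_accel_csv(base / accel_name),
                         read_labels_csv(base / label_name)))
    return sessions
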