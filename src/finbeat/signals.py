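"""Per-sample derived channels from raw tri-axial acceleration.

The raw signal on each axis is split into a *static* (gravity/posture)
component — a centred 5-sample moving average — and a *dynamic*
(body-movement) component, the raw minus the static.  From these the six
standard biologging channels are derived per sample:

========  =====================================================
odba      |Xdyn| + |Ydyn| + |Zdyn|   (overall dynamic body acceleration)
vedba     sqrt(Xdyn² + Ydyn² + Zdyn²)  (vectorial DBA)
movvar    |ΔX| + |ΔY| + |ΔZ| of the raw axes (movement variation)
energy    sqrt(X² + Y² + Z²) of the raw axes
pitch     atan(−Xs / sqrt(Ys² + Zs²)) · 180/π   (static axes), degrees
roll      atan2(Ys, Zs) · 180/π                 (static axes), degrees
========  =====================================================

Posture angles use the static axes (the gravity estimate); energy and
movement variation summarise the raw signal.  Movement variation is
aligned to samples by forward differences, the final sample repeating
its predecessor's value, so all nine channels share one index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine channels summarised per epoch, in canonical order.
CHANNELS = ("x", "y", "z", "odba", "vedba", "movvar", "energy", "pitch", "roll")


@dataclass(frozen=True)
class AccelStream:
    """A time-ordered tri-axial acceleration stream at a fixed rate.

    ``data`` has columns ``time`` (s), ``x``, ``y``, ``z`` (g); samples
    must be strictly increasing with spacing ``1/sampling_rate`` (to
    1e-6 s) and finite.
    """

    sampling_rate: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        missing = {"time", "x", "y", "z"} - set(self.data.columns)
        if missing:
            raise ValueError(f"stream missing columns: {sorted(missing)}")
        vals = self.data[["time", "x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("stream contains non-finite values")
        if len(self.data) > 1:
            dt = np.diff(vals[:, 0])
            if np.any(np.abs(dt - 1.0 / self.sampling_rate) > 1e-6):
                raise ValueError("sample spacing deviates from 1/sampling_rate "
                                 "by more than 1e-6 s")

    @classmethod
    def from_arrays(cls, time, x, y, z, sampling_rate: float,
                    validate: bool = True) -> "AccelStream":
        df = pd.DataFrame({"time": np.asarray(time, float),
                           "x": np.asarray(x, float),
                           "y": np.asarray(y, float),
                           "z": np.asarray(z, float)})
        if not validate:
            obj = object.__new__(cls)
            object.__setattr__(obj, "sampling_rate", sampling_rate)
            object.__setattr__(obj, "data", df)
            return obj
        return cls(sampling_rate=sampling_rate, data=df)

    def __len__(self) -> int:
        return len(self.data)


def smooth_static(stream: AccelStream | pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Centred moving-average gravity estimate of each raw axis.

    The window is ``window`` samples wide and shrinks at the stream
    boundaries to the samples available within the half-width, so the
    output has the input's length.  ``window`` must be odd (a centred
    window needs a centre) and >= 1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    df = stream.data if isinstance(stream, AccelStream) else stream
    if len(df) == 0:
        raise ValueError("cannot smooth an empty stream")
    n, half = len(df), window // 2
    out = {}
    for ax in ("x", "y", "z"):
        v = df[ax].to_numpy(float)
        sm = np.empty(n)
        if n >= window:
            # each window averaged independently: no accumulator drift,
            # so a constant stream smooths to itself exactly
            windows = np.lib.stride_tricks.sliding_window_view(v, window)
            sm[half:n - half] = windows.mean(axis=1)
        for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            sm[i] = v[lo:hi].mean()
        out[f"{ax}_static"] = sm
    return pd.DataFrame(out, index=df.index)


def derive_channels(stream: AccelStream, window: int = 5,
                    energy_form: str = "magnitude") -> pd.DataFrame:
    """Compute the full per-sample derived-channel table.

    Returns a DataFrame with the raw axes, static and dynamic axes, and
    the six derived channels; one row per input sample.

    ``energy_form`` selects ``magnitude`` (sqrt of the summed squared
    raw axes, the default) or ``squared`` (the summed squares).
    """
    if energy_form not in ("magnitude", "squared"):
        raise ValueError(f"energy_form must be 'magnitude' or 'squared', got {energy_form!r}")
    df = stream.data
    static = smooth_static(stream, window=window)
    out = pd.DataFrame({"time": df["time"].to_numpy()})
    for ax in ("x", "y", "z"):
        raw = df[ax].to_numpy(float)
        st = static[f"{ax}_static"].to_numpy()
        out[ax] = raw
        out[f"{ax}_static"] = st
        out[f"{ax}_dyn"] = raw - st

    xd, yd, zd = (out[c].to_numpy() for c in ("x_dyn", "y_dyn", "z_dyn"))
    out["odba"] = np.abs(xd) + np.abs(yd) + np.abs(zd)
    out["vedba"] = np.sqrt(xd**2 + yd**2 + zd**2)

    x, y, z = (df[c].to_numpy(float) for c in ("x", "y", "z"))
    n = len(df)
    movvar = np.zeros(n)
    if n > 1:
        step = np.abs(np.diff(x)) + np.abs(np.diff(y)) + np.abs(np.diff(z))
        movvar[:-1] = step
        movvar[-1] = step[-1]
    out["movvar"] = movvar

    sq = x**2 + y**2 + z**2
    out["energy"] = np.sqrt(sq) if energy_form == "magnitude" else sq

    xs, ys, zs = (out[f"{ax}_static"].to_numpy() for ax in ("x", "y", "z"))
    horiz = np.hypot(ys, zs)
    degenerate = (horiz == 0) & (xs == 0)
    if np.any(horiz == 0):
        logger.warning("pitch/roll degenerate at %d samples (Ys = Zs = 0)",
                       int(np.sum(horiz == 0)))
    # atan2(-Xs, 0) gives ±90° by the sign of -Xs; atan2(0, 0) gives 0
    out["pitch"] = np.degrees(np.arctan2(-xs, horiz))
    out.loc[degenerate, "pitch"] = 0.0
    roll = np.degrees(np.arctan2(ys, zs))
    roll[roll == -180.0] = 180.0  # range (−180, 180]
    out["roll"] = roll
    return out
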