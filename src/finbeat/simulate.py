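"""Synthetic labelled tri-axial accelerometer sessions.

Real validation data for benthic sharks pair a 10 Hz, ±2 g tri-axial
accelerometer stream with a video-coded behaviour track.  This module
emulates such sessions with an additive signal model: each behaviour is a
constant gravity posture plus (optionally) a sinusoidal tailbeat or
mastication oscillation on one device axis, plus Gaussian sensor noise,
clipped to the device range.  The four regimes carry the qualitative
signatures the downstream analysis relies on:

* ``rest`` — near-static, very low variance, belly-down posture;
* ``swim_column`` / ``swim_floor`` — rhythmic y-axis tailbeat oscillation
  (two labels, identical signal parameters, so the swim-merge test has a
  true-null instance);
* ``vertical_swim`` — posture pitched ~90° (gravity moves from the z to
  the x device axis) with the largest-amplitude, fastest tailbeats and
  hence the highest dynamic body acceleration;
* ``chew`` — short bouts (<2 s) of small fast rhythmic x-axis pulses on
  a resting posture.

Sessions are a first-order stand-in for captive observation: dwell times
are uniform per behaviour, transitions are drawn from stationary relative
frequencies with no immediate self-transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


logger = logging.getLogger(__name__)

_G = 1.0  # gravity magnitude in g units

#: Posture vectors (unit gravity direction in the device frame).
_BELLY_DOWN = (0.0, 0.0, -1.0)
_NOSE_UP = (-1.0, 0.0, 0.0)


@dataclass(frozen=True)
class BehaviourParams:
    """Signal parameters for one behaviour regime.

    Parameters
    ----------
    baseline_orientation
        Unit gravity vector in the device frame; the static (posture)
        component of the signal, in g.
    noise_sd
        Standard deviation of white Gaussian sensor noise, g.
    oscillation_axis
        Device axis ('x', 'y' or 'z') carrying the sinusoidal
        oscillation (tailbeat or mastication).
    oscillation_freq
        Oscillation frequency, Hz; must be below the Nyquist rate.
    oscillation_amp
        Oscillation amplitude, g; zero for static behaviours.
    dwell_min, dwell_max
        Bounds of the uniform dwell-time distribution, seconds.
    relative_frequency
        Probability weight of the behaviour in the transition draw;
        weights are normalised across the configured behaviours.
    """

    baseline_orientation: tuple[float, float, float]
    noise_sd: float
    oscillation_axis: str = "y"
    oscillation_freq: float = 0.0
    oscillation_amp: float = 0.0
    dwell_min: float = 1.0
    dwell_max: float = 2.0
    relative_frequency: float = 1.0


def _default_behaviours() -> dict[str, BehaviourParams]:
    swim = BehaviourParams(
        baseline_orientation=_BELLY_DOWN, noise_sd=0.03,
        oscillation_axis="y", oscillation_freq=0.7, oscillation_amp=0.2,
        dwell_min=10.0, dwell_max=60.0, relative_frequency=0.19,
    )
    return {
        "rest": BehaviourParams(
            baseline_orientation=_BELLY_DOWN, noise_sd=0.01,
            oscillation_amp=0.0, dwell_min=10.0, dwell_max=60.0,
            relative_frequency=0.30,
        ),
        "swim_column": swim,
        # identical parameters on purpose: the merge test's true null
        "swim_floor": replace(swim, relative_frequency=0.19),
        "vertical_swim": BehaviourParams(
            baseline_orientation=_NOSE_UP, noise_sd=0.05,
            oscillation_axis="y", oscillation_freq=1.2, oscillation_amp=0.6,
            dwell_min=2.0, dwell_max=10.0, relative_frequency=0.12,
        ),
        # chew bouts are kept the shortest behaviour but long enough that
        # both epoch lengths (1 s and 2 s) capture whole-bout windows
        "chew": BehaviourParams(
            baseline_orientation=_BELLY_DOWN, noise_sd=0.02,
            oscillation_axis="x", oscillation_freq=3.0, oscillation_amp=0.1,
            dwell_min=2.0, dwell_max=5.0, relative_frequency=0.20,
        ),
    }


def _rare_behaviours() -> dict[str, BehaviourParams]:
    return {
        "other": BehaviourParams(
            baseline_orientation=_BELLY_DOWN, noise_sd=0.08,
            oscillation_axis="z", oscillation_freq=1.5, oscillation_amp=0.3,
            dwell_min=1.0, dwell_max=5.0, relative_frequency=0.03,
        ),
        "out_of_camera": BehaviourParams(
            baseline_orientation=_BELLY_DOWN, noise_sd=0.02,
            oscillation_amp=0.0, dwell_min=5.0, dwell_max=30.0,
            relative_frequency=0.03,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic session generator."""

    sampling_rate: float = 10.0
    session_length: float = 600.0
    device_range: float = 2.0
    behaviours: dict[str, BehaviourParams] = field(default_factory=_default_behaviours)
    include_rare: bool = False
    seed: int = 0

    def with_rare(self) -> "GeneratorConfig":
        """Return a copy that also emits 'other'/'out_of_camera' events."""
        beh = dict(self.behaviours)
        beh.update(_rare_behaviours())
        return replace(self, behaviours=beh, include_rare=True)

    def validate(self) -> None:
        problems: list[str] = []
        if self.sampling_rate <= 0:
            problems.append("sampling_rate must be > 0")
        if self.device_range <= 0:
            problems.append("device_range must be > 0")
        if self.session_length < 0:
            problems.append("session_length must be >= 0")
        total_weight = 0.0
        for name, p in self.behaviours.items():
            if p.noise_sd < 0:
                problems.append(f"{name}: noise_sd must be >= 0")
            if p.oscillation_axis not in ("x", "y", "z"):
                problems.append(f"{name}: oscillation_axis must be x, y or z")
            if p.oscillation_freq >= self.sampling_rate / 2:
                problems.append(f"{name}: oscillation_freq must be below Nyquist "
                                f"({self.sampling_rate / 2} Hz)")
            if p.dwell_min > p.dwell_max:
                problems.append(f"{name}: dwell_min must be <= dwell_max")
            if p.dwell_min <= 0:
                problems.append(f"{name}: dwell_min must be > 0")
            if p.relative_frequency < 0:
                problems.append(f"{name}: relative_frequency must be >= 0")
            norm = float(np.linalg.norm(p.baseline_orientation))
            if abs(norm - 1.0) > 1e-6:
                problems.append(f"{name}: baseline_orientation must be a unit vector "
                                f"(norm {norm:.6f})")
            total_weight += p.relative_frequency
        if total_weight <= 0:
            problems.append("relative_frequency weights must sum to > 0")
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class BehaviourEvent:
    """One contiguous single-behaviour span of a session."""

    event_id: int
    label: str
    start: float  # seconds
    end: float    # seconds

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"event {self.event_id}: end ({self.end}) must be "
                             f"> start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _stage_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent generators for the schedule and the noise stream."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def sample_schedule(config: GeneratorConfig) -> list[BehaviourEvent]:
    """Draw a dwell-time behaviour schedule tiling ``[0, session_length]``.

    Labels are drawn by ``relative_frequency`` with no two consecutive
    identical labels; each event's duration is uniform on its label's
    ``[dwell_min, dwell_max]``; the last event is truncated to the
    session end.
    """
    config.validate()
    rng, _ = _stage_rngs(config.seed)
    if config.session_length == 0:
        return []
    names = sorted(config.behaviours)
    weights = np.array([config.behaviours[n].relative_frequency for n in names], float)
    weights /= weights.sum()
    min_dwell = min(p.dwell_min for p in config.behaviours.values())
    if config.session_length < min_dwell:
        logger.warning("session_length %.3f s shorter than smallest dwell_min %.3f s; "
                       "emitting a single truncated event", config.session_length, min_dwell)

    events: list[BehaviourEvent] = []
    t = 0.0
    prev: str | None = None
    while t < config.session_length:
        # no self-transitions: renormalise the weights over the other labels
        w = weights.copy()
        if prev is not None and w[names.index(prev)] < w.sum():
            w[names.index(prev)] = 0.0
            w /= w.sum()
        label = rng.choice(names, p=w)
        p = config.behaviours[label]
        duration = rng.uniform(p.dwell_min, p.dwell_max)
        end = min(t + duration, config.session_length)
        events.append(BehaviourEvent(event_id=len(events), label=str(label),
                                     start=t, end=end))
        prev = label
        t = end
    return events


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def synthesize_stream(schedule: list[BehaviourEvent], config: GeneratorConfig):
    """Render a schedule into a tri-axial acceleration stream.

    Per-sample signal: gravity projection of the event's posture +
    sinusoid on the oscillation axis (phase restarts at each event
    start) + white noise, clipped to ±``device_range``.

    Returns
    -------
    AccelStream
        ``round(sampling_rate × session span)`` samples at the
        configured rate.
    """
    from .signals import AccelStream  # local import to avoid a cycle

    config.validate()
    fs = config.sampling_rate
    if not schedule:
        return AccelStream.from_arrays(np.empty(0), np.empty(0), np.empty(0),
                                       np.empty(0), sampling_rate=fs, validate=False)
    span = schedule[-1].end
    n = int(round(fs * span))
    t = np.arange(n) / fs
    xyz = np.zeros((3, n))
    _, noise_rng = _stage_rngs(config.seed)

    for ev in schedule:
        i0 = int(round(ev.start * fs))
        i1 = min(int(round(ev.end * fs)), n)
        if i1 <= i0:
            continue
        p = config.behaviours[ev.label]
        seg_t = t[i0:i1] - ev.start
        seg = np.tile(_G * np.asarray(p.baseline_orientation)[:, None], (1, i1 - i0))
        if p.oscillation_amp > 0:
            ax = _AXIS_INDEX[p.oscillation_axis]
            seg[ax] += p.oscillation_amp * np.sin(2 * np.pi * p.oscillation_freq * seg_t)
        if p.noise_sd > 0:
            seg += noise_rng.normal(0.0, p.noise_sd, size=seg.shape)
        xyz[:, i0:i1] = seg

    clipped = int(np.sum(np.abs(xyz) > config.device_range))
    if clipped:
        logger.warning("clipped %d samples to ±%.1f g", clipped, config.device_range)
    xyz = np.clip(xyz, -config.device_range, config.device_range)
    return AccelStream.from_arrays(t, xyz[0], xyz[1], xyz[2], sampling_rate=fs)


def simulate_session(config: GeneratorConfig):
    """Convenience: draw a schedule and render it. Returns (stream, events)."""
    schedule = sample_schedule(config)
    return synthesize_stream(schedule, config), schedule


def session_seeds(master_seed: int, n_sessions: int) -> list[int]:
    """Deterministic per-session seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_sessions)]


def generate_dataset(n_sessions: int, config: GeneratorConfig, outdir) -> Path:
    """Write ``n_sessions`` simulated sessions plus a manifest to ``outdir``.

    Each session gets an accelerometer CSV (``time,x,y,z``) and a label
    CSV (``event_id,label,start,end``); the manifest lists the file
    pairs one per line.  Per-session seeds derive deterministically from
    ``config.seed``, so regeneration is byte-identical.

    Returns the manifest path.
    """
    from . import io as fio

    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    pairs: list[tuple[str, str]] = []
    for i, seed in enumerate(session_seeds(config.seed, n_sessions), start=1):
        scfg = replace(config, seed=seed)
        stream, events = simulate_session(scfg)
        accel_name = f"session_{i:02d}_accel.csv"
        label_name = f"session_{i:02d}_labels.csv"
        fio.write_accel_csv(stream, outdir / accel_name)
        fio.write_labels_csv(events, outdir / label_name)
        pairs.append((accel_name, label_name))
    manifest = outdir / "manifest.txt"
    manifest.write_text("".join(f"{a},{b}\n" for a, b in pairs))
    return manifest
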