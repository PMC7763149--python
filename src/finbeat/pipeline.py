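"""End-to-end pipeline: configuration, stage wiring, and result output.

One YAML config (or a :class:`RunConfig` built in code) drives the full
chain: simulate (or load) sessions → derive channels → epoch features →
swim-merge test → ethogram filtering → event split → tune/fit all
models → evaluate → report.  One master seed governs every stage seed
deterministically, so any output file is reproducible from config +
seed alone.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .epochs import build_feature_table
from .ethogram import apply_ethogram, compare_swim_classes
from .metrics import permutation_importance
from .models import (MODEL_NAMES, SplitConfig, default_specs, fast_specs,
                     run_experiment, split_events)
from .simulate import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved settings for one pipeline run."""

    seed: int = 0
    outdir: str = "finbeat_results"
    # input: either a manifest of existing sessions, or generator settings
    manifest: str | None = None
    n_sessions: int = 4
    session_length: float = 600.0
    include_rare: bool = False
    # features
    epoch_seconds: list[float] = field(default_factory=lambda: [1, 2])
    smoothing_window: int = 5
    energy_form: str = "magnitude"
    stride: int | None = None
    # ethogram
    alpha: float = 0.05
    merge_swim: str = "auto"  # auto | always | never
    # modelling
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    train_fraction: float = 0.8
    tuning_profile: str = "fast"  # fast | full
    cv_folds: int = 10
    importance_repeats: int = 10

    def validate(self) -> None:
        problems = []
        if self.manifest is not None and not Path(self.manifest).exists():
            problems.append(f"manifest {self.manifest} does not exist")
        if self.n_sessions < 1:
            problems.append("n_sessions must be >= 1")
        if self.energy_form not in ("magnitude", "squared"):
            problems.append("energy_form must be 'magnitude' or 'squared'")
        if self.merge_swim not in ("auto", "always", "never"):
            problems.append("merge_swim must be auto, always or never")
        if self.tuning_profile not in ("fast", "full"):
            problems.append("tuning_profile must be 'fast' or 'full'")
        if not 0 < self.train_fraction < 1:
            problems.append("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            problems.append("cv_folds must be >= 2")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            problems.append(f"unknown models: {sorted(unknown)}")
        if not self.epoch_seconds:
            problems.append("epoch_seconds must be non-empty")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config, applying documented defaults.

    Unknown keys, bad types and missing files are reported together in
    one error; nothing is written on failure.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"invalid run config: unknown keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _stage_seed(master: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([master, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the results directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("finbeat")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("resolved config: %s", dataclasses.asdict(cfg))
        # --- sessions ----------------------------------------------------
        if cfg.manifest is None:
            gen = GeneratorConfig(session_length=cfg.session_length,
                                  seed=_stage_seed(cfg.seed, "simulate"))
            if cfg.include_rare:
                gen = gen.with_rare()
            manifest = generate_dataset(cfg.n_sessions, gen, outdir / "sessions")
            logger.info("simulated %d sessions of %.0f s", cfg.n_sessions,
                        cfg.session_length)
        else:
            manifest = Path(cfg.manifest)
        sessions = fio.load_sessions(manifest)

        # --- features ----------------------------------------------------
        tables = {}
        for epoch_s in cfg.epoch_seconds:
            t = build_feature_table(sessions, epoch_s, window=cfg.smoothing_window,
                                    energy_form=cfg.energy_form, stride=cfg.stride)
            tables[epoch_s] = t
            t.to_csv(outdir / f"features_{epoch_s:g}s.csv", index=False)
            logger.info("%g s epochs: %d feature rows", epoch_s, len(t))

        # --- ethogram ----------------------------------------------------
        merge_table = tables[max(tables)]
        report = compare_swim_classes(merge_table, alpha=cfg.alpha)
        report.to_frame().to_csv(outdir / "merge_report.csv", index=False)
        decision = {"auto": report.decision, "always": "merge",
                    "never": "keep_separate"}[cfg.merge_swim]
        logger.info("swim-merge decision: %s (mode %s)", decision, cfg.merge_swim)
        model_tables = {e: apply_ethogram(t, decision) for e, t in tables.items()}

        # --- modelling ---------------------------------------------------
        make = fast_specs if cfg.tuning_profile == "fast" else default_specs
        specs = [dataclasses.replace(s, cv_folds=cfg.cv_folds)
                 for s in make(tuple(cfg.models))]
        split = SplitConfig(train_fraction=cfg.train_fraction,
                            seed=_stage_seed(cfg.seed, "split"))
        result = run_experiment(model_tables, specs, split,
                                seed=_stage_seed(cfg.seed, "train"))
        result.comparison.to_csv(outdir / "comparison.csv", index=False)
        for (name, epoch_s), mr in result.results.items():
            stem = f"{name.lower()}_{epoch_s:g}s"
            mr.confusion.to_frame().to_csv(outdir / f"confusion_{stem}.csv")
            mr.metrics.per_class.to_csv(outdir / f"metrics_{stem}.csv")
            mr.tuned.cv_results.to_csv(outdir / f"cv_{stem}.csv", index=False)

        # --- importance for the top model of the longest epoch -----------
        top_epoch = max(tables)
        block = result.comparison[result.comparison["epoch_s"] == top_epoch]
        top_name = block.iloc[0]["model"]
        top = result.results[(top_name, top_epoch)]
        _, test = split_events(model_tables[top_epoch], split)
        imp = permutation_importance(top.tuned, test, repeats=cfg.importance_repeats,
                                     seed=_stage_seed(cfg.seed, "importance"))
        imp.to_csv(outdir / "importance.csv", index=False)
        logger.info("top model %s (%g s); most important feature: %s",
                    top_name, top_epoch, imp.iloc[0]["feature"])
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()
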