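"""End-to-end run orchestration: simulate -> trim -> fuse -> featurize -> bench.

``run_pipeline`` materializes a run directory containing the simulated
trial files, per-trial joint-angle series, the feature matrix (CSV and
ARFF), the benchmark table with per-classifier ROC exports and an SVG
ROC figure, plus a machine-readable manifest (config + seed + versions)
that, together with the seed, fully determines every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bench import CLASSIFIER_NAMES, CVConfig, run_cv, summarize
from .errors import ConfigError, ImuWristError
from .features import build_dataset, write_arff, write_csv
from .fusion import DriftConfig, FusionConfig, joint_angle_from_trial
from .io import trim_startup, write_manifest, write_trial
from .synth import CohortSpec, SensorNoiseModel, generate_cohort

log = logging.getLogger(__name__)

DEFAULT_CLASSIFIERS = [n for n in CLASSIFIER_NAMES]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one benchmark run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    noise: SensorNoiseModel = field(default_factory=SensorNoiseModel)
    trim_seconds: float = 1.0
    fusion: FusionConfig = field(default_factory=FusionConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    harmonic_mode: str = "peaks"
    cv: CVConfig = field(default_factory=CVConfig)
    classifiers: list = field(default_factory=lambda: list(DEFAULT_CLASSIFIERS))
    outdir: str = "runs/run"
    write_trials: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        try:
            kwargs = {}
            if "cohort" in doc:
                kwargs["cohort"] = CohortSpec(**doc["cohort"])
            if "noise" in doc:
                noise = dict(doc["noise"])
                for key in ("gyro_static_bias", "mag_field"):
                    if key in noise:
                        noise[key] = tuple(noise[key])
                kwargs["noise"] = SensorNoiseModel(**noise)
            if "fusion" in doc:
                kwargs["fusion"] = FusionConfig(**doc["fusion"])
            if "drift" in doc:
                kwargs["drift"] = DriftConfig(**doc["drift"])
            if "cv" in doc:
                kwargs["cv"] = CVConfig(**doc["cv"])
            for key in ("trim_seconds", "harmonic_mode", "classifiers",
                        "outdir", "write_trials"):
                if key in doc:
                    kwargs[key] = doc[key]
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"invalid pipeline config: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rom_report(trials, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Range-of-motion table: per-trial peak angle and angular range.

    Trials are trimmed and fused with the configured settings; rows hold
    (trial id, label, max_angle, range) in degrees.
    """
    config = config or PipelineConfig()
    records = []
    for i, trial in enumerate(trials):
        trimmed = trim_startup(trial, config.trim_seconds)
        cfg = dataclasses.replace(config.fusion, dt=1.0 / trimmed.fs)
        series = joint_angle_from_trial(trimmed, cfg, config.drift)
        records.append({
            "trial_id": trial.meta.get("trial_id", f"trial{i:04d}"),
            "label": trial.label,
            "max_angle": series.max_angle,
            "range": series.range,
        })
    return pd.DataFrame.from_records(records)


def _plot_roc(table, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, res in table.rows.items():
        fpr, tpr = res.roc[1]
        ax.plot(fpr, tpr, label=f"{name} (AUC {res.auc:.3f})", lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(config: PipelineConfig | None = None) -> str:
    """Execute the full pipeline; returns the run directory path.

    Stage failures propagate as the package's own exceptions, tagged in
    the log with the stage that raised them.
    """
    config = config or PipelineConfig()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("imuwrist")
    root.addHandler(handler)
    try:
        stage = "simulate"
        t0 = time.perf_counter()
        log.info("stage %s: cohort %d CP / %d typical, seed %d", stage,
                 config.cohort.n_cp, config.cohort.n_typical, config.cohort.seed)
        trials = generate_cohort(config.cohort, noise=config.noise)
        if config.write_trials:
            trial_dir = os.path.join(outdir, "trials")
            os.makedirs(trial_dir, exist_ok=True)
            pairs = []
            for i, trial in enumerate(trials):
                p = os.path.join(trial_dir, f"trial{i:04d}.csv")
                write_trial(trial, p)
                pairs.append((trial, os.path.relpath(p, outdir)))
            write_manifest(pairs, os.path.join(outdir, "dataset.yaml"))
        log.debug("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "angle"
        t0 = time.perf_counter()
        trimmed = [trim_startup(t, config.trim_seconds) for t in trials]
        rom = rom_report(trials, config)
        rom.to_csv(os.path.join(outdir, "rom_report.csv"), index=False)
        angle_dir = os.path.join(outdir, "joint_angles")
        os.makedirs(angle_dir, exist_ok=True)
        for i, trial in enumerate(trimmed[: min(len(trimmed), 10)]):
            cfg = dataclasses.replace(config.fusion, dt=1.0 / trial.fs)
            series = joint_angle_from_trial(trial, cfg, config.drift)
            pd.DataFrame({"time_s": series.t, "angle_deg": series.angle}).to_csv(
                os.path.join(angle_dir, f"trial{i:04d}_angle.csv"), index=False
            )
        log.debug("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "featurize"
        t0 = time.perf_counter()
        dataset = build_dataset(trimmed, mode=config.harmonic_mode)
        write_csv(dataset, os.path.join(outdir, "features.csv"))
        write_arff(dataset, os.path.join(outdir, "features.arff"))
        log.debug("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "bench"
        t0 = time.perf_counter()
        table = run_cv(dataset, config.classifiers, config.cv)
        summary = summarize(table)
        summary.to_csv(os.path.join(outdir, "benchmark.csv"), index=False)
        roc_dir = os.path.join(outdir, "roc")
        os.makedirs(roc_dir, exist_ok=True)
        for name, res in table.rows.items():
            fpr, tpr = res.roc[1]
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                os.path.join(roc_dir, f"{name}.csv"), index=False
            )
        _plot_roc(table, os.path.join(outdir, "roc_curves.svg"))
        log.debug("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        manifest = {
            "config": config.to_dict(),
            "seed": config.cohort.seed,
            "versions": {
                "imuwrist": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
            },
        }
        with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return outdir
    except ImuWristError:
        log.error("stage %s failed", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
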