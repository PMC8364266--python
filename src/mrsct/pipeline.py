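"""Top-level run configuration and the staged pipeline.

A run is fully described by one ``RunConfig`` (phantom spec, atlas options,
network and training hyperparameters, evaluation options, master seed).  The
pipeline executes simulate -> preprocess -> atlas -> crossval -> report,
each stage reading its inputs from the previous stage's output directory, so
any stage can be re-run in isolation and a run is reproducible from the
resolved configuration written next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import build_atlas
from .core import FAT, MUSCLE, TISSUES, Volume3D
from .evaluate import ExperimentConfig, cross_validate, plot_mae_vs_epoch, summarize
from .io import load_cohort, save_cohort, write_volume
from .model import UNetConfig
from .phantom import BoneEllipse, PhantomSpec, generate_cohort
from .preprocess import extract_landmarks, match_ct_intensity, standardize_mri
from .train import TrainConfig

STAGES = ("simulate", "preprocess", "atlas", "crossval", "report")


@dataclass
class RunConfig:
    """Composite configuration for one end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_patients: int = 12
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(depth=3, base_filters=16))
    train: TrainConfig = field(default_factory=TrainConfig)
    out_shape: tuple[int, int] = (96, 96)
    standardize: bool = False
    k_folds: int = 3
    eval_epochs: list[int] | None = None
    capacity_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        # The master seed drives every stochastic component.
        self.phantom = dataclasses.replace(self.phantom, seed=self.seed)
        self.train = dataclasses.replace(self.train, seed=self.seed)
        self.unet = dataclasses.replace(self.unet, seed=self.seed + 1)

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(
            unet=self.unet,
            train=self.train,
            out_shape=tuple(self.out_shape),
            standardize=self.standardize,
            eval_epochs=self.eval_epochs,
            capacity_window=self.capacity_window,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            if "bones" in ph:
                ph["bones"] = [BoneEllipse(**b) for b in ph["bones"]]
            for key in ("shape", "spacing", "body_semi_axes", "body_center_offset"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            for key in ("ct_stats", "mri_stats"):
                if key in ph:
                    ph[key] = {t: tuple(v) for t, v in ph[key].items()}
            raw["phantom"] = PhantomSpec(**ph)
        if "unet" in raw:
            raw["unet"] = UNetConfig(**raw["unet"])
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        if "out_shape" in raw:
            raw["out_shape"] = tuple(raw["out_shape"])
        return cls(**raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _log(out_dir: Path, stage: str, seconds: float, **info) -> None:
    entry = {"stage": stage, "seconds": round(seconds, 3), **info}
    with open(out_dir / "pipeline_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    cohort = generate_cohort(config.phantom, config.n_patients)
    save_cohort(cohort, out_dir / "phantoms")


def stage_preprocess(config: RunConfig, out_dir: Path) -> None:
    """Standardized MRI and intensity-matched CT per patient.

    These are the co-registration inputs of the clinical workflow; the
    phantom pairs are generated pre-aligned, so the products are written for
    inspection rather than consumed by later stages.
    """
    cohort = load_cohort(out_dir / "phantoms")
    dest = out_dir / "preprocessed"
    for patient in cohort:
        pdir = dest / f"patient_{patient.patient_id:03d}"
        pdir.mkdir(parents=True, exist_ok=True)
        landmarks = extract_landmarks(
            patient.mri, patient.labels == MUSCLE, patient.labels == FAT
        )
        write_volume(standardize_mri(patient.mri, landmarks), pdir / "mri_stdn.nii.gz")
        write_volume(match_ct_intensity(patient.ct, patient.body), pdir / "ct_matched.nii.gz")


def stage_atlas(config: RunConfig, out_dir: Path) -> None:
    """Whole-cohort atlas with per-patient CF/EF metadata and eq-maps."""
    cohort = load_cohort(out_dir / "phantoms")
    atlas = build_atlas(
        [(p.patient_id, p.mri, p.ct, p.body) for p in cohort], tuple(config.out_shape)
    )
    dest = out_dir / "atlas"
    dest.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, patient in enumerate(atlas.patients):
        pdir = dest / f"patient_{patient.patient_id:03d}"
        pdir.mkdir(parents=True, exist_ok=True)
        write_volume(patient.mri, pdir / "mri.nii.gz")
        write_volume(patient.ct, pdir / "ct.nii.gz")
        write_volume(Volume3D(patient.eqmap, patient.ct.spacing), pdir / "eqmap.nii.gz")
        row = {"patient": patient.patient_id, "slices": len(patient.examples)}
        for t in TISSUES:
            row[f"cf_{t}"] = atlas.weights.cfs[t][i]
        rows.append(row)
    meta = pd.DataFrame(rows)
    for t in TISSUES:
        meta[f"ef_{t}"] = atlas.weights.efs[t]
    meta.to_csv(dest / "metadata.csv", index=False)


def stage_crossval(config: RunConfig, out_dir: Path) -> None:
    cohort = load_cohort(out_dir / "phantoms")
    records = cross_validate(cohort, k=config.k_folds, config=config.experiment())
    records.to_csv(out_dir / "crossval_records.csv", index=False)


def stage_report(config: RunConfig, out_dir: Path) -> None:
    records = pd.read_csv(out_dir / "crossval_records.csv")
    summary = summarize(records, window=config.capacity_window)
    summary.to_csv(out_dir / "summary.csv", index=False)
    plot_mae_vs_epoch(records, out_dir / "mae_vs_epoch.png")


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "atlas": stage_atlas,
    "crossval": stage_crossval,
    "report": stage_report,
}


def pipeline_run(config: RunConfig, out_dir, stage: str | None = None) -> Path:
    """Run the full pipeline (or a single stage) into ``out_dir``.

    The resolved configuration and a code-version stamp are written next to
    the outputs, so every run directory is self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    (out_dir / "VERSION").write_text(f"mrsct {__version__}\n")
    stages = [stage] if stage else list(STAGES)
    for name in stages:
        if name not in _STAGE_FNS:
            raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
        t0 = time.time()
        try:
            _STAGE_FNS[name](config, out_dir)
        except Exception as exc:
            _log(out_dir, name, time.time() - t0, error=str(exc))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        _log(out_dir, name, time.time() - t0, seed=config.seed)
    return out_dir
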