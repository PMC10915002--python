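"""Containers, run configuration and the end-to-end pipeline driver.

Sessions travel as HDF5 files (one per session: traces, timestamps,
movement mask, metadata, optional motion energy and simulator ground
truth); cohorts are directories of those files plus a YAML manifest.
Feature tables, AUC tables, fold predictions and removal logs are CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .classify import (
    DEFAULT_FALSE_LABEL_FRACTION,
    DEFAULT_N_COMPONENTS,
    ClassifierConfig,
    FoldResult,
    loso_cv,
    pooled_pain_auc,
    pooled_predictions,
)
from .features import FeatureConfig, build_auc_table, extract_cohort_features
from .session import (
    STATES,
    CalciumSession,
    MotionEnergyTrace,
    SessionCohort,
    SessionGroundTruth,
)
from .simulate import SimulationConfig, generate_cohort

MANIFEST_NAME = "cohort.yaml"

_SESSION_DATASETS = ("fluorescence", "frame_times", "movement_mask")
_SESSION_ATTRS = ("subject_id", "state_label", "session_id")


class SchemaError(ValueError):
    """A session container is missing a required field."""


def write_session(
    session: CalciumSession,
    path: str | Path,
    ground_truth: SessionGroundTruth | None = None,
    motion_energy: MotionEnergyTrace | None = None,
) -> Path:
    """Write one session (and optional sidecars) to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("fluorescence", data=session.fluorescence)
        f.create_dataset("frame_times", data=session.frame_times)
        f.create_dataset("movement_mask", data=session.movement_mask.astype(np.uint8))
        for attr in _SESSION_ATTRS:
            f.attrs[attr] = getattr(session, attr)
        if motion_energy is not None:
            g = f.create_group("motion_energy")
            g.create_dataset("energy", data=motion_energy.energy)
            g.attrs["video_rate_hz"] = motion_energy.video_rate_hz
            if motion_energy.threshold is not None:
                g.attrs["threshold"] = motion_energy.threshold
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            for moving in (True, False):
                tag = "movement" if moving else "stationary"
                g.create_dataset(f"up_rois_{tag}",
                                 data=np.asarray(ground_truth.up_rois.get(moving, []), int))
                g.create_dataset(f"down_rois_{tag}",
                                 data=np.asarray(ground_truth.down_rois.get(moving, []), int))
            g.create_dataset("bout_intervals_s", data=ground_truth.bout_intervals_s)
            g.attrs["motion_threshold"] = ground_truth.motion_threshold
            g.attrs["mislabelled"] = bool(ground_truth.mislabelled)
    return path


def read_session(
    path: str | Path,
) -> tuple[CalciumSession, SessionGroundTruth | None, MotionEnergyTrace | None]:
    """Read a session container; sidecars are None when absent.

    Raises
    ------
    SchemaError
        Naming the first missing dataset or attribute.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _SESSION_DATASETS:
            if name not in f:
                raise SchemaError(f"{path.name}: missing dataset {name!r}")
        for attr in _SESSION_ATTRS:
            if attr not in f.attrs:
                raise SchemaError(f"{path.name}: missing attribute {attr!r}")
        session = CalciumSession(
            fluorescence=f["fluorescence"][()],
            frame_times=f["frame_times"][()],
            movement_mask=f["movement_mask"][()].astype(bool),
            subject_id=str(f.attrs["subject_id"]),
            state_label=str(f.attrs["state_label"]),
            session_id=str(f.attrs["session_id"]),
        )
        truth = energy = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            truth = SessionGroundTruth(
                up_rois={True: g["up_rois_movement"][()],
                         False: g["up_rois_stationary"][()]},
                down_rois={True: g["down_rois_movement"][()],
                           False: g["down_rois_stationary"][()]},
                bout_intervals_s=g["bout_intervals_s"][()],
                motion_threshold=float(g.attrs["motion_threshold"]),
                mislabelled=bool(g.attrs["mislabelled"]),
            )
        if "motion_energy" in f:
            g = f["motion_energy"]
            energy = MotionEnergyTrace(
                energy=g["energy"][()],
                video_rate_hz=float(g.attrs["video_rate_hz"]),
                threshold=float(g.attrs["threshold"]) if "threshold" in g.attrs else None,
            )
    return session, truth, energy


def _session_filename(session_id: str) -> str:
    return session_id.replace("/", "_") + ".h5"


def write_cohort(cohort: SessionCohort, out_dir: str | Path) -> Path:
    """Write a cohort as a directory of session HDF5 files plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for session in cohort:
        fname = _session_filename(session.session_id)
        write_session(
            session, out_dir / fname,
            ground_truth=cohort.ground_truth.get(session.session_id),
            motion_energy=cohort.motion_energy.get(session.session_id),
        )
        files[session.session_id] = fname
    manifest = {
        "sessions": files,
        "reference_ids": dict(cohort.reference_ids),
    }
    with open(out_dir / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out_dir


def read_cohort(in_dir: str | Path) -> SessionCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"missing cohort manifest {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    cohort = SessionCohort(sessions=[], reference_ids=dict(manifest["reference_ids"]))
    for session_id in sorted(manifest["sessions"]):
        session, truth, energy = read_session(in_dir / manifest["sessions"][session_id])
        cohort.sessions.append(session)
        if truth is not None:
            cohort.ground_truth[session_id] = truth
        if energy is not None:
            cohort.motion_energy[session_id] = energy
    return cohort


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run.

    Every pipeline constant is present and overridable: smoothing window 29,
    baseline percentile 30, D thresholds +0.3/−0.2, 6 principal components,
    false-label fraction 0.10.
    """

    seed: int = 0
    cohort_dir: str | None = None  # read instead of simulating when set
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_components: int = DEFAULT_N_COMPONENTS
    false_label_fraction: float = DEFAULT_FALSE_LABEL_FRACTION

    _SECTIONS = {"simulation": SimulationConfig, "features": FeatureConfig,
                 "classifier": ClassifierConfig}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config missing required field 'seed'")
        kwargs = {}
        for name, value in data.items():
            section = cls._SECTIONS.get(name)
            if section is not None and isinstance(value, dict):
                valid = {f.name for f in dataclasses.fields(section)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(
                        f"unknown {name} config field(s): {sorted(bad)}")
                if name == "classifier" and "hidden_layer_sizes" in value:
                    value = {**value,
                             "hidden_layer_sizes": tuple(value["hidden_layer_sizes"])}
                kwargs[name] = section(**value)
            else:
                kwargs[name] = value
        cfg = cls(**kwargs)
        # one root seed fans out: the simulator inherits it unless the config
        # pins its own
        if "seed" not in data.get("simulation", {}) or not isinstance(
                data.get("simulation"), dict):
            cfg.simulation.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


@dataclass
class PipelineResult:
    """Results bundle of one end-to-end run."""

    feature_table: pd.DataFrame
    auc_table: pd.DataFrame
    folds: list[FoldResult]
    predictions: pd.DataFrame
    removal_log: pd.DataFrame
    metrics: dict
    config: RunConfig


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow: cohort → features → AUC screen → LOSO-CV.

    With ``out_dir`` set, writes features.csv, auc_table.csv,
    fold_predictions.csv, removal_log.csv, metrics.yaml and a manifest.yaml
    holding the fully resolved configuration (re-running from the manifest
    reproduces the bundle bit for bit).
    """
    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    if config.cohort_dir is not None:
        cohort = _stage("load-cohort", lambda: read_cohort(config.cohort_dir))
    else:
        cohort = _stage("simulate", lambda: generate_cohort(config.simulation))

    feature_table = _stage(
        "features", lambda: extract_cohort_features(cohort, config.features))
    auc_table = _stage("auc-table", lambda: build_auc_table(feature_table))
    folds = _stage("loso", lambda: loso_cv(
        feature_table,
        seed=config.seed,
        filter_fraction=config.false_label_fraction,
        n_components=config.n_components,
        config=config.classifier,
    ))
    predictions = pooled_predictions(folds)
    removal_log = pd.concat(
        [f.removal_log.assign(fold=f.held_out_subject) for f in folds],
        ignore_index=True,
    )
    proba_cols = [f"p_{s}" for s in STATES]
    predicted_class = predictions[proba_cols].to_numpy().argmax(axis=1)
    accuracy = float(np.mean(
        [STATES[k] == lab for k, lab in zip(predicted_class, predictions["class_label"])]))
    metrics = {
        "pain_vs_rest_auc": pooled_pain_auc(folds),
        "multiclass_accuracy": accuracy,
        "n_sessions": int(len(predictions)),
        "n_subjects": int(feature_table["subject_id"].nunique()),
    }
    result = PipelineResult(
        feature_table=feature_table,
        auc_table=auc_table,
        folds=folds,
        predictions=predictions,
        removal_log=removal_log,
        metrics=metrics,
        config=config,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        feature_table.to_csv(out_dir / "features.csv", index=False)
        auc_table.to_csv(out_dir / "auc_table.csv", index_label="feature")
        predictions.to_csv(out_dir / "fold_predictions.csv", index=False)
        removal_log.to_csv(out_dir / "removal_log.csv", index=False)
        with open(out_dir / "metrics.yaml", "w") as fh:
            yaml.safe_dump(metrics, fh, sort_keys=True)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return result
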