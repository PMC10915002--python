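"""Core data containers for calcium-trace sessions and session pairs.

A *session* is one head-fixed two-photon recording: an ROI × frame
fluorescence matrix (~5 Hz) with a per-imaging-frame movement mask derived
from a 30 fps behaviour video, a subject identifier and a state label
(non-pain / pain / analgesic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three behavioural-state class labels used throughout the pipeline.
STATES = ("non-pain", "pain", "analgesic")

#: Frame-subset names for movement partitioning.
MOVEMENT_STATES = ("movement", "stationary", "total")

#: Normalization method names.
NORM_METHODS = ("zscore", "deltaF")


class SessionError(ValueError):
    """Raised when a session or session pair violates its contract."""


@dataclass
class CalciumSession:
    """One recording session of extracted per-ROI fluorescence traces.

    Parameters
    ----------
    fluorescence : (n_rois, n_frames) array
        Raw mean fluorescence per ROI per imaging frame, arbitrary units.
    frame_times : (n_frames,) array
        Imaging frame timestamps in seconds, strictly increasing.
    movement_mask : (n_frames,) bool array
        True where the animal was moving during that imaging frame.
    subject_id, state_label, session_id : str
        Animal identifier, behavioural-state class label, session name.
    """

    fluorescence: np.ndarray
    frame_times: np.ndarray
    movement_mask: np.ndarray
    subject_id: str
    state_label: str
    session_id: str

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.movement_mask = np.asarray(self.movement_mask, dtype=bool)
        if self.fluorescence.ndim != 2:
            raise SessionError("fluorescence must be a 2-D ROI x frame matrix")
        n_rois, n_frames = self.fluorescence.shape
        if n_rois < 2:
            raise SessionError(f"need >= 2 ROIs, got {n_rois}")
        if n_frames < 2:
            raise SessionError(f"need >= 2 frames, got {n_frames}")
        if self.frame_times.shape != (n_frames,):
            raise SessionError("frame_times length must equal frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise SessionError("frame_times must be strictly increasing")
        if self.movement_mask.shape != (n_frames,):
            raise SessionError("movement_mask length must equal frame count")
        if self.state_label not in STATES:
            raise SessionError(
                f"unknown state label {self.state_label!r}; expected one of {STATES}"
            )

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    def frame_subset_mask(self, movement_state: str) -> np.ndarray:
        """Boolean frame mask for ``movement`` / ``stationary`` / ``total``."""
        if movement_state == "movement":
            return self.movement_mask.copy()
        if movement_state == "stationary":
            return ~self.movement_mask
        if movement_state == "total":
            return np.ones(self.n_frames, dtype=bool)
        raise SessionError(
            f"unknown movement state {movement_state!r}; expected one of {MOVEMENT_STATES}"
        )


@dataclass
class NormalizedSession:
    """A session after smoothing and ΔF or Z-score normalization.

    ``baseline_mu`` / ``baseline_sigma`` are the per-ROI baseline statistics
    (mean and sd of the sub-30th-percentile frame set by default) used by the
    normalization formula.
    """

    signal: np.ndarray
    method: str
    baseline_mu: np.ndarray
    baseline_sigma: np.ndarray
    movement_mask: np.ndarray
    subject_id: str
    state_label: str
    session_id: str

    def __post_init__(self) -> None:
        if self.method not in NORM_METHODS:
            raise SessionError(
                f"unknown normalization {self.method!r}; expected one of {NORM_METHODS}"
            )
        self.signal = np.asarray(self.signal, dtype=float)
        self.movement_mask = np.asarray(self.movement_mask, dtype=bool)

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    def frame_subset_mask(self, movement_state: str) -> np.ndarray:
        if movement_state == "movement":
            return self.movement_mask.copy()
        if movement_state == "stationary":
            return ~self.movement_mask
        if movement_state == "total":
            return np.ones(self.n_frames, dtype=bool)
        raise SessionError(
            f"unknown movement state {movement_state!r}; expected one of {MOVEMENT_STATES}"
        )


@dataclass
class MotionEnergyTrace:
    """Per-video-frame motion energy: summed absolute inter-frame pixel change."""

    energy: np.ndarray
    video_rate_hz: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.ndim != 1:
            raise SessionError("motion energy must be a 1-D trace")
        if np.any(self.energy < 0):
            raise SessionError("motion energy must be nonnegative")
        if self.video_rate_hz <= 0:
            raise SessionError("video rate must be positive")


@dataclass
class SessionPair:
    """Evaluation session A against reference session B with matched ROIs.

    ``roi_map`` is an (m, 2) integer array of matched ROI indices
    (column 0 indexes A, column 1 indexes B); the mapping must be one-to-one.
    """

    session_a: CalciumSession
    session_b: CalciumSession
    roi_map: np.ndarray

    def __post_init__(self) -> None:
        self.roi_map = np.asarray(self.roi_map, dtype=int)
        if self.roi_map.ndim != 2 or self.roi_map.shape[1] != 2:
            raise SessionError("roi_map must be an (m, 2) index array")
        if self.roi_map.shape[0] < 2:
            raise SessionError("need >= 2 matched ROIs")
        for col, sess in ((0, self.session_a), (1, self.session_b)):
            idx = self.roi_map[:, col]
            if len(np.unique(idx)) != len(idx):
                raise SessionError("roi_map must be one-to-one")
            if idx.min() < 0 or idx.max() >= sess.n_rois:
                raise SessionError("roi_map index out of range")
        if self.session_a.subject_id != self.session_b.subject_id:
            raise SessionError("paired sessions must share a subject")

    @property
    def n_matched(self) -> int:
        return self.roi_map.shape[0]

    @staticmethod
    def identity_map(n_rois: int) -> np.ndarray:
        idx = np.arange(n_rois)
        return np.stack([idx, idx], axis=1)


@dataclass
class SessionGroundTruth:
    """Simulator sidecar: planted structure emitted next to a synthetic session.

    ``up_rois`` / ``down_rois`` map a movement condition (``True`` = moving)
    to the ROI indices whose event rate was multiplied / divided by the
    effect size under that condition. ``mislabelled`` marks sessions whose
    dynamics were deliberately generated under a different state than their
    label (for false-label-filter tests).
    """

    up_rois: dict[bool, np.ndarray] = field(default_factory=dict)
    down_rois: dict[bool, np.ndarray] = field(default_factory=dict)
    bout_intervals_s: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    motion_threshold: float = 0.0
    mislabelled: bool = False


@dataclass
class SessionCohort:
    """A collection of sessions across subjects, with simulator ground truth.

    ``reference_ids`` maps each subject to the session used as the
    matched-ROI reference (the subject's first non-pain session).
    """

    sessions: list[CalciumSession]
    ground_truth: dict[str, SessionGroundTruth] = field(default_factory=dict)
    motion_energy: dict[str, MotionEnergyTrace] = field(default_factory=dict)
    reference_ids: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def by_id(self, session_id: str) -> CalciumSession:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def reference_for(self, subject_id: str) -> CalciumSession:
        return self.by_id(self.reference_ids[subject_id])
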