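"""Synthetic cohort generator for somatosensory calcium-imaging sessions.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without animal recordings:

* slow GCaMP6s-like transients (Poisson event trains convolved with a
  double-exponential kernel) sampled at ~5 Hz,
* locomotion bouts, emitted both as an imaging-frame movement mask and as a
  30 Hz motion-energy trace for the movement detector,
* state-dependent fractions of up- and down-regulated ROIs, conditional on
  whether the animal is moving (larger during movement under pain; a
  distinct pattern under analgesics),
* a state-dependent shared latent drive controlling mean pairwise
  correlation (markedly stronger under analgesics).

Every session is emitted together with a ground-truth sidecar (planted
up/down ROI sets, bout intervals, motion threshold) so oracle tests can
recount planted structure directly.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .preprocessing import map_video_to_imaging
from .session import (
    STATES,
    CalciumSession,
    MotionEnergyTrace,
    SessionCohort,
    SessionError,
    SessionGroundTruth,
)

# Default up/down-regulated ROI fractions per (state, movement condition).
# Chosen to mirror the qualitative picture reported for S1 in pain states:
# during movement both up- and down-regulated fractions rise under pain and
# the analgesic state shows an even larger up-regulated fraction; when
# stationary only the down-regulated fraction rises under pain and returns
# to baseline under analgesics.
DEFAULT_UP_FRACTIONS = {
    "non-pain": {"movement": 0.0, "stationary": 0.0},
    "pain": {"movement": 0.25, "stationary": 0.05},
    "analgesic": {"movement": 0.35, "stationary": 0.05},
}
DEFAULT_DOWN_FRACTIONS = {
    "non-pain": {"movement": 0.0, "stationary": 0.0},
    "pain": {"movement": 0.25, "stationary": 0.20},
    "analgesic": {"movement": 0.15, "stationary": 0.0},
}
# Shared-drive weights: pairwise correlation is similar in non-pain and pain
# sessions but clearly different in the drug-induced analgesic state.
DEFAULT_DRIVE_WEIGHTS = {"non-pain": 0.15, "pain": 0.15, "analgesic": 0.5}


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash (CRC32), stable across processes."""
    return zlib.crc32(text.encode("utf8")) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Durations are in seconds, rates in Hz (or bouts/min where noted), and
    fluorescence quantities in arbitrary units matching the raw traces.
    """

    n_subjects: int = 8
    sessions_per_subject_per_state: int = 2
    n_rois: int = 60
    duration_s: float = 240.0
    imaging_rate_hz: float = 5.0
    video_rate_hz: float = 30.0
    movement_bout_rate: float = 4.0  # bouts per minute
    movement_bout_len_s: float = 3.0
    base_event_rate_hz: float = 0.1  # per ROI
    up_fractions: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_UP_FRACTIONS.items()})
    down_fractions: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_DOWN_FRACTIONS.items()})
    effect_size: float = 3.0
    shared_drive_weights: dict = field(default_factory=lambda: dict(DEFAULT_DRIVE_WEIGHTS))
    shared_drive_rate_hz: float = 0.3
    kernel_rise_s: float = 0.2   # GCaMP6s-like onset
    kernel_decay_s: float = 1.5  # GCaMP6s-like decay
    baseline_fluor_au: float = 100.0
    transient_amp_au: float = 30.0
    noise_sd: float = 2.0
    motion_threshold: float = 1.0
    pain_mislabel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_rois < 2:
            raise ValueError("need >= 1 subject and >= 2 ROIs")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for name in ("imaging_rate_hz", "video_rate_hz", "base_event_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.imaging_rate_hz >= self.video_rate_hz:
            raise ValueError("imaging rate must be below the video rate")
        if self.movement_bout_rate < 0 or self.movement_bout_len_s < 0:
            raise ValueError("movement bout parameters must be nonnegative")
        if not 0 <= self.pain_mislabel_fraction < 1:
            raise ValueError("pain_mislabel_fraction must be in [0, 1)")
        for state in STATES:
            for cond in ("movement", "stationary"):
                up = self.up_fraction(state, cond == "movement")
                down = self.down_fraction(state, cond == "movement")
                if up < 0 or down < 0:
                    raise ValueError("ROI fractions must be nonnegative")
                if up + down > 1:
                    raise ValueError(
                        f"up + down fraction > 1 for ({state}, {cond})")

    def up_fraction(self, state: str, moving: bool) -> float:
        return self.up_fractions[state]["movement" if moving else "stationary"]

    def down_fraction(self, state: str, moving: bool) -> float:
        return self.down_fractions[state]["movement" if moving else "stationary"]

    def shared_drive_weight(self, state: str) -> float:
        return self.shared_drive_weights[state]

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.imaging_rate_hz))

    def null(self) -> "SimulationConfig":
        """A matched null: no rate modulation, identical drive in all states."""
        cfg = copy.deepcopy(self)
        cfg.effect_size = 1.0
        w = self.shared_drive_weights["non-pain"]
        cfg.shared_drive_weights = {s: w for s in STATES}
        return cfg


def _subject_permutation(config: SimulationConfig, subject_id: str) -> np.ndarray:
    """Fixed per-subject ROI ordering: up sets are prefixes, down sets suffixes.

    Keeping the ordering fixed across a subject's sessions makes the
    matched-ROI modulation consistent between evaluation and reference
    sessions, which is what lets the activity-share difference detect it.
    """
    rng = np.random.default_rng([config.seed, _stable_hash(subject_id), 911])
    return rng.permutation(config.n_rois)


def _sample_bouts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Locomotion bout intervals as a (k, 2) array of video-frame indices.

    One bout is placed uniformly inside each of ``k`` equal time slots
    (stratified placement), so bouts never overlap and total coverage stays
    close to rate x length. Working in integer video-frame units keeps the
    imaging mask and the motion-energy trace exactly frame-consistent.
    """
    n_bouts = int(round(config.movement_bout_rate * config.duration_s / 60.0))
    if n_bouts == 0 or config.movement_bout_len_s == 0:
        return np.empty((0, 2), dtype=int)
    slot = config.duration_s / n_bouts
    len_frames = int(np.floor(
        min(config.movement_bout_len_s, slot) * config.video_rate_hz))
    n_video = int(round(config.duration_s * config.video_rate_hz))
    intervals = []
    for k in range(n_bouts):
        lo_s = k * slot + rng.uniform(0, slot - len_frames / config.video_rate_hz)
        start = int(np.floor(lo_s * config.video_rate_hz))
        end = min(start + len_frames, n_video)
        intervals.append((start, end))
    return np.asarray(intervals, dtype=int)


def _calcium_kernel(config: SimulationConfig) -> np.ndarray:
    """Double-exponential indicator kernel sampled at the imaging rate, peak 1."""
    dt = 1.0 / config.imaging_rate_hz
    t = np.arange(0.0, config.kernel_rise_s + 6.0 * config.kernel_decay_s, dt)
    k = (1.0 - np.exp(-t / config.kernel_rise_s)) * np.exp(-t / config.kernel_decay_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate calcium kernel")
    return k / peak


def generate_session(
    config: SimulationConfig,
    subject_id: str,
    state: str,
    seed: int,
    dynamics_state: str | None = None,
) -> tuple[CalciumSession, SessionGroundTruth, MotionEnergyTrace]:
    """Simulate one recording session.

    ``state`` is the label attached to the session; ``dynamics_state``
    (defaulting to ``state``) controls the generative dynamics, which lets a
    cohort plant mislabelled sessions whose label and dynamics disagree.

    Returns the session plus its ground-truth sidecar and a motion-energy
    trace at the video rate whose planted threshold recovers the movement
    mask exactly.
    """
    if state not in STATES:
        raise SessionError(f"unknown state {state!r}; expected one of {STATES}")
    dyn = dynamics_state if dynamics_state is not None else state
    if dyn not in STATES:
        raise SessionError(f"unknown dynamics state {dyn!r}")

    rng = np.random.default_rng(
        [config.seed, _stable_hash(subject_id), int(seed), 7919])
    n_rois, n_frames = config.n_rois, config.n_frames
    dt = 1.0 / config.imaging_rate_hz
    frame_times = np.arange(n_frames) * dt

    # --- movement ---------------------------------------------------------
    bout_idx = _sample_bouts(config, rng)
    n_video = int(round(config.duration_s * config.video_rate_hz))
    video_frame = np.arange(n_video)
    video_in_bout = np.zeros(n_video, dtype=bool)
    for start, end in bout_idx:
        video_in_bout[(video_frame >= start) & (video_frame < end)] = True
    # the imaging mask is the video mask seen through the same interval
    # mapping the preprocessing stage uses, so the two stay consistent
    movement_mask = map_video_to_imaging(
        video_in_bout, config.video_rate_hz, frame_times)
    bouts = bout_idx / config.video_rate_hz
    thr = config.motion_threshold
    energy = np.where(
        video_in_bout,
        thr * rng.uniform(1.3, 3.0, size=n_video),
        thr * rng.uniform(0.1, 0.7, size=n_video),
    )

    # --- planted rate modulation -----------------------------------------
    perm = _subject_permutation(config, subject_id)
    up_rois: dict[bool, np.ndarray] = {}
    down_rois: dict[bool, np.ndarray] = {}
    for moving in (True, False):
        n_up = int(round(config.up_fraction(dyn, moving) * n_rois))
        n_down = int(round(config.down_fraction(dyn, moving) * n_rois))
        up_rois[moving] = np.sort(perm[:n_up])
        down_rois[moving] = np.sort(perm[n_rois - n_down:]) if n_down else np.empty(0, int)

    base_p = config.base_event_rate_hz * dt
    rate = np.full((n_rois, n_frames), base_p)
    for moving in (True, False):
        cols = movement_mask if moving else ~movement_mask
        if not cols.any():
            continue
        rate[np.ix_(up_rois[moving], cols)] *= config.effect_size
        rate[np.ix_(down_rois[moving], cols)] /= config.effect_size

    # --- fluorescence -----------------------------------------------------
    events = rng.poisson(rate).astype(float)
    kernel = _calcium_kernel(config)
    transients = fftconvolve(events, kernel[None, :], mode="full")[:, :n_frames]

    drive_events = rng.poisson(config.shared_drive_rate_hz * dt, size=n_frames).astype(float)
    drive = np.convolve(drive_events, kernel, mode="full")[:n_frames]
    w = config.shared_drive_weight(dyn)

    fluor = (
        config.baseline_fluor_au
        + config.transient_amp_au * (transients + w * drive[None, :])
        + rng.normal(0.0, config.noise_sd, size=(n_rois, n_frames))
    )
    np.maximum(fluor, 0.0, out=fluor)

    session = CalciumSession(
        fluorescence=fluor,
        frame_times=frame_times,
        movement_mask=movement_mask,
        subject_id=subject_id,
        state_label=state,
        session_id=f"{subject_id}/{state}/{seed}",
    )
    truth = SessionGroundTruth(
        up_rois=up_rois,
        down_rois=down_rois,
        bout_intervals_s=bouts,
        motion_threshold=thr,
        mislabelled=(dyn != state),
    )
    return session, truth, MotionEnergyTrace(energy, config.video_rate_hz, thr)


def generate_cohort(config: SimulationConfig) -> SessionCohort:
    """Simulate a full multi-subject cohort.

    Every subject contributes ``sessions_per_subject_per_state`` sessions of
    each state; the first non-pain session is that subject's matched-ROI
    reference. ROI matching across a subject's sessions is the identity.
    With ``pain_mislabel_fraction`` > 0 the corresponding fraction of
    pain-labelled sessions is generated with non-pain dynamics and flagged
    in the ground truth.
    """
    subjects = [f"m{idx:02d}" for idx in range(config.n_subjects)]
    planned: list[tuple[str, str, int]] = []
    for subj in subjects:
        for state in STATES:
            for rep in range(config.sessions_per_subject_per_state):
                planned.append((subj, state, rep))

    pain_slots = [i for i, (_, st, _) in enumerate(planned) if st == "pain"]
    n_mislabel = int(np.floor(config.pain_mislabel_fraction * len(pain_slots)))
    rng = np.random.default_rng([config.seed, 40487])
    mislabel_set = set(
        rng.choice(pain_slots, size=n_mislabel, replace=False)) if n_mislabel else set()

    cohort = SessionCohort(sessions=[])
    for i, (subj, state, rep) in enumerate(planned):
        child_seed = int(
            np.random.default_rng(
                [config.seed, _stable_hash(subj), STATES.index(state), rep]
            ).integers(0, 2**31)
        )
        dyn = "non-pain" if i in mislabel_set else None
        session, truth, energy = generate_session(
            config, subj, state, seed=child_seed, dynamics_state=dyn)
        session.session_id = f"{subj}_{state}_{rep}"
        cohort.sessions.append(session)
        cohort.ground_truth[session.session_id] = truth
        cohort.motion_energy[session.session_id] = energy
        if state == "non-pain" and rep == 0:
            cohort.reference_ids[subj] = session.session_id
    return cohort
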