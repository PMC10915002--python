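"""Handcrafted features from session pairs and per-feature AUC screens.

The core statistic is the per-ROI *activity-share difference* D between an
evaluation session A and a reference session B. For matched ROI i among n
matched ROIs,

    D_i = (X_i / Σ_j X_j)_A − (X_i / Σ_j X_j)_B,

where X_i is ROI i's mean normalized signal (ΔF or Z-score) over a frame
subset (movement / stationary / total frames), floored at zero so the
shares form a distribution. Shares sum to one in each session, hence
Σ_i D_i = 0. ROIs are called up-regulated when their relative activity
change exceeds +0.3 and down-regulated below −0.2 (both thresholds on the
per-cell scale n·D_i; see ``cell_ratios``/``extract_features``). The up and
down cell fractions over 2 normalizations × 3 movement partitions give 12
ratio features; the mean pairwise Pearson correlation of the evaluation
session's ROIs is the 13th.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocessing import DEFAULT_BASELINE_PERCENTILE, DEFAULT_WINDOW, normalize, smooth
from .session import (
    MOVEMENT_STATES,
    CalciumSession,
    NormalizedSession,
    SessionCohort,
    SessionError,
    SessionPair,
)

DEFAULT_UP_THRESHOLD = 0.3
DEFAULT_DOWN_THRESHOLD = -0.2

#: Frozen feature order: 12 cell-ratio features (normalization x dynamics x
#: movement partition) followed by the correlation feature.
FEATURE_NAMES = tuple(
    f"{method}_{dyn}_{ms}"
    for method in ("zscore", "deltaF")
    for dyn in ("up", "down")
    for ms in MOVEMENT_STATES
) + ("correlation",)

RATIO_FEATURE_NAMES = FEATURE_NAMES[:-1]

#: Metadata columns preceding the features in a cohort feature table.
META_COLUMNS = ("session_id", "subject_id", "class_label", "reference_id")


class EmptySubsetError(SessionError):
    """A movement-partition frame subset contains no frames."""


class DegenerateSessionError(SessionError):
    """Total floored activity is (numerically) zero; shares undefined."""


@dataclass
class FeatureConfig:
    """Tunable constants of the feature stage.

    ``up_threshold`` / ``down_threshold`` are the D cut-offs (+0.3 / −0.2);
    ``d_cell_scale='n'`` applies them to n·D_i, i.e. to the ROI's activity
    change relative to the session-mean activity, so that fixed thresholds
    remain meaningful regardless of ROI count (``'raw'`` thresholds the
    share difference itself).
    """

    window: int = DEFAULT_WINDOW
    baseline_percentile: float = DEFAULT_BASELINE_PERCENTILE
    baseline_mode: str = "subset-mean"
    up_threshold: float = DEFAULT_UP_THRESHOLD
    down_threshold: float = DEFAULT_DOWN_THRESHOLD
    d_cell_scale: str = "n"

    def __post_init__(self) -> None:
        if self.up_threshold <= self.down_threshold:
            raise ValueError("up threshold must exceed down threshold")
        if self.d_cell_scale not in ("n", "raw"):
            raise ValueError("d_cell_scale must be 'n' or 'raw'")


def activity_shares(
    session: NormalizedSession,
    movement_state: str,
    roi_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-ROI share of total activity over one frame subset.

    Each ROI's normalized signal is averaged over the subset frames, floored
    at zero, and divided by the total across the selected ROIs; the result
    sums to one.
    """
    mask = session.frame_subset_mask(movement_state)
    if not mask.any():
        raise EmptySubsetError(
            f"session {session.session_id}: no {movement_state} frames")
    signal = session.signal if roi_indices is None else session.signal[roi_indices]
    if signal.shape[0] < 2:
        raise SessionError("need >= 2 ROIs for activity shares")
    means = signal[:, mask].mean(axis=1)
    floored = np.maximum(means, 0.0)
    total = floored.sum()
    if total <= 1e-12:
        raise DegenerateSessionError(
            f"session {session.session_id}: total {movement_state} activity "
            "is zero after flooring")
    return floored / total


def compute_d(pair: SessionPair, movement_state: str) -> np.ndarray:
    """Activity-share difference D over the matched ROIs of a session pair.

    Both sessions must be normalized with the same method. The returned
    vector has one entry per matched ROI and sums to zero.
    """
    a, b = pair.session_a, pair.session_b
    if not isinstance(a, NormalizedSession) or not isinstance(b, NormalizedSession):
        raise SessionError("compute_d expects normalized sessions")
    if a.method != b.method:
        raise SessionError(
            f"normalization mismatch: {a.method!r} vs {b.method!r}")
    shares_a = activity_shares(a, movement_state, pair.roi_map[:, 0])
    shares_b = activity_shares(b, movement_state, pair.roi_map[:, 1])
    return shares_a - shares_b


def cell_ratios(
    d: np.ndarray,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> tuple[float, float, float]:
    """Fractions of up-regulated, down-regulated and stable ROIs.

    up = |{i : D_i > up_threshold}| / n, down = |{i : D_i < down_threshold}| / n,
    stable = 1 − up − down. Thresholds with up ≤ down are rejected.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty D vector")
    if up_threshold <= down_threshold:
        raise ValueError("up threshold must exceed down threshold")
    n = d.size
    up = float(np.count_nonzero(d > up_threshold)) / n
    down = float(np.count_nonzero(d < down_threshold)) / n
    return up, down, 1.0 - up - down


def correlation_feature(session: NormalizedSession | np.ndarray) -> float:
    """Mean pairwise Pearson correlation across all ROI pairs of a session.

    Zero-variance ROIs are excluded with a warning; fewer than two usable
    ROIs is an error.
    """
    signal = session.signal if isinstance(session, NormalizedSession) else np.asarray(session, float)
    if signal.ndim != 2 or signal.shape[0] < 2:
        raise SessionError("need an ROI x frame matrix with >= 2 ROIs")
    if signal.shape[1] < 3:
        raise SessionError("need >= 3 frames for a correlation estimate")
    variances = signal.var(axis=1)
    usable = variances > 0
    if not usable.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~usable)} zero-variance ROI(s) "
            "from the correlation feature", stacklevel=2)
    signal = signal[usable]
    if signal.shape[0] < 2:
        raise SessionError("fewer than 2 ROIs with nonzero variance")
    corr = np.corrcoef(signal)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(corr[iu].mean())


def extract_features(
    session_a: CalciumSession,
    session_b: CalciumSession,
    roi_map: np.ndarray | None = None,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """The 13-feature vector for one evaluation/reference session pair.

    Order is frozen as ``FEATURE_NAMES``: Z-score up (movement, stationary,
    total), Z-score down (…), ΔF up (…), ΔF down (…), correlation. The
    correlation feature is the mean pairwise correlation of session A's
    smoothed ΔF traces over all frames. If a session has no movement (or no
    stationary) frames the affected cell-ratio features are returned as NaN,
    to be imputed with training-set means downstream.
    """
    config = config or FeatureConfig()
    if roi_map is None:
        if session_a.n_rois != session_b.n_rois:
            raise SessionError("roi_map required when ROI counts differ")
        roi_map = SessionPair.identity_map(session_a.n_rois)

    smoothed = {
        "a": smooth(session_a.fluorescence, config.window),
        "b": smooth(session_b.fluorescence, config.window),
    }
    normalized: dict[tuple[str, str], NormalizedSession] = {}
    for method in ("zscore", "deltaF"):
        for key, sess in (("a", session_a), ("b", session_b)):
            normalized[(method, key)] = normalize(
                sess, method,
                window=config.window,
                percentile=config.baseline_percentile,
                baseline_mode=config.baseline_mode,
                presmoothed=smoothed[key],
            )

    n_matched = np.asarray(roi_map).shape[0]
    scale = float(n_matched) if config.d_cell_scale == "n" else 1.0
    values: dict[str, float] = {}
    for method in ("zscore", "deltaF"):
        pair = SessionPair(normalized[(method, "a")], normalized[(method, "b")], roi_map)
        for ms in MOVEMENT_STATES:
            try:
                d = compute_d(pair, ms)
                up, down, _ = cell_ratios(
                    scale * d, config.up_threshold, config.down_threshold)
            except EmptySubsetError:
                up = down = float("nan")
            values[f"{method}_up_{ms}"] = up
            values[f"{method}_down_{ms}"] = down

    values["correlation"] = correlation_feature(normalized[("deltaF", "a")])
    return pd.Series([values[name] for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), dtype=float)


def extract_cohort_features(
    cohort: SessionCohort,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per evaluation session.

    Every session is paired against its subject's reference session (the
    designated pre-treatment non-pain session) via the identity ROI map;
    the reference sessions themselves are not evaluated.
    """
    rows = []
    for session in cohort:
        ref_id = cohort.reference_ids.get(session.subject_id)
        if ref_id is None:
            raise SessionError(f"no reference session for subject {session.subject_id}")
        if session.session_id == ref_id:
            continue
        reference = cohort.by_id(ref_id)
        feats = extract_features(session, reference, config=config)
        meta = pd.Series(
            [session.session_id, session.subject_id, session.state_label, ref_id],
            index=list(META_COLUMNS),
        )
        rows.append(pd.concat([meta, feats]))
    if not rows:
        raise SessionError("cohort contains no evaluable session pairs")
    table = pd.DataFrame(rows).reset_index(drop=True)
    table[list(FEATURE_NAMES)] = table[list(FEATURE_NAMES)].astype(float)
    return table


def feature_auc(values: np.ndarray, is_positive: np.ndarray) -> float:
    """ROC-AUC of one scalar feature for a binary contrast.

    Computed as the tie-aware Mann-Whitney U statistic divided by n1·n2:
    the probability that a positive-group value exceeds a negative-group
    value, counting ties as one half. Raw orientation (0.5 = chance, values
    below 0.5 mean the feature ranks positives lower).
    """
    values = np.asarray(values, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if values.shape != is_positive.shape:
        raise ValueError("values and labels must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both contrast groups must be nonempty")
    ranks = rankdata(values)  # average ranks handle ties
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


#: The three screening contrasts; positive class is always pain.
DEFAULT_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "baseline_vs_pain": (("pain",), ("non-pain",)),
    "pain_vs_analgesics": (("pain",), ("analgesic",)),
    "pain_vs_analgesics_baseline": (("pain",), ("analgesic", "non-pain")),
}


def build_auc_table(
    feature_table: pd.DataFrame,
    contrasts: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
) -> pd.DataFrame:
    """Per-feature AUC for each screening contrast (13 rows × contrasts).

    Sessions pool raw across the groups named in each contrast; rows with a
    NaN feature value are dropped for that feature only.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    labels = feature_table["class_label"].to_numpy()
    out = {}
    for cname, (pos_states, neg_states) in contrasts.items():
        pos = np.isin(labels, pos_states)
        neg = np.isin(labels, neg_states)
        if not pos.any() or not neg.any():
            raise ValueError(f"contrast {cname!r}: a group is empty")
        keep = pos | neg
        col = []
        for fname in FEATURE_NAMES:
            vals = feature_table[fname].to_numpy()[keep]
            ok = ~np.isnan(vals)
            col.append(feature_auc(vals[ok], pos[keep][ok]))
        out[cname] = col
    return pd.DataFrame(out, index=list(FEATURE_NAMES))
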