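"""Activity shares, the D statistic, cell ratios, correlation and AUC screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paintrace import (
    FEATURE_NAMES,
    SessionPair,
    SimulationConfig,
    activity_shares,
    build_auc_table,
    cell_ratios,
    compute_d,
    correlation_feature,
    extract_cohort_features,
    extract_features,
    feature_auc,
    generate_cohort,
    generate_session,
)
from paintrace.features import (
    RATIO_FEATURE_NAMES,
    DegenerateSessionError,
    EmptySubsetError,
)
from paintrace.session import STATES, NormalizedSession, SessionError

from conftest import make_feature_table


def make_normalized(signal, mask=None, subject="m00", sid="test"):
    signal = np.asarray(signal, dtype=float)
    n_rois, n_frames = signal.shape
    if mask is None:
        mask = np.zeros(n_frames, dtype=bool)
        mask[: n_frames // 2] = True
    return NormalizedSession(
        signal=signal,
        method="deltaF",
        baseline_mu=np.ones(n_rois),
        baseline_sigma=np.ones(n_rois),
        movement_mask=np.asarray(mask, bool),
        subject_id=subject,
        state_label="non-pain",
        session_id=sid,
    )


# --- activity shares ------------------------------------------------------

def test_activity_shares_arithmetic():
    sess = make_normalized(np.array([[3.0] * 10, [1.0] * 10]))
    np.testing.assert_allclose(activity_shares(sess, "total"), [0.75, 0.25])


def test_activity_shares_symmetry():
    sess = make_normalized(np.full((5, 20), 2.0))
    np.testing.assert_allclose(activity_shares(sess, "movement"), np.full(5, 0.2))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_activity_shares_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_rois, n_frames = int(rng.integers(2, 12)), int(rng.integers(10, 60))
    signal = rng.normal(size=(n_rois, n_frames))
    mask = np.zeros(n_frames, bool)
    mask[rng.choice(n_frames, size=max(1, n_frames // 3), replace=False)] = True
    sess = make_normalized(signal, mask)
    # brute-force oracle: per-frame accumulation then renormalization
    means = np.array([
        sum(signal[r, f] for f in range(n_frames) if mask[f]) / mask.sum()
        for r in range(n_rois)])
    floored = np.maximum(means, 0.0)
    if floored.sum() <= 1e-12:
        with pytest.raises(DegenerateSessionError):
            activity_shares(sess, "movement")
        return
    shares = activity_shares(sess, "movement")
    np.testing.assert_allclose(shares, floored / floored.sum(), atol=1e-12)
    assert shares.sum() == pytest.approx(1.0)


def test_activity_shares_empty_subset_error():
    sess = make_normalized(np.ones((3, 10)), mask=np.zeros(10, bool))
    with pytest.raises(EmptySubsetError, match="no movement frames"):
        activity_shares(sess, "movement")


def test_activity_shares_degenerate_after_flooring():
    sess = make_normalized(-np.ones((3, 10)))
    with pytest.raises(DegenerateSessionError):
        activity_shares(sess, "total")


# --- D statistic ----------------------------------------------------------

def pair_of(a_signal, b_signal, mask=None):
    a = make_normalized(a_signal, mask, sid="A")
    b = make_normalized(b_signal, mask, sid="B")
    return SessionPair(a, b, SessionPair.identity_map(a.n_rois))


def test_compute_d_identity_pair_is_zero():
    signal = np.random.default_rng(1).gamma(2, 1, size=(6, 40))
    d = compute_d(pair_of(signal, signal), "total")
    np.testing.assert_allclose(d, 0.0, atol=1e-12)


def test_compute_d_share_arithmetic():
    # shares A = (0.7, 0.3), B = (0.5, 0.5) -> D = (0.2, -0.2)
    d = compute_d(pair_of([[7.0] * 10, [3.0] * 10], [[1.0] * 10, [1.0] * 10]), "total")
    np.testing.assert_allclose(d, [0.2, -0.2], atol=1e-12)


def test_compute_d_sums_to_zero_and_negates_on_swap():
    rng = np.random.default_rng(5)
    a_sig = rng.gamma(2, 1, size=(8, 50))
    b_sig = rng.gamma(2, 1, size=(8, 50))
    pair = pair_of(a_sig, b_sig)
    d = compute_d(pair, "total")
    assert abs(d.sum()) < 1e-9
    swapped = SessionPair(pair.session_b, pair.session_a, pair.roi_map[:, ::-1])
    np.testing.assert_allclose(compute_d(swapped, "total"), -d, atol=1e-12)


def test_compute_d_rejects_method_mismatch():
    pair = pair_of(np.ones((2, 10)), np.ones((2, 10)))
    pair.session_b.method = "zscore"
    with pytest.raises(SessionError, match="mismatch"):
        compute_d(pair, "total")


# --- cell ratios ----------------------------------------------------------

def test_cell_ratios_direct_counts():
    assert cell_ratios(np.array([0.5, -0.5, 0.0])) == (
        pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3))
    assert cell_ratios(np.zeros(7)) == (0.0, 0.0, 1.0)


def test_cell_ratios_rejects_crossed_thresholds():
    with pytest.raises(ValueError):
        cell_ratios(np.array([0.1]), up_threshold=-0.2, down_threshold=0.3)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_cell_ratios_matches_brute_force_and_sums_to_one(seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(scale=0.5, size=rng.integers(1, 40))
    down_thr, up_thr = sorted(rng.uniform(-1, 1, size=2))
    if up_thr == down_thr:
        return
    up, down, stable = cell_ratios(d, up_thr, down_thr)
    assert up == sum(1 for x in d if x > up_thr) / d.size
    assert down == sum(1 for x in d if x < down_thr) / d.size
    assert up + down + stable == 1.0  # exact


def test_cell_ratios_monotone_in_up_threshold():
    rng = np.random.default_rng(2)
    d = rng.normal(scale=0.5, size=100)
    ups = [cell_ratios(d, thr, -1.5)[0] for thr in np.linspace(-1.0, 1.0, 21)]
    assert all(a >= b for a, b in zip(ups, ups[1:]))


# --- correlation feature --------------------------------------------------

def test_correlation_feature_extremes():
    t = np.sin(np.linspace(0, 8 * np.pi, 200))
    assert correlation_feature(np.stack([t, t])) == pytest.approx(1.0)
    assert correlation_feature(np.stack([t, -t])) == pytest.approx(-1.0)


def test_correlation_feature_matches_pairwise_loop_oracle():
    rng = np.random.default_rng(8)
    signal = rng.normal(size=(10, 150))
    expected = np.mean([
        np.corrcoef(signal[i], signal[j])[0, 1]
        for i in range(10) for j in range(i + 1, 10)])
    assert correlation_feature(signal) == pytest.approx(expected, abs=1e-12)


def test_correlation_feature_excludes_zero_variance_rois():
    signal = np.vstack([np.ones(50), np.sin(np.arange(50.0)), np.cos(np.arange(50.0))])
    with pytest.warns(UserWarning, match="zero-variance"):
        value = correlation_feature(signal)
    expected = np.corrcoef(signal[1], signal[2])[0, 1]
    assert value == pytest.approx(expected)
    with pytest.raises(SessionError, match="nonzero variance"):
        with pytest.warns(UserWarning):
            correlation_feature(np.vstack([np.ones(50), np.ones(50) * 2, np.sin(np.arange(50.0))]))


# --- feature vector -------------------------------------------------------

def test_extract_features_names_and_count(small_cohort):
    sessions = small_cohort.sessions
    feats = extract_features(sessions[1], sessions[0])
    assert list(feats.index) == list(FEATURE_NAMES)
    assert len(feats) == 13
    assert len(RATIO_FEATURE_NAMES) == 12


def test_extract_features_identity_pair_all_ratio_features_zero(small_cohort):
    session = small_cohort.sessions[0]
    feats = extract_features(session, session)
    for name in RATIO_FEATURE_NAMES:
        assert feats[name] == 0.0
    assert -1.0 <= feats["correlation"] <= 1.0


def test_extract_features_empty_movement_subset_is_nan():
    cfg = SimulationConfig(n_subjects=1, n_rois=8, duration_s=30.0,
                           movement_bout_rate=0.0, seed=3)
    a, _, _ = generate_session(cfg, "m00", "pain", seed=1)
    b, _, _ = generate_session(cfg, "m00", "non-pain", seed=2)
    feats = extract_features(a, b)
    for name in RATIO_FEATURE_NAMES:
        if name.endswith("_movement"):
            assert np.isnan(feats[name])
        else:
            assert np.isfinite(feats[name])


# --- feature AUC ----------------------------------------------------------

def test_feature_auc_extremes():
    assert feature_auc(np.array([3.0, 4, 5, 0, 1, 2]),
                       np.array([1, 1, 1, 0, 0, 0], bool)) == 1.0
    same = np.array([1.0, 1, 1, 1])
    assert feature_auc(same, np.array([1, 1, 0, 0], bool)) == 0.5


def test_feature_auc_rejects_empty_group():
    with pytest.raises(ValueError, match="nonempty"):
        feature_auc(np.ones(3), np.ones(3, bool))


def test_feature_auc_matches_all_pairs_oracle_and_sklearn():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(123)
    for _ in range(100):
        n1, n2 = rng.integers(2, 15, size=2)
        pos = rng.normal(0.2, 1, size=n1).round(1)  # rounding forces ties
        neg = rng.normal(0.0, 1, size=n2).round(1)
        values = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)])
        brute = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg])
        auc = feature_auc(values, labels)
        assert auc == pytest.approx(brute, abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)


# --- AUC table ------------------------------------------------------------

def test_auc_table_null_cohort_near_chance():
    rng = np.random.default_rng(44)
    table = make_feature_table(rng, {"non-pain": 60, "pain": 60, "analgesic": 60},
                               pain_shift=0.0)
    table["correlation"] = rng.uniform(0, 1, size=len(table))  # no class shift
    auc = build_auc_table(table)
    assert auc.shape == (13, 3)
    assert ((auc - 0.5).abs() < 0.15).all().all()


def test_auc_table_movement_specific_planted_effect():
    """Movement-only pain modulation: movement features screen better than
    stationary ones in the baseline-vs-pain contrast."""
    up = {"non-pain": {"movement": 0.0, "stationary": 0.0},
          "pain": {"movement": 0.3, "stationary": 0.0},
          "analgesic": {"movement": 0.0, "stationary": 0.0}}
    down = {s: {"movement": 0.0, "stationary": 0.0} for s in STATES}
    cfg = SimulationConfig(n_subjects=6, sessions_per_subject_per_state=1,
                           n_rois=40, duration_s=120.0, up_fractions=up,
                           down_fractions=down,
                           shared_drive_weights={s: 0.1 for s in STATES}, seed=6)
    # per_state=1 leaves no non-pain rows; add an extra non-pain session each
    cohort = generate_cohort(cfg)
    from paintrace.simulate import generate_session as gen
    for subj in cohort.subjects:
        extra, truth, energy = gen(cfg, subj, "non-pain", seed=123456)
        extra.session_id = f"{subj}_non-pain_extra"
        cohort.sessions.append(extra)
        cohort.ground_truth[extra.session_id] = truth
    table = extract_cohort_features(cohort)
    auc = build_auc_table(table)
    col = auc["baseline_vs_pain"]
    assert col["deltaF_up_movement"] > col["deltaF_up_stationary"]
    assert col["zscore_up_movement"] > col["zscore_up_stationary"]


def test_auc_table_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    table = make_feature_table(rng, {"non-pain": 10, "pain": 10, "analgesic": 10})
    auc = build_auc_table(table)
    path = tmp_path / "auc.csv"
    auc.to_csv(path, index_label="feature")
    back = pd.read_csv(path, index_col="feature")
    pd.testing.assert_frame_equal(auc, back, check_names=False)


def test_auc_table_missing_group_rejected():
    rng = np.random.default_rng(10)
    table = make_feature_table(rng, {"non-pain": 10, "pain": 10})
    with pytest.raises(ValueError, match="empty"):
        build_auc_table(table)
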