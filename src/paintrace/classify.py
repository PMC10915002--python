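"""PCA reduction, three-class dense classifier, false-label management and
leave-one-subject-out cross-validation.

The 13 handcrafted features are standardized and condensed to 6 principal
components (all of which are used), then fed to a small dense-layer network
that outputs class probabilities for non-pain / pain / analgesic. The
probability assigned to the pain class is the session's *predicted pain
value*. Because spontaneous pain cannot be guaranteed present throughout a
pain-labelled recording, a false-label pass trains on everything, scores
every pain-labelled session and drops the bottom fraction (10% by default)
before the real training. Validation is leave-one-subject-out: all sessions
of one animal form the test set of a fold, and filtering, PCA fitting and
classifier training see only the remaining subjects.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .features import FEATURE_NAMES, feature_auc
from .session import STATES

DEFAULT_N_COMPONENTS = 6
DEFAULT_FALSE_LABEL_FRACTION = 0.10

PAIN = "pain"


def _fold_seed(root_seed: int, subject_id: str) -> int:
    """Per-fold seed from the root seed and the held-out subject only.

    Depending on nothing else guarantees that corrupting one subject's data
    cannot perturb the randomness of any other fold.
    """
    h = zlib.crc32(subject_id.encode("utf8")) & 0x7FFFFFFF
    return (int(root_seed) * 1000003 + h) % (2**31)


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters of the dense network."""

    hidden_layer_sizes: tuple[int, ...] = (16, 8)
    # moderate L2: the false-label pass scores *training* sessions, so the
    # network must generalize from feature structure, not memorize labels
    alpha: float = 0.1
    max_iter: int = 500
    balance_classes: bool = True  # deterministic minority oversampling


@dataclass
class PCATransform:
    """Standardization + 13 → 6 PCA projection fitted on training data only."""

    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_: np.ndarray
    n_components: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return ((x - self.mean_) / self.scale_) @ self.components_.T


def fit_pca(training_features: np.ndarray,
            n_components: int = DEFAULT_N_COMPONENTS) -> PCATransform:
    """Fit the dimensionality-reduction stage on a training feature matrix.

    Columns are standardized with training statistics, then ``n_components``
    orthonormal components ordered by explained variance are fitted. Inputs
    whose standardized matrix has rank below ``n_components`` are rejected
    with the observed rank.
    """
    x = np.asarray(training_features, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected an (n, {len(FEATURE_NAMES)}) feature matrix")
    if x.shape[0] < n_components + 1:
        raise ValueError(
            f"need >= {n_components + 1} training rows, got {x.shape[0]}")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains NaN; impute before fitting")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    z = (x - mean) / scale
    rank = np.linalg.matrix_rank(z - z.mean(axis=0))
    if rank < n_components:
        raise ValueError(
            f"training matrix rank {rank} < {n_components} components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(z)
    return PCATransform(
        mean_=mean,
        scale_=scale,
        components_=pca.components_,
        explained_variance_=pca.explained_variance_,
        n_components=n_components,
    )


@dataclass
class ClassifierModel:
    """Fitted dense-layer network emitting a probability simplex per session."""

    mlp: MLPClassifier
    classes: tuple[str, ...]
    seed: int

    def predict_proba(self, pcs: np.ndarray) -> pd.DataFrame:
        """Class probabilities (columns non-pain / pain / analgesic, rows sum to 1)."""
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        proba = self.mlp.predict_proba(pcs)
        frame = pd.DataFrame(proba, columns=list(self.mlp.classes_))
        return frame[list(STATES)]

    def predicted_pain_value(self, pcs: np.ndarray) -> np.ndarray:
        """Probability of the pain class for each session."""
        return self.predict_proba(pcs)[PAIN].to_numpy()


def _balanced_indices(labels: np.ndarray) -> np.ndarray:
    """Deterministically oversample minority classes up to the majority count.

    Equivalent to integer inverse-frequency class weights in the loss.
    """
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    out = []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        reps = int(np.ceil(target / idx.size))
        out.append(np.tile(idx, reps)[:target])
    return np.sort(np.concatenate(out))


def train_classifier(
    pcs: np.ndarray,
    labels: np.ndarray,
    seed: int,
    config: ClassifierConfig | None = None,
) -> ClassifierModel:
    """Train the three-class dense network on projected training features.

    Deterministic given ``seed`` (full-batch L-BFGS optimizer, fixed
    initialization). All three classes must be present.
    """
    config = config or ClassifierConfig()
    pcs = np.asarray(pcs, dtype=float)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    missing = [s for s in STATES if s not in present]
    if missing:
        raise ValueError(f"training data missing class(es): {missing}")
    if config.balance_classes:
        idx = _balanced_indices(labels)
        pcs, labels = pcs[idx], labels[idx]
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation="relu",
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_iter,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        # L-BFGS stopping at max_iter / a flat line search is an acceptable
        # plateau stop for this small network
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(pcs, labels)
    return ClassifierModel(mlp=mlp, classes=tuple(mlp.classes_), seed=int(seed))


def _impute(x: np.ndarray, column_means: np.ndarray) -> np.ndarray:
    """Replace NaN entries (empty-subset sentinel features) by training means."""
    out = np.array(x, dtype=float)
    nan = np.isnan(out)
    if nan.any():
        out[nan] = np.broadcast_to(column_means, out.shape)[nan]
    return out


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[list(FEATURE_NAMES)].to_numpy(dtype=float)


def _train_on_table(
    table: pd.DataFrame,
    seed: int,
    n_components: int,
    config: ClassifierConfig | None,
) -> tuple[PCATransform, ClassifierModel, np.ndarray]:
    """Impute, fit PCA and train the classifier on one feature table."""
    x = _feature_matrix(table)
    col_means = np.nanmean(x, axis=0)
    x = _impute(x, col_means)
    pca = fit_pca(x, n_components)
    model = train_classifier(pca.transform(x), table["class_label"].to_numpy(),
                             seed=seed, config=config)
    return pca, model, col_means


def false_label_filter(
    feature_table: pd.DataFrame,
    fraction: float = DEFAULT_FALSE_LABEL_FRACTION,
    seed: int = 0,
    n_components: int = DEFAULT_N_COMPONENTS,
    config: ClassifierConfig | None = None,
    n_iterations: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the pain-labelled sessions scored least pain-like.

    Trains on the full table, scores every pain-labelled session's predicted
    pain value and removes the ``floor(fraction × n_pain)`` lowest-scoring
    ones (ties broken by session-ID order); non-pain and analgesic sessions
    are never touched. With ``n_iterations`` > 1 the train-score-remove pass
    repeats on the surviving table.

    Returns the filtered table and a removal log (session_id, subject_id,
    predicted_pain_value, iteration).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if (feature_table["class_label"] == PAIN).sum() == 0:
        raise ValueError("cohort has no pain-labelled sessions")
    table = feature_table.reset_index(drop=True)
    log_rows = []
    for iteration in range(n_iterations):
        n_pain = int((table["class_label"] == PAIN).sum())
        n_remove = int(np.floor(fraction * n_pain))
        if n_remove == 0:
            break
        pca, model, col_means = _train_on_table(table, seed, n_components, config)
        pain_rows = table[table["class_label"] == PAIN]
        pcs = pca.transform(_impute(_feature_matrix(pain_rows), col_means))
        scores = model.predicted_pain_value(pcs)
        order = pain_rows.assign(_score=scores).sort_values(
            ["_score", "session_id"], kind="mergesort")
        removed = order.head(n_remove)
        for _, row in removed.iterrows():
            log_rows.append({
                "session_id": row["session_id"],
                "subject_id": row["subject_id"],
                "predicted_pain_value": row["_score"],
                "iteration": iteration,
            })
        table = table[~table["session_id"].isin(removed["session_id"])]
        table = table.reset_index(drop=True)
    log = pd.DataFrame(
        log_rows,
        columns=["session_id", "subject_id", "predicted_pain_value", "iteration"],
    )
    return table, log


@dataclass
class FoldResult:
    """One leave-one-subject-out fold: model artifacts and test predictions."""

    held_out_subject: str
    predictions: pd.DataFrame  # session_id, class_label, p_*, predicted_pain_value
    pca: PCATransform
    model: ClassifierModel
    removal_log: pd.DataFrame
    train_column_means: np.ndarray = field(repr=False, default=None)


def loso_cv(
    feature_table: pd.DataFrame,
    seed: int = 0,
    filter_fraction: float = DEFAULT_FALSE_LABEL_FRACTION,
    n_components: int = DEFAULT_N_COMPONENTS,
    config: ClassifierConfig | None = None,
) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation of the full training stack.

    One fold per subject (sorted order). Within each fold the false-label
    filter, feature imputation, PCA fit and classifier training use only the
    training subjects; the held-out subject's sessions are scored once, so
    every session appears in exactly one test set.
    """
    subjects = sorted(feature_table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    folds: list[FoldResult] = []
    for subject in subjects:
        train = feature_table[feature_table["subject_id"] != subject]
        test = feature_table[feature_table["subject_id"] == subject]
        fold_seed = _fold_seed(seed, subject)
        filtered, removal_log = false_label_filter(
            train, fraction=filter_fraction, seed=fold_seed,
            n_components=n_components, config=config)
        pca, model, col_means = _train_on_table(
            filtered, fold_seed, n_components, config)
        pcs = pca.transform(_impute(_feature_matrix(test), col_means))
        proba = model.predict_proba(pcs)
        predictions = test[["session_id", "subject_id", "class_label"]].copy()
        predictions = predictions.reset_index(drop=True)
        for state in STATES:
            predictions[f"p_{state}"] = proba[state].to_numpy()
        predictions["predicted_pain_value"] = proba[PAIN].to_numpy()
        folds.append(FoldResult(
            held_out_subject=subject,
            predictions=predictions,
            pca=pca,
            model=model,
            removal_log=removal_log,
            train_column_means=col_means,
        ))
    return folds


def pooled_predictions(folds: list[FoldResult]) -> pd.DataFrame:
    """Concatenate the held-out predictions of all folds."""
    return pd.concat([f.predictions for f in folds], ignore_index=True)


def pooled_pain_auc(folds: list[FoldResult],
                    positive: str = PAIN) -> float:
    """AUC of the predicted pain value for positive-class vs all other sessions."""
    pooled = pooled_predictions(folds)
    return feature_auc(
        pooled["predicted_pain_value"].to_numpy(),
        (pooled["class_label"] == positive).to_numpy(),
    )


@dataclass
class GroupComparison:
    """Two-group comparison of predicted pain values."""

    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    statistic: float
    p_value: float
    auc: float
    test: str
    n_a: int
    n_b: int


def evaluate_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    test: str = "ttest",
) -> GroupComparison:
    """Compare two groups of predicted pain values.

    ``test`` is ``'ttest'`` (unpaired two-sided t-test) or ``'mannwhitney'``
    (two-sided Mann-Whitney U). Also reports mean ± SEM per group and the
    AUC of group A vs group B.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "ttest":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs >= 2 values per group")
        res = stats.ttest_ind(a, b)
    elif test == "mannwhitney":
        if a.size < 1 or b.size < 1:
            raise ValueError("both groups must be nonempty")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    pooled = np.concatenate([a, b])
    is_a = np.zeros(pooled.size, dtype=bool)
    is_a[: a.size] = True
    return GroupComparison(
        mean_a=float(a.mean()),
        sem_a=float(stats.sem(a)) if a.size > 1 else float("nan"),
        mean_b=float(b.mean()),
        sem_b=float(stats.sem(b)) if b.size > 1 else float("nan"),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        auc=feature_auc(pooled, is_a),
        test=test,
        n_a=int(a.size),
        n_b=int(b.size),
    )
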