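# Methods

This note records the scientific and numerical choices behind `paintrace`:
what the pipeline computes, what the synthetic cohorts emulate, and where
the design was genuinely open.

## Signal model and preprocessing

Input is a per-session ROI × frame matrix of raw mean fluorescence at
~5 Hz, with a per-frame movement mask. Movement is detected on the
behaviour video (30 fps) by summed absolute inter-frame pixel change
(*motion energy*): a video frame is movement-positive when its energy
strictly exceeds an experimenter-set threshold. The video-rate mask is
projected to imaging frames by interval overlap — an imaging frame is
flagged iff any video frame timestamped inside its inter-frame interval
is positive. The final imaging frame's interval is extended by the median
frame period.

Traces are smoothed with a unit-sum Gaussian window of size 29 frames.
Only the size is canonical; the shape parameter is our choice, set to
σ = (window − 1)/6 ≈ 4.67 frames so that ±3σ spans the window
(configurable). Edges use reflect padding so constant traces stay exactly
constant.

Per ROI, the baseline frame set is every frame at or below the 30th
percentile (linear interpolation; ties at the cut included) of the
smoothed trace. The normalization formulas need both a baseline mean μ
and SD σ, which a single percentile value cannot supply, so the default
(`baseline_mode="subset-mean"`) takes μ and σ over that frame set; the
alternative reading, μ = the percentile value itself, is available as
`baseline_mode="percentile-value"`. σ uses ddof = 0 (population SD); a
literally constant baseline reports σ = 0 exactly and Z-scoring then
fails per ROI with the ROI index. ΔF = (X − μ)/μ requires μ ≠ 0.

## The activity-share difference D and the 13 features

For matched ROI *i* of evaluation session A and reference session B,
X_i is the ROI's mean normalized signal over a frame subset (movement /
stationary / total), floored at 0 so that shares X_i / Σ_j X_j form a
probability distribution over ROIs. D_i is the share difference A − B;
shares each sum to one, so Σ_i D_i = 0 identically.

**Threshold scale.** Up/down calls use the canonical cut-offs +0.3 and
−0.2, applied by default to n·D_i — the ROI's activity change relative to
the session-mean activity — rather than to the raw share difference. Raw
shares scale as 1/n, so with realistic ROI counts (tens to hundreds) a
fixed threshold of 0.3 on D itself could never be exceeded by more than
three ROIs (Σ of positive parts ≤ 1), which is incompatible with observed
up-regulated fractions of tens of percent; on the n·D scale, 0.3 means "a
30-percentage-point shift relative to the mean cell", independent of n.
`FeatureConfig(d_cell_scale="raw")` restores literal thresholds on D.

The 12 ratio features are (Z-score, ΔF) × (up, down) × (movement,
stationary, total), in that frozen order, so PCA loadings stay
interpretable across runs. The 13th feature is the mean pairwise Pearson
correlation over all ROI pairs of the evaluation session, computed on its
smoothed ΔF traces over all frames: the signal and subset for the
correlation feature are not canonically specified, and a single
correlation feature exists, so we use the evaluation session's ΔF signal
over the whole recording. Zero-variance ROIs are excluded (with a
warning); fewer than two usable ROIs is an error.

**Reference rule.** Which session acts as baseline is an explicit
configuration; the default pairs every session against the subject's
first pre-treatment non-pain session, and that reference is not itself
evaluated (a self-pair is identically zero).

**Empty subsets.** A session with no movement (or no stationary) frames
gets NaN for the affected ratio features; downstream training imputes
NaN with the training-set column mean, keeping LOSO folds intact.

Per-feature screening uses ROC-AUC computed as the tie-aware
Mann-Whitney U statistic divided by n₁·n₂, in raw orientation (0.5 =
chance; values below 0.5 mean the feature ranks the pain group lower).
The three screening contrasts are baseline vs pain, pain vs analgesics,
and pain vs analgesics + baseline, pooling raw sessions (no group
reweighting).

## Classification stack

Features are standardized with training-set statistics and reduced
13 → 6 by PCA; all six components are retained. The classifier is a dense
network (hidden layers 16 and 8, ReLU, softmax head) trained with
full-batch L-BFGS at fixed seed, which makes training deterministic.
Class imbalance is handled by deterministic oversampling of minority
classes to the majority count — the integer equivalent of
inverse-frequency loss weights, which the underlying estimator does not
expose directly. Weight decay defaults to α = 0.1: the false-label pass
scores *training* sessions, so the network must rank them by feature
structure rather than memorize conflicting labels; with negligible
regularization a flexible network fits mislabelled sessions and the
filter loses its signal.

**False-label management.** A model is trained on the full cohort, every
pain-labelled session's pain probability is computed, and the
floor(0.10 × n_pain) lowest-scoring pain sessions are removed; non-pain
and analgesic sessions are never touched. Ties at the boundary break by
session-ID order for determinism. The recursion depth of the
train-score-remove loop is not canonical; the default is a single pass,
with `n_iterations` exposed.

**LOSO-CV.** One fold per subject (sorted order). Within a fold the
false-label filter, imputation statistics, PCA and classifier see only
the training subjects. Each fold's RNG seed derives from the root seed
and the held-out subject's ID only, so corrupting one subject's data
cannot perturb another fold's randomness — fold models are bit-identical
under arbitrary corruption of their held-out subject, which the tests
assert directly.

The scalar read-out is the **predicted pain value** = softmax probability
of the pain class. Because "classification performance" can reasonably
mean either, the pipeline emits both the pain-vs-rest AUC of the
predicted pain value and the three-class arg-max accuracy. Group
comparisons report mean ± SEM with an unpaired two-sided t-test or
Mann-Whitney test, plus the AUC of the contrast.

## What the synthetic cohorts emulate

`simulate.generate_session` draws per-ROI Poisson event trains
(base rate 0.1 Hz), convolves them with a double-exponential kernel
(rise 0.2 s, decay 1.5 s — typical GCaMP6s kinetics; the indicator's
kinetics are not canonically specified and are configurable), adds a
shared latent drive (its own 0.3 Hz event train) with state-dependent
weight, scales by a transient amplitude of 30 a.u. on a baseline of
100 a.u., adds Gaussian noise (SD 2 a.u.) and floors at zero. Sessions
last 240 s at 5 Hz (≈ a 4-minute recording), 60 ROIs by default.

Locomotion bouts (4/min, 3 s) are placed one per equal time slot
(stratified, non-overlapping), snapped to the 30 Hz video grid; the
session emits both the imaging-frame mask (derived through the same
video-to-imaging mapping the preprocessing stage uses, so the two are
consistent by construction) and a motion-energy trace whose planted
threshold separates bout from non-bout frames with margin.

State effects are planted as fractions of ROIs whose event rate is
multiplied (up) or divided (down) by `effect_size` (default 3) under a
given (state, movement) condition. No quantitative effect sizes are
canonical for these fractions; the defaults encode the qualitative
pattern reported for S1 — during movement both up and down fractions
rise under pain (0.25/0.25) and the analgesic state shows an even larger
up fraction (0.35/0.15); when stationary only the down fraction rises
under pain (0.20) and returns to baseline under analgesics — and pairwise
correlation is similar in non-pain and pain (drive weight 0.15) but
markedly higher under analgesics (0.5). Up/down ROI identities are fixed
per subject across that subject's sessions (prefix/suffix of one
per-subject permutation), so matched-ROI modulation is consistent — the
condition under which D detects planted effects. Every session carries a
ground-truth sidecar (planted ROI sets, bout intervals, threshold,
mislabel flag) for oracle tests; `pain_mislabel_fraction` plants
pain-labelled sessions with non-pain dynamics to exercise the
false-label filter.

A *matched null* cohort (`SimulationConfig.null()`) sets effect_size = 1
and a state-independent drive weight, leaving no state-dependent
structure at all: any classifier performance above chance on it would
indicate leakage.

**What the simulator does not emulate:** pixel-level movies and ROI
segmentation errors, slow drift and photobleaching, indicator saturation
and nonlinearity, imperfect longitudinal ROI matching (the matched-ROI
map is the identity by construction), heavy-tailed firing-rate
distributions, and drug-specific analgesic signatures beyond a single
analgesic archetype. Passing tests therefore demonstrate that the
implementation recovers the structure the method assumes, not that the
method works on real recordings.

## Cohort layout

A cohort holds `sessions_per_subject_per_state` sessions for each of the
three states per subject; the first non-pain session doubles as that
subject's reference and is excluded from the feature table. With one
session per state the non-pain class would have no evaluable pairs, so
classification-grade cohorts use two or more sessions per state
(default 2); the mild class imbalance this creates (1 non-pain vs 2 pain
vs 2 analgesic pairs per subject) is absorbed by the oversampling
balancer.

## Problem sizes and statistical checks

The test suite runs its structural checks on miniature cohorts (tens of
ROIs, ≤ 2-minute sessions) and its statistical checks at the default
study scale: conservation of Σ D = 0 over 1000 randomized pairs; AUC,
smoothing and PCA against brute-force oracles (all-pairs comparison,
direct dot-product convolution, covariance eigendecomposition); and
parameter recovery on 10-subject cohorts pooled over three seeds —
strong-effect cohorts must reach pooled LOSO pain-vs-rest AUC ≥ 0.8,
matched null cohorts must stay within 0.5 ± 0.1 (pooling three cohorts
narrows the null sampling band to ≈ ±0.05 SD). The false-label filter is
checked on a cohort with 12.5% planted mislabels via a hypergeometric
enrichment test on the removed set.

## Known limitations

* The share floor at zero discards information in strongly suppressed
  ROIs (a ROI can contribute at most "zero share"); keeping signed shares
  would break the distribution interpretation, so flooring is the
  default and the only implemented option.
* With many up-regulated ROIs, share renormalization drags stable ROIs
  below the −0.2 cut (shares are zero-sum), so down-fractions are partly
  a mirror of up-fractions; the classifier sees both, but the features
  are not independent measurements.
* The dense network is small but still saturates probabilities on
  well-separated synthetic data; predicted pain values near 0/1 should
  not be read as calibrated probabilities.
* Subjects are assumed exchangeable; no hierarchical/random-effect
  structure is modelled across animals.
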