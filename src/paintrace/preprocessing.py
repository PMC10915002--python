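"""Denoising, baseline normalization and movement partitioning.

Raw per-ROI traces are smoothed with a unit-sum Gaussian window (size 29 by
default), a per-ROI baseline is estimated from the frames at or below the
30th percentile of the smoothed trace, and the trace is normalized either as

* ΔF: (X − μ) / μ, or
* Z-score: (X − μ) / σ,

where μ and σ are the mean and standard deviation of the baseline frames.
Movement is detected by thresholding a motion-energy trace at the video rate
and mapped onto imaging frames by interval overlap.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal.windows import gaussian as gaussian_window

from .session import CalciumSession, MotionEnergyTrace, NormalizedSession, SessionError

DEFAULT_WINDOW = 29
DEFAULT_BASELINE_PERCENTILE = 30.0


class DegenerateBaselineError(SessionError):
    """Baseline statistics unusable for the requested normalization."""

    def __init__(self, roi: int, message: str):
        self.roi = roi
        super().__init__(f"ROI {roi}: {message}")


def detect_movement(energy: MotionEnergyTrace | np.ndarray, threshold: float) -> np.ndarray:
    """Flag video frames whose motion energy strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    values = energy.energy if isinstance(energy, MotionEnergyTrace) else np.asarray(energy, float)
    if values.size == 0:
        raise ValueError("empty motion-energy trace")
    return values > threshold


def map_video_to_imaging(
    video_mask: np.ndarray,
    video_rate_hz: float,
    frame_times: np.ndarray,
) -> np.ndarray:
    """Project a video-rate movement mask onto imaging frames.

    An imaging frame is movement-positive iff any video frame timestamped
    inside its inter-frame interval [t_i, t_{i+1}) is positive; the final
    frame's interval extends by the median frame period.
    """
    if video_rate_hz <= 0:
        raise ValueError("video rate must be positive")
    video_mask = np.asarray(video_mask, dtype=bool)
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.ndim != 1 or frame_times.size < 2:
        raise ValueError("need >= 2 imaging frame times")
    dt = float(np.median(np.diff(frame_times)))
    edges = np.append(frame_times, frame_times[-1] + dt)
    video_times = np.arange(video_mask.size) / video_rate_hz
    if video_times.size == 0 or video_times[-1] + 1.0 / video_rate_hz < edges[-2]:
        raise ValueError("video recording shorter than the imaging span")
    # bin video frames into imaging intervals; bin 0 = before first frame
    bins = np.searchsorted(edges, video_times, side="right") - 1
    out = np.zeros(frame_times.size, dtype=bool)
    valid = (bins >= 0) & (bins < out.size)
    np.logical_or.at(out, bins[valid], video_mask[valid])
    return out


def gaussian_kernel(window: int = DEFAULT_WINDOW, sigma: float | None = None) -> np.ndarray:
    """Unit-sum Gaussian smoothing kernel of odd length ``window``.

    ``sigma`` defaults to (window − 1)/6 so ±3σ spans the window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if sigma is None:
        sigma = (window - 1) / 6.0 if window > 1 else 1.0
    k = gaussian_window(window, std=sigma)
    return k / k.sum()


def smooth(trace: np.ndarray, window: int = DEFAULT_WINDOW,
           sigma: float | None = None) -> np.ndarray:
    """Gaussian-smooth traces along the frame axis (reflect-padded edges).

    Accepts a 1-D trace or an ROI × frame matrix; output shape equals input
    shape and constant traces are preserved exactly.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if window > n:
        raise ValueError(f"window {window} larger than trace length {n}")
    kernel = gaussian_kernel(window, sigma)
    return convolve1d(trace, kernel, axis=-1, mode="reflect")


def baseline_stats(
    trace: np.ndarray,
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    mode: str = "subset-mean",
) -> tuple[float, float]:
    """Baseline mean and sd of one (smoothed) trace.

    The baseline frame set is every frame at or below the trace's
    ``percentile``-th percentile (linear interpolation; ties included).
    ``mode='subset-mean'`` (default) returns the mean of that set as μ;
    ``mode='percentile-value'`` returns the percentile value itself as μ.
    σ is always the population sd (ddof=0) over the baseline set. A constant
    baseline yields σ = 0, which downstream Z-scoring rejects.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    cut = np.percentile(trace, percentile)
    baseline = trace[trace <= cut]
    if mode == "subset-mean":
        mu = float(baseline.mean())
    elif mode == "percentile-value":
        mu = float(cut)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    # a literally constant baseline must report sigma exactly 0, not fp dust
    sigma = 0.0 if np.ptp(baseline) == 0 else float(baseline.std(ddof=0))
    return mu, sigma


def normalize(
    session: CalciumSession,
    method: str,
    window: int = DEFAULT_WINDOW,
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    baseline_mode: str = "subset-mean",
    presmoothed: np.ndarray | None = None,
) -> NormalizedSession:
    """Smooth and normalize a session per ROI.

    ``method`` is ``'deltaF'`` ((X−μ)/μ) or ``'zscore'`` ((X−μ)/σ), with μ/σ
    taken from that ROI's own baseline frames in the same session. Pass
    ``presmoothed`` to reuse an already-smoothed matrix across methods.

    Raises
    ------
    DegenerateBaselineError
        If a ROI's baseline μ is 0 (ΔF) or σ is 0 (Z-score).
    """
    if method not in ("deltaF", "zscore"):
        raise SessionError(f"unknown normalization method {method!r}")
    sm = smooth(session.fluorescence, window) if presmoothed is None else presmoothed
    n_rois = sm.shape[0]
    mus = np.empty(n_rois)
    sigmas = np.empty(n_rois)
    for r in range(n_rois):
        mus[r], sigmas[r] = baseline_stats(sm[r], percentile, baseline_mode)
    if method == "deltaF":
        bad = np.nonzero(mus == 0)[0]
        if bad.size:
            raise DegenerateBaselineError(int(bad[0]), "baseline mean is zero; ΔF undefined")
        signal = (sm - mus[:, None]) / mus[:, None]
    else:
        bad = np.nonzero(sigmas == 0)[0]
        if bad.size:
            raise DegenerateBaselineError(int(bad[0]), "baseline sd is zero; Z-score undefined")
        signal = (sm - mus[:, None]) / sigmas[:, None]
    return NormalizedSession(
        signal=signal,
        method=method,
        baseline_mu=mus,
        baseline_sigma=sigmas,
        movement_mask=session.movement_mask.copy(),
        subject_id=session.subject_id,
        state_label=session.state_label,
        session_id=session.session_id,
    )
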