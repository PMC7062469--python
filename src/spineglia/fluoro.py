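"""Quality control and ΔF/F_σ response extraction for calcium trial traces.

Adult-born granule cell dendrites are often so dim at rest that ΔF/F₀ is
unreliable; responses are therefore normalized by the baseline standard
deviation instead: ΔF/F_σ = (F - F₀)/F_σ, with F₀ the baseline mean (or
the endpoint of an exponential baseline fit when drift is detected) and
F_σ the baseline SD.  The response value of a dendrite-odor pair is the
mean ΔF/F_σ over the 5 s analysis window following odor onset, averaged
over surviving trials.

QC operates at three levels, each with an explicit reason code:

* frames — cosine similarity against the best-trial mean and the trial's
  baseline mean (out-of-frame motion);
* trials — dimming (immersion water / laser power), baseline-vs-odor
  brightness shifts, and the 75%-surviving-frames rule applied to the
  baseline and analysis windows separately;
* ROIs — baseline F_σ above 30% of the baseline mean ("too noisy").
"""

from __future__ import annotations

import logging
import warnings
import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "FRAME_QC_THRESHOLDS",
    "frame_qc",
    "trial_qc",
    "bleach_correct",
    "dff_sigma",
    "response_value",
    "roi_qc",
    "sniff_rate",
]

# state -> (max relative deviation from best-trial mean similarity,
#           max relative deviation from trial-baseline mean similarity)
FRAME_QC_THRESHOLDS: dict[str, tuple[float, float]] = {
    "anesthetized": (0.25, 0.20),
    "awake": (0.30, 0.15),
}


def frame_qc(
    similarities: np.ndarray,
    best_trial_mean: float,
    baseline_mean: float,
    state: str = "anesthetized",
) -> tuple[np.ndarray, list[str]]:
    """Flag frames with out-of-frame motion from cosine-similarity series.

    A frame is discarded when its similarity deviates from the best-trial
    mean by more than 25% (30% awake) or from the trial's baseline mean by
    more than 20% (15% awake), in relative absolute terms.

    Returns (keep flags, reason code per frame: "" | "cosine_vs_best" |
    "cosine_vs_baseline"); the first violated rule is the primary reason.
    """
    if state not in FRAME_QC_THRESHOLDS:
        raise ValueError(f"state must be one of {sorted(FRAME_QC_THRESHOLDS)}")
    if best_trial_mean == 0 or baseline_mean == 0:
        raise ValueError("reference similarity means must be nonzero")
    sim = np.asarray(similarities, dtype=float)
    thr_best, thr_base = FRAME_QC_THRESHOLDS[state]
    dev_best = np.abs(sim - best_trial_mean) / abs(best_trial_mean)
    dev_base = np.abs(sim - baseline_mean) / abs(baseline_mean)
    bad_best = dev_best > thr_best
    bad_base = dev_base > thr_base
    keep = ~(bad_best | bad_base)
    reasons = [
        "cosine_vs_best" if bb else ("cosine_vs_baseline" if bs else "")
        for bb, bs in zip(bad_best, bad_base)
    ]
    return keep, reasons


def trial_qc(
    trial_brightness: float,
    first_three_trials_brightness: float,
    baseline_brightness: float,
    odor_brightness: float,
    first_trial_brightness_sd: float,
    frac_frames_surviving_baseline: float,
    frac_frames_surviving_analysis: float,
    *,
    n_reference_trials: int = 3,
) -> tuple[bool, str]:
    """Keep/discard decision for one trial, with the primary reason code.

    Discards when average brightness falls below half the mean of the first
    three trials ("dim"), when |baseline - odor| brightness exceeds three
    first-trial SDs ("brightness_shift"), or when fewer than 75% of frames
    survive frame QC in either the baseline or the analysis window
    ("insufficient_frames").
    """
    if n_reference_trials < 3:
        raise ValueError("reference requires at least the first three trials")
    if trial_brightness < 0.5 * first_three_trials_brightness:
        return False, "dim"
    if abs(baseline_brightness - odor_brightness) > 3.0 * first_trial_brightness_sd:
        return False, "brightness_shift"
    if (
        frac_frames_surviving_baseline < 0.75
        or frac_frames_surviving_analysis < 0.75
    ):
        return False, "insufficient_frames"
    return True, ""


def _exp_model(t, a, b, c):
    return a * np.exp(b * t) + c


def bleach_correct(
    baseline: np.ndarray,
    frame_rate_hz: float,
    *,
    ratio_threshold: float = 1.1,
    direction: str = "rising",
) -> tuple[float, bool]:
    """Baseline mean F₀, with exponential drift correction when triggered.

    When the mean fluorescence of the last 2.5 s of the baseline exceeds
    ``ratio_threshold`` times the mean of the first 2.5 s (strictly), a
    single exponential a·exp(b·t)+c is fitted to the baseline and its value
    at the end of the baseline is used as F₀; otherwise F₀ is the plain
    baseline mean.

    The printed trigger acts on *rising* baselines; ``direction`` may be set
    to ``"falling"`` (trigger when first > 1.1x last, the photobleaching
    reading) or ``"both"``.  Returns (F₀, corrected?).
    """
    f = np.asarray(baseline, dtype=float)
    n_sub = int(round(2.5 * frame_rate_hz))
    if f.size < 2 * n_sub:
        raise ValueError("baseline must be at least 5 s so both 2.5 s windows exist")
    first = f[:n_sub].mean()
    last = f[-n_sub:].mean()
    if direction == "rising":
        triggered = last > ratio_threshold * first
    elif direction == "falling":
        triggered = first > ratio_threshold * last
    elif direction == "both":
        triggered = max(first, last) > ratio_threshold * min(first, last)
    else:
        raise ValueError("direction must be rising, falling or both")
    if not triggered:
        return float(f.mean()), False
    t = np.arange(f.size) / frame_rate_hz
    t_end = t[-1]
    try:
        sign = 1.0 if last >= first else -1.0
        p0 = (sign * max(abs(last - first), 1e-6), sign * 0.1, first)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_exp_model, t, f, p0=p0, maxfev=10_000)
        return float(_exp_model(t_end, *popt)), True
    except (RuntimeError, ValueError):
        logger.warning("baseline exponential fit failed; falling back to plain mean")
        return float(f.mean()), False


def dff_sigma(trace: np.ndarray, f0: float, f_sigma: float) -> np.ndarray:
    """Normalized fluorescence change (F - F₀)/F_σ."""
    if f_sigma <= 0:
        raise ValueError("F_sigma must be positive (degenerate baseline)")
    return (np.asarray(trace, dtype=float) - f0) / f_sigma


def response_value(
    dff: np.ndarray,
    odor_onset_frame: int,
    frame_rate_hz: float,
    analysis_window_s: float = 5.0,
    keep_frames: np.ndarray | None = None,
) -> float:
    """Mean ΔF/F_σ over the analysis window [onset, onset + window).

    Frames discarded by QC are dropped from the mean, not interpolated.
    Returns NaN when no analysis-window frame survives.
    """
    dff = np.asarray(dff, dtype=float)
    n_win = int(round(analysis_window_s * frame_rate_hz))
    sel = np.zeros(dff.size, dtype=bool)
    sel[odor_onset_frame : odor_onset_frame + n_win] = True
    if keep_frames is not None:
        sel &= np.asarray(keep_frames, dtype=bool)
    if not sel.any():
        return float("nan")
    return float(dff[sel].mean())


def roi_qc(f_sigma: float, baseline_mean: float, *, max_ratio: float = 0.30) -> bool:
    """Keep the ROI iff baseline F_σ is at most 30% of the baseline mean."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return f_sigma <= max_ratio * baseline_mean


def sniff_rate(
    respiration: np.ndarray,
    sample_rate_hz: float,
    *,
    min_peak_interval_s: float = 0.1,
) -> float:
    """Respiration rate in peaks/s with a 0.1 s minimum inter-peak interval."""
    resp = np.asarray(respiration, dtype=float)
    duration_s = resp.size / sample_rate_hz
    if duration_s < min_peak_interval_s:
        raise ValueError("window shorter than the minimum peak interval")
    distance = max(1, int(round(min_peak_interval_s * sample_rate_hz)))
    peaks, _ = find_peaks(resp, distance=distance)
    return peaks.size / duration_s
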