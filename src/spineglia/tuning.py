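"""Tuning metrics: ROC thresholds, effective odors, lifetime sparseness,
sliding-window event detection, and the principal-subspace permutation test.

Response thresholds are set from the blank ("no odor") trial distribution:
the lowest candidate threshold whose blank false-positive rate does not
exceed the 10% design target, computed on control and treated responses
pooled.  A dendrite's *effective odors* are those whose trial-averaged
response exceeds the threshold, and lifetime sparseness

    LS = (Σ_j r_j / m)² / (Σ_j r_j² / m)

summarizes tuning breadth over the m-odor panel on the thresholded
response vector (sub-threshold entries zeroed; LS := 0 when every entry is
sub-threshold, the sparsest possible representation).  LS = 1 for uniform
responders and 1/m for single-odor responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.linalg import subspace_angles, svd

logger = logging.getLogger(__name__)

__all__ = [
    "RocThreshold",
    "EventParams",
    "Event",
    "SubspaceTestResult",
    "roc_threshold",
    "effective_odors",
    "lifetime_sparseness",
    "threshold_responses",
    "grid_search_event_params",
    "detect_events",
    "event_response",
    "subspace_permutation_test",
]


@dataclass(frozen=True)
class RocThreshold:
    """Response threshold chosen to cap the blank-trial false-positive rate."""

    theta: float
    target_fpr: float
    achieved_fpr: float
    n_noise: int
    n_signal: int


def roc_threshold(
    signal: np.ndarray,
    noise: np.ndarray,
    target_fpr: float = 0.10,
) -> RocThreshold:
    """Lowest observed-value threshold with blank FPR at or below the target.

    Candidates are the sorted unique values pooled from both distributions;
    the false-positive rate of a candidate θ is the fraction of noise
    (blank-trial) responses strictly above θ.
    """
    noise = np.asarray(noise, dtype=float).ravel()
    signal = np.asarray(signal, dtype=float).ravel()
    if noise.size == 0:
        raise ValueError("noise (blank-trial) sample is empty")
    candidates = np.unique(np.concatenate([signal, noise]))
    noise_sorted = np.sort(noise)
    # fraction of noise strictly above each candidate
    n_above = noise.size - np.searchsorted(noise_sorted, candidates, side="right")
    fpr = n_above / noise.size
    ok = np.nonzero(fpr <= target_fpr)[0]
    idx = ok[0]  # candidates ascend, so the first admissible one is lowest
    return RocThreshold(
        theta=float(candidates[idx]),
        target_fpr=target_fpr,
        achieved_fpr=float(fpr[idx]),
        n_noise=noise.size,
        n_signal=signal.size,
    )


def effective_odors(responses: np.ndarray, theta: float) -> int:
    """Number of odors with response strictly above the threshold."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return int(np.count_nonzero(np.asarray(responses, dtype=float) > theta))


def threshold_responses(responses: np.ndarray, theta: float) -> np.ndarray:
    """Zero out sub-threshold responses (strictly-above rule)."""
    r = np.asarray(responses, dtype=float).copy()
    r[r <= theta] = 0.0
    return r


def lifetime_sparseness(r: np.ndarray, m: int | None = None) -> float:
    """Lifetime sparseness of a thresholded response vector.

    LS = (Σ r_j / m)² / (Σ r_j² / m).  All-zero vectors get LS = 0.
    Entries must be non-negative (threshold first with
    :func:`threshold_responses`).
    """
    r = np.asarray(r, dtype=float).ravel()
    m = r.size if m is None else int(m)
    if m == 0:
        raise ValueError("m must be positive")
    if r.size != m:
        raise ValueError("response vector length must equal m")
    if (r < 0).any():
        raise ValueError("thresholded responses must be non-negative")
    ssq = float(np.sum(r * r))
    if ssq == 0.0:
        return 0.0
    # Cauchy-Schwarz bounds LS by 1; clip float jitter at the boundary
    return min(1.0, float((r.sum() / m) ** 2 / (ssq / m)))


# ---------------------------------------------------------------------------
# Event detection


@dataclass(frozen=True)
class EventParams:
    """Sliding-window event criterion: >= n_min consecutive frames >= k F_σ."""

    n_min: int
    k: float

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.k <= 0:
            raise ValueError("n_min >= 1 and k > 0 required")


@dataclass(frozen=True)
class Event:
    onset_frame: int
    offset_frame: int  # inclusive
    peak_frame: int
    peak_value: float


def detect_events(
    dff: np.ndarray,
    params: EventParams,
    response_slice: slice | None = None,
    *,
    strict: bool = False,
) -> list[Event]:
    """Runs of >= n_min consecutive frames at or above k (ΔF/F_σ units).

    ``response_slice`` restricts detection to the response period.  With
    ``strict=True`` the in-frame criterion becomes strictly greater.
    """
    x = np.asarray(dff, dtype=float)
    start0 = 0
    if response_slice is not None:
        start0 = response_slice.start or 0
        x = x[response_slice]
    above = (x > params.k) if strict else (x >= params.k)
    events: list[Event] = []
    run_start = None
    for i, a in enumerate(np.append(above, False)):
        if a and run_start is None:
            run_start = i
        elif not a and run_start is not None:
            if i - run_start >= params.n_min:
                seg = x[run_start:i]
                pk = run_start + int(np.argmax(seg))
                events.append(
                    Event(
                        onset_frame=start0 + run_start,
                        offset_frame=start0 + i - 1,
                        peak_frame=start0 + pk,
                        peak_value=float(x[pk]),
                    )
                )
            run_start = None
    return events


def event_response(
    repeat_dffs: list[np.ndarray],
    params: EventParams,
    response_slice: slice,
    frame_rate_hz: float,
    odor_onset_frame: int,
) -> dict:
    """Across-repeat event response for one dendrite-odor pair.

    Frames belonging to an event in *any* repeat are pooled; the mean trace
    across repeats is evaluated at those frames, and the response is the
    mean over a 1 s window centered on the peak of that mean trace (clipped
    to the response period).  Latency is the mean onset-minus-odor-onset
    over repeats that contain at least one event.  Returns dict with
    ``response`` and ``latency_s`` (NaN when undefined) plus the per-repeat
    event lists.
    """
    if not repeat_dffs:
        raise ValueError("no surviving repeats")
    per_repeat = [detect_events(d, params, response_slice) for d in repeat_dffs]
    event_frames = sorted(
        {
            f
            for evs in per_repeat
            for e in evs
            for f in range(e.onset_frame, e.offset_frame + 1)
        }
    )
    out = {"events": per_repeat, "response": float("nan"), "latency_s": float("nan")}
    if not event_frames:
        return out
    mean_trace = np.mean(np.stack(repeat_dffs), axis=0)
    frames = np.asarray(event_frames)
    peak = frames[np.argmax(mean_trace[frames])]
    half = int(round(0.5 * frame_rate_hz))
    lo = max(response_slice.start or 0, peak - half)
    hi = min(response_slice.stop or mean_trace.size, peak + half + 1)
    # the mean event trace exists only on event frames; average those that
    # fall inside the 1 s window around its peak
    in_window = frames[(frames >= lo) & (frames < hi)]
    out["response"] = float(mean_trace[in_window].mean())
    latencies = [
        (min(e.onset_frame for e in evs) - odor_onset_frame) / frame_rate_hz
        for evs in per_repeat
        if evs
    ]
    out["latency_s"] = float(np.mean(latencies))
    return out


def grid_search_event_params(
    blank_dffs: list[np.ndarray],
    response_slice: slice,
    target_fpr: float = 0.10,
    n_min_grid: tuple[int, ...] = (1, 2, 3, 4, 5),
    k_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> tuple[EventParams, float]:
    """Choose (n_min, k) whose blank-trial event rate is closest to the target.

    The blank false-positive rate of a parameter pair is the fraction of
    blank traces containing at least one detected event in the response
    period.  Ties break toward larger n_min, then larger k (more
    conservative).  Returns (params, achieved blank FPR); warns when no
    pair comes within 5 percentage points of the target.
    """
    if not blank_dffs:
        raise ValueError("blank trials required")
    if not n_min_grid or not k_grid:
        raise ValueError("empty parameter grid")
    best: tuple[float, int, float] | None = None  # (|fpr-target|, n_min, k)
    best_fpr = float("nan")
    for n_min, k in product(n_min_grid, k_grid):
        params = EventParams(n_min=n_min, k=k)
        hits = sum(bool(detect_events(d, params, response_slice)) for d in blank_dffs)
        fpr = hits / len(blank_dffs)
        key = (abs(fpr - target_fpr), n_min, k)
        if best is None or key[0] < best[0] or (key[0] == best[0] and key[1:] > best[1:]):
            best = key
            best_fpr = fpr
    assert best is not None
    if best[0] > 0.05:
        logger.warning(
            "no event-parameter pair reaches within 5 points of the %.0f%% target "
            "(closest blank FPR %.3f)",
            100 * target_fpr,
            best_fpr,
        )
    return EventParams(n_min=best[1], k=best[2]), best_fpr


# ---------------------------------------------------------------------------
# Temporal-dynamics subspace test


@dataclass
class SubspaceTestResult:
    angle_deg: float
    all_angles_deg: np.ndarray
    null_angles_deg: np.ndarray
    p: float
    n_pc: int


def _principal_axes(traces: np.ndarray, n_pc: int) -> np.ndarray:
    """Top right-singular vectors (time-loading vectors) of centered traces."""
    X = traces - traces.mean(axis=0, keepdims=True)
    _, _, vt = svd(X, full_matrices=False)
    return vt[:n_pc].T  # (T, n_pc)


def _max_angle_deg(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    angles = np.degrees(subspace_angles(a, b))  # descending
    return float(angles[0]), angles


def subspace_permutation_test(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    n_pc: int = 3,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SubspaceTestResult:
    """Permutation test on the angle between response-time-course subspaces.

    Each group's traces (rows = cell-odor pairs, columns = frames of the
    odor analysis period) are centered and decomposed by SVD; the statistic
    is the largest principal angle between the spans of the first ``n_pc``
    component loading vectors.  The null reassigns whole traces to groups
    of the original sizes ``n_perm`` times; p uses the add-one convention.
    All principal angles are returned alongside the largest.
    """
    A = np.atleast_2d(np.asarray(traces_a, dtype=float))
    B = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the time base")
    if min(A.shape[0], B.shape[0], A.shape[1]) < n_pc:
        raise ValueError(f"need at least {n_pc} traces per group and {n_pc} frames")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed, all_angles = _max_angle_deg(
        _principal_axes(A, n_pc), _principal_axes(B, n_pc)
    )
    pooled = np.vstack([A, B])
    n_a = A.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa = pooled[perm[:n_a]]
        pb = pooled[perm[n_a:]]
        null[i], _ = _max_angle_deg(_principal_axes(pa, n_pc), _principal_axes(pb, n_pc))
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return SubspaceTestResult(
        angle_deg=observed,
        all_angles_deg=all_angles,
        null_angles_deg=null,
        p=float(p),
        n_pc=n_pc,
    )
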