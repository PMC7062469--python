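"""Voltage-clamp sweep QC, passive-property estimation, trace conditioning,
and synaptic-event post-filters.

Passive membrane properties come from small voltage steps (-10 mV, 20 ms)
under the single-compartment circuit: the instantaneous peak current gives
the series resistance Rs = |ΔV|/|I_peak|, the steady-state current over the
last 20% of the step gives the total resistance Rs + Rm, and the membrane
capacitance follows from the relaxation time constant, Cm = τ/(Rs‖Rm),
with τ fitted between the 20% and 80% points of the capacitive decay.

Sweep-level QC drops sweeps whose series resistance deviates more than 25%
from the mean of the first three sweeps or whose holding current exceeds
100 pA in magnitude, and excludes the cell entirely when fewer than half
the sweeps survive.  Event *detection* is upstream; this module applies
only the stated post-filters (sub-3-ms doublet exclusion, noisy-section
masks) and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .synth import EventTrain, TestPulse

__all__ = [
    "PassiveProps",
    "SweepRecord",
    "estimate_passive_properties",
    "sweep_qc",
    "bandstop_condition",
    "doublet_exclusion",
    "train_summary",
    "MAX_INITIAL_RS_MOHM",
]

MAX_INITIAL_RS_MOHM = 50.0  # cell-inclusion bound on the initial series resistance


@dataclass(frozen=True)
class PassiveProps:
    rs_mohm: float
    rm_mohm: float
    cm_pf: float
    tau_ms: float

    def passes_inclusion(self) -> bool:
        return self.rs_mohm < MAX_INITIAL_RS_MOHM


@dataclass(frozen=True)
class SweepRecord:
    sweep_id: str
    rs_mohm: float
    holding_pa: float
    keep: bool = True
    reason: str = ""


def estimate_passive_properties(pulse: TestPulse) -> PassiveProps:
    """Estimate (Rs, Rm, Cm, τ) from an averaged test-pulse current.

    Repetitions are averaged before any measurement.  The capacitive decay
    is fitted log-linearly on the samples where the remaining transient
    lies between 20% and 80% of its initial span.
    """
    i_pa = pulse.mean_current()
    t = pulse.t_s
    dt = 1.0 / pulse.sample_rate_hz
    on = int(round(pulse.step_onset_s / dt))
    off = on + int(round(pulse.step_duration_s / dt))
    i_base = i_pa[:on].mean() if on > 0 else 0.0
    step = i_pa[on:off] - i_base
    dv = abs(pulse.delta_v_mv) * 1e-3

    ipk_idx = int(np.argmax(np.abs(step)))
    i_peak = abs(step[ipk_idx]) * 1e-12
    if i_peak == 0:
        raise ValueError("flat test pulse; no step current")
    rs = dv / i_peak

    n_ss = max(1, int(round(0.2 * step.size)))
    i_ss = abs(step[-n_ss:].mean()) * 1e-12
    if i_ss == 0:
        raise ValueError("zero steady-state current")
    r_total = dv / i_ss

    # capacitive transient relative to steady state, normalized to its span
    span = abs(step[ipk_idx]) - abs(step[-n_ss:].mean())
    if span <= 1e-3 * abs(step[ipk_idx]):
        # pure-resistor limit: I_peak = I_ss, tau -> 0, Cm ~ 0; the series vs
        # membrane split is then unidentifiable and Rm is reported as the
        # residual R_total - Rs (zero when Rs absorbs the whole step)
        return PassiveProps(
            rs_mohm=rs * 1e-6, rm_mohm=(r_total - rs) * 1e-6, cm_pf=0.0, tau_ms=0.0
        )
    rm = r_total - rs
    if rm <= 0:
        raise ValueError("non-positive membrane resistance (leaky seal?)")
    frac = (np.abs(step[ipk_idx:]) - abs(step[-n_ss:].mean())) / span
    sel = np.nonzero((frac >= 0.2) & (frac <= 0.8))[0]
    if sel.size < 2:
        raise ValueError("too few samples in the 20-80% decay window for a fit")
    if np.any(np.diff(frac[sel]) >= 0.05):  # tolerate sub-noise jitter only
        raise ValueError("non-monotone decay segment; cannot fit time constant")
    y = np.log(frac[sel])
    x = sel * dt
    slope, _ = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("non-decaying transient")
    tau = -1.0 / slope
    cm = tau / (rs * rm / (rs + rm))
    return PassiveProps(
        rs_mohm=rs * 1e-6,
        rm_mohm=rm * 1e-6,
        cm_pf=cm * 1e12,
        tau_ms=tau * 1e3,
    )


def mean_passive_properties(before: PassiveProps, after: PassiveProps) -> PassiveProps:
    """Report the mean of the pre- and post-recording test-pulse estimates."""
    return PassiveProps(
        rs_mohm=(before.rs_mohm + after.rs_mohm) / 2,
        rm_mohm=(before.rm_mohm + after.rm_mohm) / 2,
        cm_pf=(before.cm_pf + after.cm_pf) / 2,
        tau_ms=(before.tau_ms + after.tau_ms) / 2,
    )


def sweep_qc(
    sweeps: list[SweepRecord],
    *,
    max_rs_deviation: float = 0.25,
    max_holding_pa: float = 100.0,
    min_kept_fraction: float = 0.5,
) -> tuple[list[SweepRecord], bool]:
    """Apply the sweep-stability rules; returns (annotated sweeps, cell keep).

    The series-resistance reference is the mean over the first three sweeps;
    a sweep is dropped when |Rs - ref|/ref > 25% or |holding| > 100 pA.  The
    cell is excluded when fewer than half the sweeps remain.
    """
    if len(sweeps) < 3:
        raise ValueError("need at least three sweeps for the Rs reference")
    ref = float(np.mean([s.rs_mohm for s in sweeps[:3]]))
    annotated: list[SweepRecord] = []
    for s in sweeps:
        if abs(s.rs_mohm - ref) / ref > max_rs_deviation:
            annotated.append(SweepRecord(s.sweep_id, s.rs_mohm, s.holding_pa, False, "rs_deviation"))
        elif abs(s.holding_pa) > max_holding_pa:
            annotated.append(SweepRecord(s.sweep_id, s.rs_mohm, s.holding_pa, False, "holding_current"))
        else:
            annotated.append(SweepRecord(s.sweep_id, s.rs_mohm, s.holding_pa, True, ""))
    kept = sum(s.keep for s in annotated)
    cell_keep = kept >= min_kept_fraction * len(annotated)
    return annotated, cell_keep


def bandstop_condition(
    trace: np.ndarray,
    sample_rate_hz: float,
    line_hz: float = 60.0,
    n_harmonics: int = 5,
    q: float = 30.0,
) -> np.ndarray:
    """Remove line noise: cascaded notch filters at 60, 120, ... Hz.

    Contract: each harmonic is attenuated by at least 20 dB while tones well
    outside the notches (30 Hz, 1 kHz) pass within 1 dB.  Zero-phase
    (forward-backward) filtering, so no group delay is introduced.
    """
    top = line_hz * n_harmonics
    if sample_rate_hz <= 2 * top:
        raise ValueError(
            f"sample rate {sample_rate_hz:g} Hz too low for a {top:g} Hz notch"
        )
    x = np.asarray(trace, dtype=float)
    for h in range(1, n_harmonics + 1):
        b, a = _sig.iirnotch(line_hz * h, q, fs=sample_rate_hz)
        x = _sig.filtfilt(b, a, x)
    return x


def doublet_exclusion(
    train: EventTrain, min_separation_ms: float = 3.0
) -> tuple[EventTrain, np.ndarray]:
    """Drop events closer than 3 ms to the last *kept* event.

    Sequential scan: the first event of any cluster is kept; later events
    are excluded while they fall within ``min_separation_ms`` of the most
    recently kept one (so in {0, 2, 4} ms, 2 is excluded but 4 is kept).
    Returns (filtered train, excluded flags aligned to the input) — events
    are flagged, never silently dropped.
    """
    t = train.times_ms
    if np.any(np.diff(t) < 0):
        raise ValueError("event times must be sorted")
    excluded = np.zeros(t.size, dtype=bool)
    last_kept = -np.inf
    for i, ti in enumerate(t):
        if ti - last_kept < min_separation_ms:
            excluded[i] = True
        else:
            last_kept = ti
    keep = ~excluded
    filtered = EventTrain(
        times_ms=t[keep],
        amplitudes_pa=train.amplitudes_pa[keep],
        duration_ms=train.duration_ms,
        is_doublet=train.is_doublet[keep],
    )
    return filtered, excluded


def train_summary(
    train: EventTrain,
    noise_masks_ms: list[tuple[float, float]] | None = None,
) -> dict:
    """Event frequency and amplitude / inter-event-interval distributions.

    ``noise_masks_ms`` are user-noted [start, end) intervals with elevated
    noise; events inside them are dropped and the masked time is removed
    from the duration used for the frequency.
    """
    masks = noise_masks_ms or []
    t = train.times_ms
    keep = np.ones(t.size, dtype=bool)
    masked_ms = 0.0
    for lo, hi in masks:
        lo, hi = max(0.0, lo), min(train.duration_ms, hi)
        if hi <= lo:
            continue
        keep &= ~((t >= lo) & (t < hi))
        masked_ms += hi - lo
    unmasked_s = (train.duration_ms - masked_ms) / 1e3
    if unmasked_s <= 0:
        raise ValueError("unmasked duration must be positive")
    kept_t = t[keep]
    return {
        "frequency_hz": kept_t.size / unmasked_s,
        "amplitudes_pa": train.amplitudes_pa[keep],
        "inter_event_intervals_ms": np.diff(kept_t),
        "n_events": int(kept_t.size),
        "n_masked_out": int((~keep).sum()),
        "unmasked_duration_s": unmasked_s,
    }
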