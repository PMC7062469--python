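"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (contact scoring, calcium QC and
response extraction, event detection, passive-property estimation,
hierarchical bootstrap) consumes data whose real-world counterparts are
two-photon movies and patch-clamp recordings.  This module generates all of
them from a single seeded random generator so that each stage can be tested
against the generating model:

* two-channel microglia/spine movies on a 3-minute frame interval with
  motile processes and an optional targeting bias toward mushroom spines;
* trial-structured GCaMP-like fluorescence traces at 4 Hz with a baseline
  segment, a 2 s odor pulse, blank ("no odor") trials, optional
  photobleaching drift, and double-exponential transients;
* single-compartment RC test-pulse currents (-10 mV, 20 ms steps);
* two-level (e.g. mouse -> dendrite) Gaussian value tables;
* Poisson synaptic-event trains with a controlled fraction of sub-3-ms
  double detections.

All randomness flows from ``numpy.random.default_rng(seed)`` per dataset;
there is no global state, so identical (seed, config) pairs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.draw import disk as _sk_disk

from .contact import FILOPODIAL, MUSHROOM, SpineROI
from .hstats import HierarchicalDataset

__all__ = [
    "SynthConfig",
    "ContactMovie",
    "CalciumDataset",
    "TestPulse",
    "EventTrain",
    "make_contact_movie",
    "make_calcium_dataset",
    "make_rc_testpulse",
    "make_hierarchical_values",
    "make_event_train",
    "gcamp_kernel",
    "threshold_segment",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared acquisition parameters for the synthetic experiments.

    Defaults mirror the acquisition the pipeline targets: z-stacks of the
    microglia/spine channels every 3 minutes, calcium frames at 4 Hz, a
    15-odor panel with 3-5 repeats plus one blank trial per repeat set.
    """

    seed: int = 0
    image_size_px: int = 800
    frame_interval_min: float = 3.0
    frame_rate_hz: float = 4.0
    n_odors: int = 15
    n_repeats: int = 4
    baseline_s: float = 10.0
    odor_duration_s: float = 2.0
    analysis_window_s: float = 5.0
    post_s: float = 10.0

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        if self.frame_rate_hz <= 0 or self.frame_interval_min <= 0:
            raise ValueError("rates must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Microglia-spine contact movies


@dataclass
class ContactMovie:
    """Two-channel movie plus ROIs and generation ground truth.

    ``dendrite`` is a 16-bit intensity stack, ``microglia_mask`` a binary
    stack of the same (T, H, W) shape.  ``true_contact_frames`` maps
    spine_id -> frame indices where a process was deliberately placed on
    that spine head.
    """

    dendrite: np.ndarray
    microglia_mask: np.ndarray
    spines: list[SpineROI]
    frame_interval_min: float
    true_contact_frames: dict[str, np.ndarray]


def _torus_disk(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Disk pixel indices with wrap-around placement (stationary on the torus)."""
    H, W = shape
    rr, cc = _sk_disk((float(center[0]), float(center[1])), radius,
                      shape=None)
    return rr % H, cc % W


def make_contact_movie(
    cfg: SynthConfig,
    n_spines: int = 20,
    bias: float = 0.0,
    motility_px_per_frame: float = 4.0,
    n_frames: int = 16,
    n_processes: int = 30,
    process_radius_px: float = 3.0,
    spine_radius_px: float = 3.0,
    p_targeted_contact: float = 0.1,
) -> ContactMovie:
    """Generate a two-channel microglia/spine movie with ground truth.

    Microglial processes are modelled as disks performing independent random
    walks on the image torus, so with ``bias = 0`` the mask is statistically
    translation-invariant and independent of spine placement — exactly the
    situation the channel-offset null assumes.  With ``bias > 0``, each
    mushroom spine additionally receives a process placed directly on its
    head in each frame with probability ``min(1, bias * p_targeted_contact)``;
    those frames are recorded as ground-truth contacts.

    Half the spines (rounded up) are mushroom (round bright heads), the rest
    filopodial (thin headless protrusions).
    """
    if n_spines < 1:
        raise ValueError("n_spines must be >= 1")
    if bias < 0:
        raise ValueError("bias must be >= 0")
    rng = cfg.rng()
    S = cfg.image_size_px
    shape = (S, S)

    # spine ROIs: centers away from the border so polygons stay in bounds
    margin = spine_radius_px + 4
    spines: list[SpineROI] = []
    centers = rng.uniform(margin, S - margin, size=(n_spines, 2))
    theta = np.linspace(0, 2 * np.pi, 13, endpoint=False)
    for i, (r0, c0) in enumerate(centers):
        mushroom = i < (n_spines + 1) // 2
        if mushroom:
            rad = spine_radius_px * rng.uniform(0.8, 1.2)
            poly = np.column_stack([r0 + rad * np.sin(theta), c0 + rad * np.cos(theta)])
        else:
            # filopodial: thin elongated protrusion, no head
            ang = rng.uniform(0, np.pi)
            half_len = spine_radius_px * rng.uniform(1.5, 2.5)
            half_w = max(0.9, spine_radius_px * 0.35)
            a = np.array([np.sin(ang), np.cos(ang)])
            b = np.array([-np.cos(ang), np.sin(ang)])
            poly = np.array(
                [
                    [r0, c0] + half_len * a + half_w * b,
                    [r0, c0] + half_len * a - half_w * b,
                    [r0, c0] - half_len * a - half_w * b,
                    [r0, c0] - half_len * a + half_w * b,
                ]
            )
        poly = np.clip(poly, 0.0, S - 1.0)
        spines.append(
            SpineROI(
                spine_id=f"sp{i:03d}",
                spine_class=MUSHROOM if mushroom else FILOPODIAL,
                polygon=poly,
            )
        )

    # dendrite channel: static shaft plus bright spine heads, mild shot noise
    dendrite0 = np.zeros(shape, dtype=float)
    shaft_r = rng.uniform(0, S, size=3)
    for r in shaft_r:
        dendrite0[int(r) % S, :] = 800.0
    for sp in spines:
        rr, cc = sp.raster_indices(shape)
        dendrite0[rr, cc] = 3000.0 if sp.spine_class == MUSHROOM else 1500.0

    # microglia: random-walking process disks on the torus
    proc_pos = rng.uniform(0, S, size=(n_processes, 2))
    p_hit = min(1.0, bias * p_targeted_contact)
    mask = np.zeros((n_frames, S, S), dtype=bool)
    dendrite = np.empty((n_frames, S, S), dtype=np.uint16)
    true_contacts: dict[str, list[int]] = {sp.spine_id: [] for sp in spines}
    for t in range(n_frames):
        frame = np.zeros(shape, dtype=bool)
        for p in range(n_processes):
            rr, cc = _torus_disk(shape, tuple(proc_pos[p]), process_radius_px)
            frame[rr, cc] = True
        if p_hit > 0:
            for sp in spines:
                if sp.spine_class != MUSHROOM:
                    continue
                if rng.random() < p_hit:
                    center = sp.polygon.mean(axis=0)
                    rr, cc = _torus_disk(shape, (center[0], center[1]), process_radius_px)
                    frame[rr, cc] = True
                    true_contacts[sp.spine_id].append(t)
        mask[t] = frame
        noisy = dendrite0 + rng.normal(0, 30.0, size=shape)
        dendrite[t] = np.clip(noisy, 0, 65535).astype(np.uint16)
        proc_pos = (proc_pos + rng.normal(0, motility_px_per_frame, size=proc_pos.shape)) % S

    return ContactMovie(
        dendrite=dendrite,
        microglia_mask=mask,
        spines=spines,
        frame_interval_min=cfg.frame_interval_min,
        true_contact_frames={k: np.asarray(v, dtype=int) for k, v in true_contacts.items()},
    )


def threshold_segment(intensity_stack: np.ndarray, threshold: float) -> np.ndarray:
    """Binary microglia mask from a raw intensity movie by global thresholding.

    Contract: one binary mask per frame.  This is a convenience for users
    with raw intensity movies; curated segmentations should be supplied
    directly as binary stacks.
    """
    stack = np.asarray(intensity_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("intensity_stack must be (T, H, W)")
    return stack > threshold


# ---------------------------------------------------------------------------
# Calcium traces


def gcamp_kernel(
    t_s: np.ndarray, rise_s: float = 0.2, decay_s: float = 1.5
) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalized to 1.

    Rise/decay defaults are plausible GCaMP6s time constants; the response
    pipeline is insensitive to the exact kernel shape.
    """
    t = np.asarray(t_s, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    peak_t = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-peak_t / decay_s) - np.exp(-peak_t / rise_s)
    return k / peak


@dataclass
class CalciumDataset:
    """Long-format trial traces plus generation ground truth.

    ``traces`` maps (mouse_id, dendrite_id, odor_id, trial) -> 1-D
    fluorescence array; odor_id ``"blank"`` marks no-odor trials.
    ``true_amplitude`` maps (mouse_id, dendrite_id, odor_id) to the injected
    transient amplitude in raw fluorescence units (0 for non-responders).
    """

    traces: dict[tuple[str, str, str, int], np.ndarray]
    frame_rate_hz: float
    baseline_s: float
    odor_duration_s: float
    analysis_window_s: float
    noise_sd: float
    f0: float
    true_amplitude: dict[tuple[str, str, str], float]

    @property
    def n_frames(self) -> int:
        return next(iter(self.traces.values())).size

    @property
    def odor_onset_frame(self) -> int:
        return int(round(self.baseline_s * self.frame_rate_hz))

    def odor_ids(self) -> list[str]:
        return sorted({k[2] for k in self.traces} - {"blank"})


BLANK = "blank"


def make_calcium_dataset(
    cfg: SynthConfig,
    n_mice: int = 3,
    n_dendrites_per_mouse: int = 10,
    p_respond: float = 0.2,
    amp_sd_units: float = 3.0,
    bleach_tau_s: float | None = None,
    noise_sd: float = 5.0,
    f0: float = 100.0,
) -> CalciumDataset:
    """Trial-structured GCaMP-like traces with known responders.

    Each dendrite x odor pair is a responder with probability ``p_respond``;
    responders carry a double-exponential transient of amplitude
    ``amp_sd_units * noise_sd`` starting at odor onset, identical across
    repeats.  One blank trial accompanies every repeat set.  When
    ``bleach_tau_s`` is set the whole trace decays as exp(-t/tau).
    """
    if not 0 <= p_respond <= 1:
        raise ValueError("p_respond must be in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = cfg.rng()
    fs = cfg.frame_rate_hz
    n_frames = int(round((cfg.baseline_s + cfg.odor_duration_s + cfg.post_s) * fs))
    onset = int(round(cfg.baseline_s * fs))
    t_rel = (np.arange(n_frames) - onset) / fs
    kernel = gcamp_kernel(t_rel)
    decay = (
        np.exp(-np.arange(n_frames) / (bleach_tau_s * fs))
        if bleach_tau_s is not None
        else np.ones(n_frames)
    )

    traces: dict[tuple[str, str, str, int], np.ndarray] = {}
    amp_true: dict[tuple[str, str, str], float] = {}
    odors = [f"odor{j:02d}" for j in range(cfg.n_odors)]
    for m in range(n_mice):
        mouse = f"m{m:02d}"
        for d in range(n_dendrites_per_mouse):
            dend = f"d{d:03d}"
            for odor in odors:
                amp = amp_sd_units * noise_sd if rng.random() < p_respond else 0.0
                amp_true[(mouse, dend, odor)] = amp
                for trial in range(cfg.n_repeats):
                    clean = (f0 + amp * kernel) * decay
                    traces[(mouse, dend, odor, trial)] = clean + rng.normal(
                        0, noise_sd, size=n_frames
                    )
            amp_true[(mouse, dend, BLANK)] = 0.0
            for trial in range(cfg.n_repeats):
                traces[(mouse, dend, BLANK, trial)] = f0 * decay + rng.normal(
                    0, noise_sd, size=n_frames
                )
    return CalciumDataset(
        traces=traces,
        frame_rate_hz=fs,
        baseline_s=cfg.baseline_s,
        odor_duration_s=cfg.odor_duration_s,
        analysis_window_s=cfg.analysis_window_s,
        noise_sd=noise_sd,
        f0=f0,
        true_amplitude=amp_true,
    )


# ---------------------------------------------------------------------------
# RC test pulses


@dataclass
class TestPulse:
    """Voltage-clamp test-pulse recording (single or repeated sweeps).

    ``current_pa`` is (n_repetitions, n_samples); ``t_s`` the shared time
    base.  The voltage step spans [step_onset_s, step_onset_s + duration].
    """

    t_s: np.ndarray
    current_pa: np.ndarray
    delta_v_mv: float
    step_onset_s: float
    step_duration_s: float
    sample_rate_hz: float

    def mean_current(self) -> np.ndarray:
        return self.current_pa.mean(axis=0)


def make_rc_testpulse(
    rs_mohm: float,
    rm_mohm: float,
    cm_pf: float,
    noise_pa: float = 0.0,
    *,
    delta_v_mv: float = -10.0,
    duration_ms: float = 20.0,
    sample_rate_hz: float = 20_000.0,
    n_repetitions: int = 50,
    baseline_ms: float = 5.0,
    seed: int = 0,
) -> TestPulse:
    """Current response of the single-compartment voltage-clamp circuit.

    For a step dV applied through series resistance Rs onto a membrane
    (Rm || Cm): instantaneous current dV/Rs, steady state dV/(Rs+Rm),
    relaxation time constant tau = Cm * Rs*Rm/(Rs+Rm).  White noise of SD
    ``noise_pa`` is added independently per repetition.
    """
    if min(rs_mohm, rm_mohm, cm_pf) <= 0:
        raise ValueError("rs, rm, cm must be positive")
    rs = rs_mohm * 1e6
    rm = rm_mohm * 1e6
    cm = cm_pf * 1e-12
    dv = delta_v_mv * 1e-3
    tau = cm * rs * rm / (rs + rm)
    dt = 1.0 / sample_rate_hz
    n_base = int(round(baseline_ms * 1e-3 / dt))
    n_step = int(round(duration_ms * 1e-3 / dt))
    n_post = n_base
    n = n_base + n_step + n_post
    t = np.arange(n) * dt
    i = np.zeros(n)
    ts = (np.arange(n_step)) * dt  # first in-step sample at the step instant
    i_ss = dv / (rs + rm)
    i[n_base : n_base + n_step] = i_ss + (dv / rs - i_ss) * np.exp(-ts / tau)
    # relaxation back to zero after the step, same tau
    i[n_base + n_step :] = (i[n_base + n_step - 1] - dv / rs) * np.exp(
        -np.arange(n_post) * dt / tau
    )
    i_pa = i * 1e12
    rng = np.random.default_rng(seed)
    sweeps = i_pa[None, :] + rng.normal(0, noise_pa, size=(n_repetitions, n))
    return TestPulse(
        t_s=t,
        current_pa=sweeps,
        delta_v_mv=delta_v_mv,
        step_onset_s=n_base * dt,
        step_duration_s=n_step * dt,
        sample_rate_hz=sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# Hierarchical value tables


def make_hierarchical_values(
    n_upper: int,
    n_lower_per_upper: int | Sequence[int],
    between_sd: float,
    within_sd: float,
    effect: float = 0.0,
    *,
    grand_mean: float = 0.0,
    seed: int = 0,
) -> tuple[HierarchicalDataset, HierarchicalDataset]:
    """Two-level Gaussian control/treated datasets.

    Upper-unit means are N(grand_mean, between_sd^2); values within a unit
    are N(unit mean, within_sd^2).  The treated group's grand mean is
    shifted by ``-effect``.
    """
    if between_sd < 0 or within_sd < 0:
        raise ValueError("sds must be >= 0")
    rng = np.random.default_rng(seed)
    if np.isscalar(n_lower_per_upper):
        sizes = [int(n_lower_per_upper)] * n_upper
    else:
        sizes = [int(x) for x in n_lower_per_upper]
        if len(sizes) != n_upper:
            raise ValueError("n_lower_per_upper length must equal n_upper")

    def one(mean: float, label: str) -> HierarchicalDataset:
        units = {}
        for u in range(n_upper):
            mu = rng.normal(mean, between_sd)
            units[f"u{u:02d}"] = rng.normal(mu, within_sd, size=sizes[u])
        return HierarchicalDataset(units=units, group=label)

    return one(grand_mean, "control"), one(grand_mean - effect, "treated")


# ---------------------------------------------------------------------------
# Synaptic event trains


@dataclass
class EventTrain:
    """Sorted event times with amplitudes; doublets flagged in ground truth."""

    times_ms: np.ndarray
    amplitudes_pa: np.ndarray
    duration_ms: float
    is_doublet: np.ndarray  # ground truth: injected duplicate detections

    def __len__(self) -> int:
        return self.times_ms.size


def make_event_train(
    rate_hz: float,
    duration_s: float,
    doublet_fraction: float = 0.0,
    seed: int = 0,
    *,
    amp_mean_pa: float = 10.0,
    amp_sd_pa: float = 3.0,
) -> EventTrain:
    """Poisson event train with a controlled fraction of double detections.

    A ``doublet_fraction`` of the primary events is duplicated at a random
    offset below 3 ms; duplicates are flagged in ``is_doublet``.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0, duration_s * 1e3, size=n))
    dup_mask = rng.random(n) < doublet_fraction
    dup_times = times[dup_mask] + rng.uniform(0.2, 2.9, size=int(dup_mask.sum()))
    all_times = np.concatenate([times, dup_times])
    all_flags = np.concatenate([np.zeros(n, bool), np.ones(dup_times.size, bool)])
    order = np.argsort(all_times, kind="stable")
    amps = np.abs(rng.normal(amp_mean_pa, amp_sd_pa, size=all_times.size))
    return EventTrain(
        times_ms=all_times[order],
        amplitudes_pa=amps[order],
        duration_ms=duration_s * 1e3,
        is_doublet=all_flags[order],
    )
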