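"""Microglia-spine interaction scoring against a channel-offset chance null.

A spine head is scored as *covered* in a frame when the binary microglia
mask overlaps its ROI polygon; the fraction of ROI pixels that are
mask-positive is the coverage fraction, and a frame with coverage at or
above the interaction criterion (default 5% of the spine-head area) counts
toward an interaction.  Because microglial processes tile the neuropil,
apparent contact can arise by chance; the null model translates the
microglia channel circularly relative to the dendrite channel (horizontal,
vertical and diagonal shifts, starting beyond the maximum spine width and
stepping by the mean spine width) and recomputes every statistic at each
offset.  A one-tailed permutation test then asks whether the statistic in
the unshifted data exceeds the offset distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "SpineROI",
    "ContactSeries",
    "Interaction",
    "OffsetGrid",
    "InteractionSummary",
    "coverage_fraction",
    "detect_interactions",
    "summarize_dendrite",
    "generate_offsets",
    "offset_statistics",
    "permutation_test_one_tailed",
    "AllFramesInvalidError",
]

MUSHROOM = "mushroom"
FILOPODIAL = "filopodial"


class AllFramesInvalidError(ValueError):
    """Raised when a coverage series has no valid frames at all.

    Distinct from the legitimate outcome "valid frames but no interaction".
    """


@dataclass(frozen=True)
class SpineROI:
    """Spine-head region of interest drawn in its single brightest plane.

    ``polygon`` holds 0-based (row, col) pixel vertices as an (N, 2) float
    array.  ``area_px`` is the rasterized pixel count, filled on first use.
    """

    spine_id: str
    spine_class: str  # "mushroom" or "filopodial"
    polygon: np.ndarray
    plane_index: int = 0

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (N>=3, 2) vertex array")
        object.__setattr__(self, "polygon", poly)
        if self.spine_class not in (MUSHROOM, FILOPODIAL):
            raise ValueError(f"unknown spine class {self.spine_class!r}")

    def raster_indices(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of pixels inside the polygon, checked against *shape*."""
        poly = self.polygon
        if poly[:, 0].min() < 0 or poly[:, 1].min() < 0:
            raise ValueError(f"spine {self.spine_id}: polygon extends below 0")
        if poly[:, 0].max() > shape[0] - 1 or poly[:, 1].max() > shape[1] - 1:
            raise ValueError(f"spine {self.spine_id}: polygon exceeds image bounds")
        rr, cc = _sk_polygon(poly[:, 0], poly[:, 1], shape=shape)
        if rr.size == 0:
            raise ValueError(f"spine {self.spine_id}: polygon rasterizes to zero pixels")
        return rr, cc

    @property
    def area_px(self) -> int:
        # upper bound of the bbox is enough for area; real bounds are checked
        # against the actual image inside raster_indices
        shape = (int(self.polygon[:, 0].max()) + 2, int(self.polygon[:, 1].max()) + 2)
        rr, _ = self.raster_indices(shape)
        return int(rr.size)


@dataclass
class ContactSeries:
    """Per-frame fractional microglial coverage of one spine head."""

    spine_id: str
    coverage: np.ndarray  # fraction in [0, 1] per frame
    frame_interval_min: float
    valid_frames: np.ndarray | None = None  # bool per frame; None = all valid

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.coverage.ndim != 1 or self.coverage.size < 1:
            raise ValueError("coverage must be a non-empty 1-D array")
        if np.nanmin(self.coverage) < 0 or np.nanmax(self.coverage) > 1:
            raise ValueError("coverage fractions must lie in [0, 1]")
        if self.valid_frames is None:
            self.valid_frames = np.ones(self.coverage.size, dtype=bool)
        else:
            self.valid_frames = np.asarray(self.valid_frames, dtype=bool)
            if self.valid_frames.shape != self.coverage.shape:
                raise ValueError("valid_frames must match coverage length")


@dataclass(frozen=True)
class Interaction:
    """One maximal run of frames meeting the coverage criterion."""

    start_frame: int
    end_frame: int  # inclusive
    length_min: float
    max_coverage: float


@dataclass(frozen=True)
class OffsetGrid:
    """Circular channel translations defining the chance null."""

    offsets: tuple[tuple[int, int], ...]  # (drow, dcol)
    start_px: int
    step_px: int
    image_size_px: int

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass(frozen=True)
class InteractionSummary:
    """Dendrite-level interaction statistics over one spine class."""

    n_spines: int
    prop_with_interaction: float
    rate_per_10min: float
    mean_length_min: float  # NaN when no spine interacted
    mean_max_coverage: float  # NaN when no spine interacted
    mean_coverage: float


def coverage_fraction(spine: SpineROI, mask: np.ndarray) -> float:
    """Fraction of the spine-head ROI overlapped by the binary microglia mask.

    Parameters
    ----------
    spine : SpineROI
    mask : 2-D bool/int array, one segmented microglia frame.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D image")
    rr, cc = spine.raster_indices(mask.shape)
    return float(np.count_nonzero(mask[rr, cc])) / rr.size


def detect_interactions(
    series: ContactSeries,
    criterion: float = 0.05,
    *,
    strict: bool = False,
) -> list[Interaction]:
    """Find maximal runs of consecutive valid frames meeting the criterion.

    ``strict=False`` (default) treats coverage equal to the criterion as a
    contact ("at least 5% of the area of a spine head"); ``strict=True``
    requires strictly greater coverage.  Invalid frames break runs.
    """
    if not 0 < criterion < 1:
        raise ValueError("criterion must be in (0, 1)")
    valid = series.valid_frames
    if not valid.any():
        raise AllFramesInvalidError(
            f"spine {series.spine_id}: no valid frames in coverage series"
        )
    c = series.coverage
    hit = (c > criterion) if strict else (c >= criterion)
    hit = hit & valid
    out: list[Interaction] = []
    start = None
    for i, h in enumerate(hit):
        if h and start is None:
            start = i
        elif not h and start is not None:
            out.append(_make_interaction(series, start, i - 1))
            start = None
    if start is not None:
        out.append(_make_interaction(series, start, len(hit) - 1))
    return out


def _make_interaction(series: ContactSeries, start: int, end: int) -> Interaction:
    return Interaction(
        start_frame=start,
        end_frame=end,
        length_min=(end - start + 1) * series.frame_interval_min,
        max_coverage=float(series.coverage[start : end + 1].max()),
    )


def summarize_dendrite(
    interactions_per_spine: dict[str, list[Interaction]],
    total_valid_minutes: float,
    coverage_per_spine: dict[str, np.ndarray] | None = None,
) -> InteractionSummary:
    """Aggregate per-spine interactions into dendrite-level statistics.

    The interaction rate is normalized to a 10-minute observation window and
    averaged (unweighted) across spines.  Mean interaction length and mean
    peak coverage are computed only over spines with at least one
    interaction, and reported as NaN when no spine interacted.
    """
    if total_valid_minutes <= 0:
        raise ValueError("total_valid_minutes must be positive")
    if not interactions_per_spine:
        raise ValueError("no spines supplied")
    n = len(interactions_per_spine)
    rates = [
        len(ints) * 10.0 / total_valid_minutes
        for ints in interactions_per_spine.values()
    ]
    with_int = [ints for ints in interactions_per_spine.values() if ints]
    if with_int:
        mean_length = float(np.mean([np.mean([i.length_min for i in ints]) for ints in with_int]))
        mean_maxcov = float(np.mean([np.mean([i.max_coverage for i in ints]) for ints in with_int]))
    else:
        mean_length = float("nan")
        mean_maxcov = float("nan")
    if coverage_per_spine:
        mean_cov = float(np.mean([np.mean(c) for c in coverage_per_spine.values()]))
    else:
        mean_cov = float("nan")
    return InteractionSummary(
        n_spines=n,
        prop_with_interaction=len(with_int) / n,
        rate_per_10min=float(np.mean(rates)),
        mean_length_min=mean_length,
        mean_max_coverage=mean_maxcov,
        mean_coverage=mean_cov,
    )


def generate_offsets(
    image_size_px: int, start_px: int = 32, step_px: int = 10
) -> OffsetGrid:
    """Build the circular-shift offset grid for the chance null.

    Shift magnitudes run ``start_px, start_px + step_px, ...`` up to the
    largest value strictly below ``image_size_px``; each magnitude is applied
    horizontally, vertically, and diagonally (equal row/col components), so
    the total count is three times the per-axis count.  An 800-px field with
    the defaults yields 77 magnitudes and 231 offsets.
    """
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    if not 0 < start_px < image_size_px:
        raise ValueError("start_px must satisfy 0 < start_px < image_size_px")
    magnitudes = np.arange(start_px, image_size_px, step_px, dtype=int)
    offsets: list[tuple[int, int]] = []
    for m in magnitudes:
        offsets.append((0, int(m)))  # horizontal
    for m in magnitudes:
        offsets.append((int(m), 0))  # vertical
    for m in magnitudes:
        offsets.append((int(m), int(m)))  # diagonal
    return OffsetGrid(
        offsets=tuple(offsets),
        start_px=start_px,
        step_px=step_px,
        image_size_px=image_size_px,
    )


# ---------------------------------------------------------------------------
# Whole-movie scoring


def _spine_pixel_table(
    spines: Sequence[SpineROI], shape: tuple[int, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    return [s.raster_indices(shape) for s in spines]


def score_movie(
    mask_stack: np.ndarray,
    spines: Sequence[SpineROI],
    frame_interval_min: float = 3.0,
    valid_frames: np.ndarray | None = None,
    offset: tuple[int, int] = (0, 0),
) -> dict[str, ContactSeries]:
    """Coverage series for every spine, optionally under a circular mask shift.

    ``offset`` = (drow, dcol) translates the microglia channel; sampling the
    shifted mask at a spine pixel (r, c) reads ``mask[(r - drow) % H,
    (c - dcol) % W]``, i.e. shifts wrap around the field of view.
    """
    mask_stack = np.asarray(mask_stack)
    if mask_stack.ndim != 3:
        raise ValueError("mask_stack must be (T, H, W)")
    T, H, W = mask_stack.shape
    drow, dcol = offset
    out: dict[str, ContactSeries] = {}
    for spine, (rr, cc) in zip(spines, _spine_pixel_table(spines, (H, W))):
        r = (rr - drow) % H
        c = (cc - dcol) % W
        cov = mask_stack[:, r, c].astype(bool).mean(axis=1)
        out[spine.spine_id] = ContactSeries(
            spine_id=spine.spine_id,
            coverage=cov,
            frame_interval_min=frame_interval_min,
            valid_frames=valid_frames,
        )
    return out


_STATISTICS: dict[str, Callable[[InteractionSummary], float]] = {
    "mean_coverage": lambda s: s.mean_coverage,
    "prop_with_interaction": lambda s: s.prop_with_interaction,
    "rate_per_10min": lambda s: s.rate_per_10min,
    "mean_length_min": lambda s: s.mean_length_min,
    "mean_max_coverage": lambda s: s.mean_max_coverage,
}


def movie_statistic(
    mask_stack: np.ndarray,
    spines: Sequence[SpineROI],
    statistic: str = "mean_coverage",
    criterion: float = 0.05,
    frame_interval_min: float = 3.0,
    spine_class: str | None = None,
    valid_frames: np.ndarray | None = None,
    offset: tuple[int, int] = (0, 0),
) -> float:
    """One dendrite-level summary value for a movie at a given channel offset."""
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    use = [s for s in spines if spine_class is None or s.spine_class == spine_class]
    if not use:
        raise ValueError(f"no spines of class {spine_class!r}")
    series = score_movie(mask_stack, use, frame_interval_min, valid_frames, offset)
    interactions = {sid: detect_interactions(s, criterion) for sid, s in series.items()}
    n_valid = int(next(iter(series.values())).valid_frames.sum())
    total_min = n_valid * frame_interval_min
    summary = summarize_dendrite(
        interactions,
        total_valid_minutes=total_min,
        coverage_per_spine={sid: s.coverage[s.valid_frames] for sid, s in series.items()},
    )
    return _STATISTICS[statistic](summary)


def offset_statistics(
    mask_stack: np.ndarray,
    spines: Sequence[SpineROI],
    grid: OffsetGrid,
    statistic: str = "mean_coverage",
    criterion: float = 0.05,
    frame_interval_min: float = 3.0,
    spine_class: str | None = None,
    valid_frames: np.ndarray | None = None,
) -> np.ndarray:
    """Null distribution: the chosen statistic recomputed at every grid offset.

    Per-offset failures propagate as NaN entries (never silently dropped);
    ``permutation_test_one_tailed`` excludes them with a warning.
    """
    if len(grid) == 0:
        raise ValueError("offset grid is empty")
    out = np.empty(len(grid), dtype=float)
    for i, off in enumerate(grid.offsets):
        try:
            out[i] = movie_statistic(
                mask_stack,
                spines,
                statistic=statistic,
                criterion=criterion,
                frame_interval_min=frame_interval_min,
                spine_class=spine_class,
                valid_frames=valid_frames,
                offset=off,
            )
        except (ValueError, AllFramesInvalidError):
            out[i] = np.nan
    return out


def permutation_test_one_tailed(observed: float, null: np.ndarray) -> float:
    """One-tailed permutation p-value: is the observed statistic high?

    p = (1 + #{null >= observed}) / (N + 1), the add-one convention, so p is
    never exactly 0.  NaN null entries are excluded from N with a warning.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    missing = int(np.isnan(null).sum())
    if missing:
        warnings.warn(
            f"{missing} of {null.size} null entries missing; excluded from the test",
            stacklevel=2,
        )
        null = null[~np.isnan(null)]
        if null.size == 0:
            raise ValueError("all null entries missing")
    k = int(np.count_nonzero(null >= observed))
    return (1.0 + k) / (null.size + 1.0)
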