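"""Spine classification, density, and head-volume summaries from
filament-tracing morphometry tables.

Tables follow the Imaris export convention: one row per spine with
"HeadMaxDiameter", "NeckMeanDiameter" and "Spine Part Volume Head"
columns, and per-dendrite "Filament No. Spine Terminal Pts" counts.
A spine is *filopodial* when its maximum head diameter is less than 1.5
times its mean neck diameter (no distinct head), otherwise *mushroom*;
density counts spine terminal points per micron of dendrite (branched
spines count once per head), restricted to dendrites at least 40 µm long,
and protrusions 10 µm or longer are not spines.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from . import hstats
from .contact import FILOPODIAL, MUSHROOM

logger = logging.getLogger(__name__)

__all__ = [
    "IMARIS_COLUMNS",
    "classify_spine",
    "classify_table",
    "spine_density",
    "cell_density",
    "volume_summary",
]

#: accepted Imaris-style header strings -> tidy names
IMARIS_COLUMNS = {
    "Filament No. Spine Terminal Pts": "terminal_point_count",
    "Spine Part Volume Head": "head_volume_um3",
    "HeadMaxDiameter": "head_max_diameter_um",
    "NeckMeanDiameter": "neck_mean_diameter_um",
}

HEAD_NECK_RATIO = 1.5
MIN_DENDRITE_LENGTH_UM = 40.0
MAX_PROTRUSION_LENGTH_UM = 10.0


def classify_spine(head_max_diameter_um: float, neck_mean_diameter_um: float) -> str:
    """Mushroom/filopodial call from the head:neck diameter ratio.

    Filopodial iff head_max < 1.5 x neck_mean (strict); a ratio of exactly
    1.5 is mushroom.  Depends only on the ratio, so it is scale invariant.
    """
    if head_max_diameter_um <= 0 or neck_mean_diameter_um <= 0:
        raise ValueError("diameters must be positive")
    if head_max_diameter_um < HEAD_NECK_RATIO * neck_mean_diameter_um:
        return FILOPODIAL
    return MUSHROOM


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``spine_class`` column to a per-spine morphometry table.

    Accepts either tidy column names or the exact Imaris header strings;
    rows with a protrusion length of 10 µm or more are dropped (they are
    not spines) when a ``length_um`` column is present.
    """
    df = table.rename(columns=IMARIS_COLUMNS).copy()
    if "length_um" in df.columns:
        n0 = len(df)
        df = df[df["length_um"] < MAX_PROTRUSION_LENGTH_UM]
        if len(df) < n0:
            logger.info("dropped %d protrusions >= 10 um (not spines)", n0 - len(df))
    df["spine_class"] = [
        classify_spine(h, n)
        for h, n in zip(df["head_max_diameter_um"], df["neck_mean_diameter_um"])
    ]
    return df


def spine_density(terminal_point_count: int, dendrite_length_um: float) -> float:
    """Spines per micron for one dendrite (terminal-point counting rule).

    Dendrites shorter than 40 µm are ineligible and raise.
    """
    if dendrite_length_um < MIN_DENDRITE_LENGTH_UM:
        raise ValueError(
            f"dendrite too short for density ({dendrite_length_um:g} um < "
            f"{MIN_DENDRITE_LENGTH_UM:g} um)"
        )
    if terminal_point_count < 0:
        raise ValueError("terminal point count must be >= 0")
    return terminal_point_count / dendrite_length_um


def cell_density(dendrites: pd.DataFrame) -> float:
    """Unweighted mean density across one cell's (1-5) eligible dendrites.

    ``dendrites`` needs ``terminal_point_count`` and ``length_um`` columns.
    """
    dens = [
        spine_density(int(row.terminal_point_count), float(row.length_um))
        for row in dendrites.itertuples()
    ]
    if not dens:
        raise ValueError("no eligible dendrites")
    return float(np.mean(dens))


def volume_summary(
    spines: pd.DataFrame,
    *,
    group_col: str = "group",
    upper_col: str = "dendrite_id",
    value_col: str = "head_volume_um3",
    class_col: str | None = None,
    n_boot: int = 1000,
    n_lower: int = 100,
    seed: int = 0,
) -> dict[str, dict]:
    """Head-volume distributions and hierarchical-bootstrap means per group.

    The bootstrap resamples dendrites (upper level) then spines within each
    drawn dendrite (``n_lower`` per draw).  Empty classes/groups are
    omitted with a warning.  Returns per-group dicts with the raw values,
    the bootstrap result, and when exactly two groups are present a
    ``"p_direction"`` entry P(first group mean > second).
    """
    df = spines if class_col is None else spines
    out: dict[str, dict] = {}
    results = {}
    for i, (group, sub) in enumerate(df.groupby(group_col, sort=True)):
        if sub.empty:
            logger.warning("group %r empty; omitted", group)
            continue
        data = hstats.HierarchicalDataset.from_table(
            sub[upper_col].to_numpy(), sub[value_col].to_numpy(), group=str(group)
        )
        res = hstats.hierarchical_bootstrap(
            data, statistic="mean", n_boot=n_boot, n_lower=n_lower, seed=seed + i
        )
        results[str(group)] = res
        out[str(group)] = {
            "values": sub[value_col].to_numpy(dtype=float),
            "bootstrap": res,
            "mean": res.mean,
            "sd": res.sd,
        }
    if len(results) == 2:
        (ga, ra), (gb, rb) = sorted(results.items())
        out["p_direction"] = {
            "a": ga,
            "b": gb,
            "p": hstats.bootstrap_p(ra, rb),
        }
    return out
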