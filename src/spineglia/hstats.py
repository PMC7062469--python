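"""Hierarchical bootstrap and group-comparison statistics for nested data.

Imaging and slice-physiology datasets are nested: dozens of dendrites per
mouse, hundreds of spines per dendrite, thousands of synaptic events per
cell.  Treating the lowest-level observations as independent overstates the
effective sample size, so group comparisons here use a two-level bootstrap:
each iteration resamples the upper units (mice, dendrites, cells) with
replacement, then draws a fixed number of lower-level values with
replacement from each sampled unit — equal representation of units
regardless of how many observations each contributed.  The directional
probability P(statistic_A > statistic_B) across paired iterations serves as
the bootstrap p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats as _sps

__all__ = [
    "HierarchicalDataset",
    "BootstrapResult",
    "hierarchical_bootstrap",
    "bootstrap_p",
    "rank_and_distribution_tests",
]


@dataclass
class HierarchicalDataset:
    """Upper units (mice/dendrites/cells) mapped to their lower-level values."""

    units: dict[str, np.ndarray]
    group: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("dataset needs at least one upper unit")
        clean = {}
        for k, v in self.units.items():
            arr = np.asarray(v, dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"unit {k!r} has no values")
            clean[k] = arr
        self.units = clean

    @property
    def n_upper(self) -> int:
        return len(self.units)

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.units.values()))

    @classmethod
    def from_table(cls, upper_ids, values, group: str = "") -> "HierarchicalDataset":
        """Build from parallel (upper_id, value) columns of a tidy table."""
        upper_ids = np.asarray(upper_ids)
        values = np.asarray(values, dtype=float)
        units = {str(u): values[upper_ids == u] for u in np.unique(upper_ids)}
        return cls(units=units, group=group)


@dataclass
class BootstrapResult:
    """Bootstrap sampling distribution of a group-level statistic."""

    distribution: np.ndarray
    statistic: str
    n_lower: int

    @property
    def mean(self) -> float:
        return float(self.distribution.mean())

    @property
    def sd(self) -> float:
        """SD of the sampling distribution (the reported bootstrap SE)."""
        return float(self.distribution.std(ddof=0))


_STATS = {
    "mean": lambda x: x.mean(axis=-1),
    "median": lambda x: np.median(x, axis=-1),
}


def hierarchical_bootstrap(
    data: HierarchicalDataset,
    statistic: str = "mean",
    n_boot: int = 1000,
    n_lower: int = 100,
    seed: int | np.random.Generator = 0,
    proportion_predicate=None,
) -> BootstrapResult:
    """Two-level bootstrap sampling distribution of a pooled statistic.

    Each of the ``n_boot`` iterations draws ``n_upper`` units with
    replacement (the observed number of upper units), then ``n_lower``
    values with replacement within each drawn unit; the statistic is
    computed on the pooled ``n_upper * n_lower`` values.  ``n_lower`` should
    be chosen slightly larger than the largest per-unit sample so every unit
    is represented in full.

    ``statistic`` is one of ``"mean"``, ``"median"`` or ``"proportion"``;
    for ``"proportion"``, ``proportion_predicate`` maps a value array to a
    boolean array (default: value == 0).
    """
    if n_lower < 1 or n_boot < 1:
        raise ValueError("n_boot and n_lower must be >= 1")
    if statistic not in ("mean", "median", "proportion"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    values = list(data.units.values())
    sizes = np.array([v.size for v in values])
    flat = np.concatenate(values)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n_upper = data.n_upper

    unit_idx = rng.integers(0, n_upper, size=(n_boot, n_upper))
    # vectorized within-unit draw: uniform -> index into each unit's slice
    u = rng.random(size=(n_boot, n_upper, n_lower))
    within = np.floor(u * sizes[unit_idx][..., None]).astype(np.int64)
    draws = flat[offsets[unit_idx][..., None] + within]
    pooled = draws.reshape(n_boot, n_upper * n_lower)

    if statistic == "proportion":
        pred = proportion_predicate or (lambda x: x == 0)
        dist = pred(pooled).mean(axis=-1)
    else:
        dist = _STATS[statistic](pooled)
    return BootstrapResult(distribution=np.asarray(dist, float), statistic=statistic, n_lower=n_lower)


def bootstrap_p(res_a: BootstrapResult, res_b: BootstrapResult) -> float:
    """Directional probability P(A > B) over paired bootstrap iterations.

    Ties count 0.5, so p(A, B) + p(B, A) = 1 exactly.  Callers report p or
    1 - p depending on the direction of interest.
    """
    a, b = res_a.distribution, res_b.distribution
    if a.size != b.size:
        raise ValueError("bootstrap distributions must share n_boot")
    return float(np.mean(np.where(a > b, 1.0, np.where(a < b, 0.0, 0.5))))


def rank_and_distribution_tests(group_a, group_b) -> dict[str, float]:
    """Wilcoxon rank-sum and two-sample Kolmogorov-Smirnov comparisons.

    Thin delegation to the standard routines, returned together with the
    medians and interquartile ranges that accompany them in reports.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be nonempty")
    rs = _sps.ranksums(a, b)
    ks = _sps.ks_2samp(a, b)
    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return {
        "ranksum_z": float(rs.statistic),
        "ranksum_p": float(rs.pvalue),
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "median_a": float(qa[1]),
        "iqr_a_low": float(qa[0]),
        "iqr_a_high": float(qa[2]),
        "median_b": float(qb[1]),
        "iqr_b_low": float(qb[0]),
        "iqr_b_high": float(qb[2]),
    }
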