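"""Binary Bernoulli simulators for grouped and time-structured expression data.

Cells belong to groups; each group is characterized at each time point by
a small set of highly expressed genes (HEGs).  Entries are drawn
independently as Bernoulli(p_high) at a cell's own HEG positions and
Bernoulli(p_low) elsewhere, giving a dichotomized caricature of
scRNA-seq counts in which group structure is carried entirely by which
genes are "on" often.  HEG sets of distinct groups are disjoint at every
time point; within a group, consecutive time points share a designed
overlap of genes, mimicking gradual up- and down-regulation along a
developmental trajectory.

Gene indices are 1-based in design configuration and reports, matching
the usual table conventions; all in-memory arrays are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .boosting import StandardizedMatrix, standardize_columns

__all__ = [
    "TimeSeriesDesign",
    "TimeSeriesBundle",
    "default_timeseries_design",
    "stairlike_design",
    "simulate_binary_groups",
    "standardize_and_rescale_noise",
    "standardized_bundle",
    "bernoulli_noise_pool",
    "replace_top_genes_with_noise",
    "NOISE_FACTOR_TIMESERIES",
    "NOISE_FACTOR_STAIRLIKE",
]

#: post-standardization scaling of noise columns in the time-structured design
NOISE_FACTOR_TIMESERIES = 0.5
#: post-standardization scaling of noise columns in the stair-like design
NOISE_FACTOR_STAIRLIKE = 2.0 / 3.0


def _split_evenly(total: int, k: int) -> tuple:
    """Split ``total`` cells into ``k`` groups as evenly as possible,
    assigning remainder cells to the lowest-index groups."""
    base, rem = divmod(total, k)
    return tuple(base + (1 if g < rem else 0) for g in range(k))


@dataclass(frozen=True)
class TimeSeriesDesign:
    """Per-(group, time point) highly-expressed-gene sets with Bernoulli rates.

    ``heg_sets`` maps ``(group, time)`` (0-based) to a frozenset of 0-based
    gene indices.  HEG sets of distinct groups must be disjoint at every
    time point.
    """

    n_groups: int
    n_timepoints: int
    heg_sets: Mapping
    p_high: float
    p_low: float
    cells_per_timepoint: tuple
    p_total: int

    def __post_init__(self):
        for t in range(self.n_timepoints):
            seen: set = set()
            for g in range(self.n_groups):
                s = self.heg_sets[(g, t)]
                if seen & s:
                    raise ValueError(
                        f"HEG sets of distinct groups overlap at time point {t + 1}")
                seen |= s
                if s and (min(s) < 0 or max(s) >= self.p_total):
                    raise ValueError("HEG index outside gene range")

    @property
    def all_hegs(self) -> frozenset:
        return frozenset().union(*self.heg_sets.values())

    @property
    def noise_genes(self) -> frozenset:
        """Genes never highly expressed in any group at any time point."""
        return frozenset(range(self.p_total)) - self.all_hegs

    def group_sizes(self, t: int) -> tuple:
        return _split_evenly(self.cells_per_timepoint[t], self.n_groups)

    def heg_ranges_1based(self):
        """Report HEG sets as sorted 1-based index lists."""
        return {(g + 1, t + 1): sorted(i + 1 for i in s)
                for (g, t), s in self.heg_sets.items()}


@dataclass
class TimeSeriesBundle:
    """Simulated matrices (one per time point) with group labels per cell."""

    matrices: list
    group_labels: list
    design: TimeSeriesDesign
    gene_ids: tuple = ()

    def __post_init__(self):
        if not self.gene_ids:
            self.gene_ids = tuple(f"gene_{j + 1}" for j in range(self.design.p_total))


def default_timeseries_design() -> TimeSeriesDesign:
    """Three cell groups over three time points, 80 genes.

    HEG index ranges (1-based, inclusive): group 1: 1-8, 6-13, 11-18;
    group 2: 21-28, 26-33, 31-38; group 3: 41-48, 46-53, 51-58.  Each
    group has 8 HEGs per time point, 3 of which remain highly expressed
    at the next time point; 54 genes are HEGs somewhere and the other 26
    are uninformative noise.  Cell counts per time point are 310, 298 and
    306, divided equally among the groups.
    """
    ranges = {
        (0, 0): (1, 8), (0, 1): (6, 13), (0, 2): (11, 18),
        (1, 0): (21, 28), (1, 1): (26, 33), (1, 2): (31, 38),
        (2, 0): (41, 48), (2, 1): (46, 53), (2, 2): (51, 58),
    }
    heg_sets = {key: frozenset(range(lo - 1, hi)) for key, (lo, hi) in ranges.items()}
    return TimeSeriesDesign(
        n_groups=3, n_timepoints=3, heg_sets=heg_sets,
        p_high=0.6, p_low=0.1, cells_per_timepoint=(310, 298, 306), p_total=80)


def stairlike_design(n_groups: int = 10, p_total: int = 50,
                     block_size: Optional[int] = None,
                     cells_per_group: int = 100,
                     p_high: float = 0.6, p_low: float = 0.1) -> TimeSeriesDesign:
    """Single-time-point design with one disjoint consecutive HEG block per group.

    With the defaults (10 groups, 50 genes) each group owns a block of 5
    consecutive genes, producing the stair-like block-diagonal pattern.
    ``block_size`` can be set below the equal partition to leave noise
    genes at the end of the index range.
    """
    if block_size is None:
        block_size = p_total // n_groups
    if block_size < 1 or n_groups * block_size > p_total:
        raise ValueError(
            f"{n_groups} blocks of {block_size} genes do not fit into {p_total} genes")
    heg_sets = {(g, 0): frozenset(range(g * block_size, (g + 1) * block_size))
                for g in range(n_groups)}
    return TimeSeriesDesign(
        n_groups=n_groups, n_timepoints=1, heg_sets=heg_sets,
        p_high=p_high, p_low=p_low,
        cells_per_timepoint=(cells_per_group * n_groups,), p_total=p_total)


def simulate_binary_groups(design: TimeSeriesDesign, seed: int) -> TimeSeriesBundle:
    """Draw the 0/1 matrices of a design: entry (i, j) ~ Bernoulli(p_high) if
    gene j is a HEG of cell i's group at that time point, else Bernoulli(p_low)."""
    rng = np.random.default_rng(seed)
    matrices, labels = [], []
    for t in range(design.n_timepoints):
        n_t = design.cells_per_timepoint[t]
        sizes = design.group_sizes(t)
        grp = np.repeat(np.arange(design.n_groups), sizes)
        P = np.full((n_t, design.p_total), design.p_low)
        for g in range(design.n_groups):
            cols = sorted(design.heg_sets[(g, t)])
            rows = np.flatnonzero(grp == g)
            P[np.ix_(rows, cols)] = design.p_high
        matrices.append((rng.random((n_t, design.p_total)) < P).astype(float))
        labels.append(grp)
    return TimeSeriesBundle(matrices, labels, design)


def standardize_and_rescale_noise(X: np.ndarray, noise_idx: Sequence[int],
                                  factor: float,
                                  column_ids=None) -> StandardizedMatrix:
    """Z-score all columns, then multiply the noise columns by ``factor``.

    Damping the noise columns after standardization brings their value
    range in line with the informative genes, whose binary draws are less
    balanced and therefore spread wider after z-scoring.
    """
    std = standardize_columns(X, column_ids)
    values = std.values.copy()
    noise_idx = list(noise_idx)
    values[:, noise_idx] *= factor
    rescaled = frozenset(std.column_ids[j] for j in noise_idx) if factor != 1.0 else frozenset()
    return StandardizedMatrix(values, std.column_ids, rescaled)


def standardized_bundle(bundle: TimeSeriesBundle, factor: float = NOISE_FACTOR_TIMESERIES):
    """Standardize each time point's matrix and rescale the design's noise genes."""
    noise = sorted(bundle.design.noise_genes)
    return [standardize_and_rescale_noise(X, noise, factor, bundle.gene_ids)
            for X in bundle.matrices]


def bernoulli_noise_pool(n_cells: int, n_columns: int, p: float = 0.1,
                         seed: int = 0) -> np.ndarray:
    """Freshly drawn Bernoulli noise columns, usable as a replacement pool."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_cells, n_columns)) < p).astype(float)


def replace_top_genes_with_noise(X: np.ndarray, selection_freq: Sequence[float],
                                 q: float, noise_pool: np.ndarray,
                                 seed: int = 0):
    """Replace the top q% most frequently selected genes with pool columns.

    The ceil(q/100 * p) genes with the highest selection frequency (ties
    broken toward the lower gene index) have their columns swapped for
    distinct columns drawn at random from ``noise_pool``.  Returns the new
    matrix and the mapping {gene index -> pool column index}.
    """
    X = np.asarray(X, dtype=float)
    freq = np.asarray(selection_freq, dtype=float)
    n, p = X.shape
    if freq.shape != (p,):
        raise ValueError("selection_freq length must equal the number of genes")
    if not 0 <= q <= 100:
        raise ValueError("q must be a percentage in [0, 100]")
    k = math.ceil(q / 100.0 * p)
    if k == 0:
        return X.copy(), {}
    if noise_pool.shape[0] != n:
        raise ValueError("noise_pool must have one row per cell")
    if noise_pool.shape[1] < k:
        raise ValueError(f"noise pool has {noise_pool.shape[1]} columns, need {k}")
    # stable sort on (-freq, index): highest frequency first, lower index wins ties
    order = np.lexsort((np.arange(p), -freq))
    targets = np.sort(order[:k])
    rng = np.random.default_rng(seed)
    drawn = rng.choice(noise_pool.shape[1], size=k, replace=False)
    Xnew = X.copy()
    Xnew[:, targets] = noise_pool[:, drawn]
    return Xnew, {int(t): int(c) for t, c in zip(targets, drawn)}
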