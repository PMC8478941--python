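"""Sorting observables: crosslinker density grids and Binder cumulants.

The spatial distribution of a crosslinker species at one time is
summarized as a 2D probability-density function: a histogram of the
locations of doubly bound crosslinkers on a fixed ``n_bins × n_bins``
grid over [−r_c, r_c]², each bin divided by its area and the total
count.  The Binder cumulant

    U₄ = 1 − ⟨s⁴⟩ / (3 ⟨s²⟩²)

of the per-bin PDF values ``s`` (spatial average over all bins, zeros
included) measures how concentrated the distribution is: a constant
positive grid gives exactly 2/3, and a grid with k equal nonzero bins of
N total gives 1 − N/(3k), decreasing as mass concentrates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import SystemState, Trajectory

__all__ = ["DensityGrid", "BinderSeries", "bound_crosslinker_pdf",
           "binder_cumulant", "binder_timeseries", "average_final_pdf",
           "central_mass"]


@dataclass
class DensityGrid:
    """A normalized 2D density grid for one species at one time.

    ``values[i, j]`` is the PDF (µm⁻²) in the bin with x-index i and
    y-index j; the domain is the square [−half_extent, half_extent]².
    ``n_samples`` is the number of crosslinkers that contributed; a grid
    with ``n_samples == 0`` is the explicit empty signal (all zeros, and
    not normalizable).
    """

    values: np.ndarray
    half_extent: float
    species: str
    time: float
    n_samples: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square 2D array")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_area(self) -> float:
        w = 2.0 * self.half_extent / self.n_bins
        return w * w

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    def integral(self) -> float:
        return float(self.values.sum() * self.bin_area)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.linspace(-self.half_extent, self.half_extent,
                            self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def to_table(self) -> np.ndarray:
        """Long-format (x_center, y_center, value) rows."""
        c = self.bin_centers
        xx, yy = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), self.values.ravel()])


def crosslinker_locations(frame: SystemState, species,
                          point: str = "midpoint") -> np.ndarray:
    """Cartesian locations of doubly bound crosslinkers of one species.

    ``point`` selects the representative point: the midpoint of the two
    heads (default) or the individual head positions.
    """
    sid = frame.species_index(species)
    both = (frame.bound[:, 0] == 1) & (frame.bound[:, 1] == 1)
    sel = both & (frame.species_id == sid)
    heads = frame.head_pos[sel]
    if point == "midpoint":
        return heads.mean(axis=1)
    if point == "heads":
        return heads.reshape(-1, 2)
    raise ValueError("point must be 'midpoint' or 'heads'")


def bound_crosslinker_pdf(frame: SystemState, species, n_bins: int = 20,
                          half_extent: float | None = None,
                          point: str = "midpoint") -> DensityGrid:
    """Histogram the doubly bound crosslinkers of a species into a PDF.

    Each bin value is the count divided by the bin area and the total
    number of contributing crosslinkers, so the grid integrates to one
    whenever at least one crosslinker contributed.  Bins are half-open
    with the right edge closed on the last bin; the domain is fixed to
    [−r_c, r_c]² by default so grids are comparable across frames.
    """
    if half_extent is None:
        half_extent = frame.confinement.r_c
    pts = crosslinker_locations(frame, species, point)
    name = frame.species[frame.species_index(species)].name
    edges = np.linspace(-half_extent, half_extent, n_bins + 1)
    if len(pts) == 0:
        return DensityGrid(np.zeros((n_bins, n_bins)), half_extent, name,
                           frame.time, 0)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
    bin_area = (2.0 * half_extent / n_bins) ** 2
    values = hist / (bin_area * len(pts))
    return DensityGrid(values, half_extent, name, frame.time, len(pts))


def binder_cumulant(grid) -> float:
    """U₄ = 1 − ⟨s⁴⟩/(3⟨s²⟩²) of the per-bin values, zeros included."""
    s = grid.values if isinstance(grid, DensityGrid) else np.asarray(grid, float)
    if not np.any(s != 0):
        raise ValueError("Binder cumulant is undefined for an all-zero grid")
    s2 = np.mean(s ** 2)
    s4 = np.mean(s ** 4)
    return float(1.0 - s4 / (3.0 * s2 * s2))


@dataclass
class BinderSeries:
    """Per-replicate Binder cumulant time series with replicate stats."""

    times: np.ndarray               # (T,)
    values: np.ndarray              # (R, T) per replicate
    species: str

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.times):
            raise ValueError("values must be (n_replicates, n_times)")

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.values.shape[0] < 2:
            return np.zeros(self.values.shape[1])
        return self.values.std(axis=0, ddof=1)


def binder_timeseries(trajs: list[Trajectory], species, n_bins: int = 20,
                      point: str = "midpoint") -> BinderSeries:
    """Binder cumulant per frame for each replicate, then mean ± SD.

    U₄ is measured for each simulation independently and averaged across
    replicates; all trajectories must share their frame times.  Frames
    with no doubly bound crosslinker yield NaN (undefined cumulant) and
    are excluded from the replicate mean by the caller if needed.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    times = trajs[0].times
    for t in trajs[1:]:
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise ValueError("trajectories do not share frame times")
    rows = []
    name = None
    for t in trajs:
        row = []
        for frame in t.frames:
            grid = bound_crosslinker_pdf(frame, species, n_bins, point=point)
            name = grid.species
            row.append(np.nan if grid.is_empty else binder_cumulant(grid))
        rows.append(row)
    return BinderSeries(times, np.array(rows), name)


def average_final_pdf(trajs: list[Trajectory], species, n_bins: int = 20,
                      point: str = "midpoint") -> DensityGrid:
    """Element-wise mean of the final-frame PDFs of several replicates."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    grids = [bound_crosslinker_pdf(t.final(), species, n_bins, point=point)
             for t in trajs]
    nonempty = [g for g in grids if not g.is_empty]
    if not nonempty:
        g0 = grids[0]
        return DensityGrid(np.zeros_like(g0.values), g0.half_extent,
                           g0.species, g0.time, 0)
    values = np.mean([g.values for g in nonempty], axis=0)
    g0 = nonempty[0]
    return DensityGrid(values, g0.half_extent, g0.species, g0.time,
                       sum(g.n_samples for g in nonempty))


def central_mass(grid: DensityGrid, half_width: int = 1) -> float:
    """Probability mass in the central ``(2·half_width)²`` bins."""
    n = grid.n_bins
    lo, hi = n // 2 - half_width, n // 2 + half_width
    return float(grid.values[lo:hi, lo:hi].sum() * grid.bin_area)
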