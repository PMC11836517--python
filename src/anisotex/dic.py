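"""Strain-field heterogeneity from digital image correlation (DIC).

Two quantities are extracted from a time series of full-field surface
strain maps recorded during a tensile test:

* a **dynamic Poisson's-ratio trace** nu(t), the frame-to-frame ratio of
  the transverse to the axial mean-strain increment, whose drop between
  the linear regime and failure signals air-filled or dilatant
  microstructure;
* a **Global Moran's I heterogeneity profile**: the spatial
  autocorrelation of the final pre-fracture strain field under a
  single-axis ("horizontal") neighbour kernel, evaluated at neighbour
  distances 1..d_max and summarized by the slope of a linear fit.  A
  steep (more negative) slope means strain decorrelates over a short
  distance, i.e. a spatially heterogeneous strain field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

DEFAULT_GRID_SPACING_UM = 37.0  # physical size of one DIC grid cell
DEFAULT_MAX_DISTANCE = 8


class TraceError(ValueError):
    """No valid frames available for a Poisson's-ratio trace."""


class DegenerateFieldError(ValueError):
    """Spatially constant field: Moran's I undefined (zero variance)."""


class WeightsError(ValueError):
    """Spatial weights sum to zero."""


@dataclass
class StrainFieldSeries:
    """Time-ordered axial and transverse strain grids from one tensile specimen.

    ``axial`` and ``transverse`` are float arrays of shape
    (n_frames, rows, cols).  ``axial_axis`` names the *grid* axis (0=rows,
    1=cols) that lies along the tensile (axial) direction.
    """

    axial: np.ndarray
    transverse: np.ndarray
    axial_axis: int = 0
    grid_spacing: float = DEFAULT_GRID_SPACING_UM
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axial = np.asarray(self.axial, dtype=float)
        self.transverse = np.asarray(self.transverse, dtype=float)
        if self.axial.shape != self.transverse.shape:
            raise ValueError("axial and transverse series must have identical shape")
        if self.axial.ndim != 3:
            raise ValueError("expected (n_frames, rows, cols) arrays")
        if self.axial_axis not in (0, 1):
            raise ValueError("axial_axis must be 0 (rows) or 1 (cols)")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.axial.shape[0]

    @property
    def transverse_axis(self) -> int:
        return 1 - self.axial_axis


@dataclass
class PoissonTrace:
    """Per-frame dynamic Poisson's ratio (positive magnitude) with validity mask."""

    nu: np.ndarray          # length n_frames-1, NaN where invalid
    valid: np.ndarray       # boolean mask, same length
    nu_linear: float        # first valid value
    nu_failure: float       # last valid value

    @property
    def decrease(self) -> float:
        return self.nu_linear - self.nu_failure


@dataclass
class MoranWeights:
    """Single-axis binary neighbour weights for Global Moran's I.

    Cells i and j are neighbours iff they share their coordinate on every
    grid axis except ``axis``, along which they are offset by 1..``max_offset``
    cells.  The equivalent dense kernel for ``max_offset=2`` is the 5x5
    matrix whose centre row reads 1 1 0 1 1 (all other entries zero).
    """

    axis: int = 1
    max_offset: int = 1

    def __post_init__(self) -> None:
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")
        if self.max_offset < 1:
            raise ValueError("max_offset must be >= 1")

    def kernel(self) -> np.ndarray:
        """Dense (2d+1)x(2d+1) kernel matrix; zero diagonal, symmetric."""
        d = self.max_offset
        k = np.zeros((2 * d + 1, 2 * d + 1), dtype=int)
        for off in range(1, d + 1):
            if self.axis == 1:
                k[d, d - off] = k[d, d + off] = 1
            else:
                k[d - off, d] = k[d + off, d] = 1
        return k


@dataclass
class MoranProfile:
    """Global Moran's I versus neighbour distance, with its linear-fit slope."""

    distances: np.ndarray
    I_values: np.ndarray
    fit_slope: float
    fit_intercept: float
    grid_spacing: float = DEFAULT_GRID_SPACING_UM

    # slope per physical length, for cross-study comparison
    @property
    def slope_per_um(self) -> float:
        return self.fit_slope / self.grid_spacing


def poisson_trace(
    series: StrainFieldSeries,
    min_axial_increment: float = 1e-5,
    median_window: int = 3,
) -> PoissonTrace:
    """Dynamic Poisson's ratio nu(t) from consecutive-frame mean-strain increments.

    nu(t) = |Delta mean transverse strain| / |Delta mean axial strain| over
    consecutive frames, reported as a positive magnitude so that 0.5 means
    volume-conserving deformation.  Frames whose axial increment is below
    ``min_axial_increment`` are marked invalid (scatter-outlier exclusion);
    the surviving trace is smoothed with a ``median_window``-frame median
    filter (set 1 to disable).  The first/last valid values define
    ``nu_linear``/``nu_failure``.
    """
    if series.n_frames < 2:
        raise TraceError("at least two frames are required")
    mean_ax = series.axial.mean(axis=(1, 2))
    mean_tr = series.transverse.mean(axis=(1, 2))
    d_ax = np.diff(mean_ax)
    d_tr = np.diff(mean_tr)
    valid = np.abs(d_ax) >= min_axial_increment
    if not valid.any():
        raise TraceError("no frame pair has a usable axial strain increment")
    nu = np.full(d_ax.shape, np.nan)
    nu[valid] = np.abs(d_tr[valid] / d_ax[valid])
    if median_window > 1 and valid.sum() >= 2:
        nu_valid = median_filter(nu[valid], size=median_window, mode="nearest")
        nu[valid] = nu_valid
    idx = np.flatnonzero(valid)
    return PoissonTrace(
        nu=nu,
        valid=valid,
        nu_linear=float(nu[idx[0]]),
        nu_failure=float(nu[idx[-1]]),
    )


def poisson_decrease(trace: PoissonTrace) -> float:
    """Drop of the Poisson's ratio from the linear regime to failure.

    First valid trace value minus last valid trace value; NaN entries are
    excluded.
    """
    finite = np.flatnonzero(trace.valid & np.isfinite(trace.nu))
    if len(finite) < 2:
        raise TraceError("need at least two valid frames for a decrease")
    return float(trace.nu[finite[0]] - trace.nu[finite[-1]])


def morans_I(field: np.ndarray, weights: MoranWeights) -> float:
    """Global Moran's I of a 2D field under a single-axis binary kernel.

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with the double sum over all cell pairs linked by the kernel.  Edge
    cells simply have fewer neighbours.  Implemented with shifted-array
    products; the literal double sum is kept as an independent test oracle.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be 2D")
    dev = field - field.mean()
    denom = float(np.sum(dev * dev))
    if denom == 0.0:
        raise DegenerateFieldError("constant field has undefined Moran's I")
    arr = dev if weights.axis == 1 else dev.T
    n_rows, n_cols = arr.shape
    num = 0.0
    W = 0
    for off in range(1, weights.max_offset + 1):
        if off >= n_cols:
            continue
        num += 2.0 * float(np.sum(arr[:, :-off] * arr[:, off:]))
        W += 2 * n_rows * (n_cols - off)
    if W == 0:
        raise WeightsError("weights matrix links no cell pairs on this grid")
    N = field.size
    return (N / W) * num / denom


def moran_profile(
    field: np.ndarray,
    axis: int = 1,
    d_max: int = DEFAULT_MAX_DISTANCE,
    kind: str = "cumulative",
    grid_spacing: float = DEFAULT_GRID_SPACING_UM,
) -> MoranProfile:
    """Moran's I at neighbour distances 1..d_max and the slope of its linear fit.

    ``kind='cumulative'`` (default) uses all offsets 1..d at distance d,
    matching the printed 5x5 kernel with centre row 1 1 0 1 1;
    ``kind='ring'`` uses only the exact offset d.  If the grid is narrower
    than ``2*d_max + 1`` along the adjacency axis, d_max is reduced with a
    warning.
    """
    field = np.asarray(field, dtype=float)
    length = field.shape[axis]
    if length < 2 * d_max + 1:
        reduced = max(1, (length - 1) // 2)
        warnings.warn(
            f"grid extent {length} < {2 * d_max + 1}; reducing d_max to {reduced}",
            stacklevel=2,
        )
        d_max = reduced
    distances = np.arange(1, d_max + 1)
    values = np.empty(d_max)
    for i, d in enumerate(distances):
        if kind == "cumulative":
            values[i] = morans_I(field, MoranWeights(axis=axis, max_offset=int(d)))
        elif kind == "ring":
            values[i] = _morans_I_ring(field, axis, int(d))
        else:
            raise ValueError(f"unknown kernel kind {kind!r}")
    slope, intercept = np.polyfit(distances, values, 1)
    return MoranProfile(
        distances=distances,
        I_values=values,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        grid_spacing=grid_spacing,
    )


def _morans_I_ring(field: np.ndarray, axis: int, d: int) -> float:
    """Moran's I with neighbours at exactly offset d (ring variant)."""
    field = np.asarray(field, dtype=float)
    dev = field - field.mean()
    denom = float(np.sum(dev * dev))
    if denom == 0.0:
        raise DegenerateFieldError("constant field has undefined Moran's I")
    arr = dev if axis == 1 else dev.T
    n_rows, n_cols = arr.shape
    if d >= n_cols:
        raise WeightsError("offset exceeds grid extent")
    num = 2.0 * float(np.sum(arr[:, :-d] * arr[:, d:]))
    W = 2 * n_rows * (n_cols - d)
    return (field.size / W) * num / denom
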