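"""2D micrograph morphometry: contrast, thresholding, shape and orientation.

Pipeline for stained confocal sections of a protein matrix: the protein
phase is bright, non-protein domains (mostly air) are dark.  Steps:

1. auto-contrast (percentile-clipped linear rescale);
2. minimum thresholding of the 256-bin histogram (smooth until exactly
   two maxima remain; threshold at the valley between them);
3. shape extraction of dark domains larger than 40 um (maximum caliper),
   with Feret diameter, minimum-caliper width, roundness and the shape
   anisotropy index Feret/width via rotating calipers on each component's
   convex hull of pixel corners;
4. structure-tensor dominant direction and coherency
   C = (l1 - l2)/(l1 + l2) in [0, 1], where 1 means one dominant texture
   direction and 0 none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from anisotex._geometry import (
    convex_hull_points,
    max_caliper,
    min_caliper,
    pixel_corner_points,
)

DEFAULT_MIN_FERET_UM = 40.0
DEFAULT_CLIP_FRACTION = 0.0035  # fraction of pixels saturated at each tail


class ThresholdError(ValueError):
    """Histogram could not be reduced to two modes."""


class UndefinedOrientationError(ValueError):
    """Zero-gradient image has no orientation."""


@dataclass
class Micrograph:
    """Single-channel micrograph with physical pixel size (um)."""

    intensities: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("expected a 2D image")
        if min(self.intensities.shape) < 64:
            raise ValueError("image must be at least 64x64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class Shape2D:
    """Caliper-based descriptors of one dark domain (physical units)."""

    area: float          # um^2
    feret: float         # um, maximum caliper
    width: float         # um, minimum caliper
    roundness: float     # 4*area / (pi * feret^2), in (0, 1]
    shape_aix: float     # feret / width, >= 1
    centroid: tuple[float, float]  # (row, col) in um
    touches_border: bool = False


@dataclass
class OrientationResult:
    """Image-level texture orientation from the aggregated structure tensor."""

    dominant_direction: float  # degrees in [0, 180), from the column axis
    coherency: float           # (l1 - l2)/(l1 + l2) in [0, 1]
    energy: float              # l1 + l2, total gradient energy


def auto_contrast(
    image: Micrograph, clip_fraction: float = DEFAULT_CLIP_FRACTION
) -> Micrograph:
    """Percentile-clipped linear rescale to the full output range.

    ``clip_fraction`` of pixels saturate at each tail (0.35% by default).
    Integer images rescale to the full dtype range; float images to
    [0, 1].  A constant image is returned unchanged with a warning.
    """
    data = image.intensities
    lo, hi = np.percentile(data, [100.0 * clip_fraction, 100.0 * (1.0 - clip_fraction)])
    if hi <= lo:
        warnings.warn("constant image: contrast left unchanged", stacklevel=2)
        return image
    scaled = np.clip((data.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = (scaled * (info.max - info.min) + info.min).astype(data.dtype)
    else:
        out = scaled
    return Micrograph(intensities=out, pixel_size=image.pixel_size)


def minimum_threshold(
    image: Micrograph, nbins: int = 256, max_smoothings: int = 10000
) -> float:
    """Minimum-method threshold: smooth the histogram with a 3-bin moving
    mean until exactly two local maxima remain, then take the minimum
    between them.

    Edge bins count as maxima candidates, so fully saturated bimodal
    images (all mass in the extreme bins) still threshold.  Raises
    :class:`ThresholdError` if the histogram never becomes bimodal.
    """
    data = np.asarray(image.intensities, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise ThresholdError("constant image has no threshold")
    hist, edges = np.histogram(data.ravel(), bins=nbins, range=(lo, hi))
    smoothed = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for _ in range(max_smoothings):
        padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
        maxima = np.flatnonzero(
            (smoothed > padded[:-2]) & (smoothed >= padded[2:])
        )
        if len(maxima) == 2:
            a, b = maxima
            valley = a + int(np.argmin(smoothed[a : b + 1]))
            return float(centers[valley])
        # 3-bin moving mean with reflected edges
        padded = np.concatenate([smoothed[:1], smoothed, smoothed[-1:]])
        smoothed = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    raise ThresholdError("histogram never became bimodal")


def _region_shape(coords: np.ndarray, pixel_size: float, img_shape: tuple[int, int]) -> Shape2D:
    corners = pixel_corner_points(coords)
    hull = convex_hull_points(corners)
    feret_px = max_caliper(hull)
    width_px = min_caliper(hull)
    area = len(coords) * pixel_size**2
    feret = feret_px * pixel_size
    width = width_px * pixel_size
    centroid = coords.mean(axis=0) * pixel_size
    touches = bool(
        (coords[:, 0].min() == 0)
        or (coords[:, 1].min() == 0)
        or (coords[:, 0].max() == img_shape[0] - 1)
        or (coords[:, 1].max() == img_shape[1] - 1)
    )
    return Shape2D(
        area=area,
        feret=feret,
        width=width,
        roundness=4.0 * area / (np.pi * feret**2) if feret > 0 else 1.0,
        shape_aix=feret / width if width > 0 else float("inf"),
        centroid=(float(centroid[0]), float(centroid[1])),
        touches_border=touches,
    )


def extract_shapes(
    image: Micrograph,
    threshold: float,
    min_feret: float = DEFAULT_MIN_FERET_UM,
    polarity: str = "dark",
    keep_border: bool = True,
    size_metric: str = "feret",
) -> list[Shape2D]:
    """Measure 8-connected domains on one side of the threshold.

    ``polarity='dark'`` selects below-threshold pixels (non-protein
    domains under protein staining); ``'bright'`` inverts.  Domains whose
    size — maximum caliper by default, or area-equivalent diameter with
    ``size_metric='equivalent_diameter'`` — is not larger than
    ``min_feret`` (um) are discarded.  Returns an empty list with a
    warning when nothing survives.
    """
    data = image.intensities
    mask = data < threshold if polarity == "dark" else data > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    shapes = []
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        coords = np.argwhere(labels[sl] == sl_idx) + np.array([s.start for s in sl])
        shape = _region_shape(coords, image.pixel_size, data.shape)
        if not keep_border and shape.touches_border:
            continue
        if size_metric == "feret":
            size = shape.feret
        elif size_metric == "equivalent_diameter":
            size = 2.0 * np.sqrt(shape.area / np.pi)
        else:
            raise ValueError(f"unknown size_metric {size_metric!r}")
        if size > min_feret:
            shapes.append(shape)
    if not shapes:
        warnings.warn("no shapes survive the size filter", stacklevel=2)
    return shapes


def shape_summary(shapes: list[Shape2D]) -> dict[str, float]:
    """Image-level means of the shape descriptors (NaN when no shapes)."""
    if not shapes:
        return {k: float("nan") for k in ("ShapeArea", "Feret", "Width", "Roundness", "ShapeAIx")}
    return {
        "ShapeArea": float(np.mean([s.area for s in shapes])),
        "Feret": float(np.mean([s.feret for s in shapes])),
        "Width": float(np.mean([s.width for s in shapes])),
        "Roundness": float(np.mean([s.roundness for s in shapes])),
        "ShapeAIx": float(np.mean([s.shape_aix for s in shapes])),
    }


def orientation_coherency(
    image: Micrograph,
    gradient_sigma: float = 1.0,
    mode: str = "summed",
) -> OrientationResult:
    """Dominant texture direction and coherency from the structure tensor.

    Gaussian-derivative gradients (SD ``gradient_sigma`` px) feed the
    2x2 structure tensor J = sum [gx^2, gx gy; gx gy, gy^2] over the whole
    image (``mode='summed'``, energy-weighted).  The dominant direction is
    the texture orientation — perpendicular to the principal gradient
    eigenvector — in degrees from the column axis, mod 180.
    ``mode='mean_pixel'`` instead averages per-pixel coherencies computed
    from a locally smoothed tensor.
    """
    data = image.intensities.astype(float)
    gx = ndimage.gaussian_filter(data, gradient_sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(data, gradient_sigma, order=(1, 0), mode="reflect")
    jxx, jxy, jyy = gx * gx, gx * gy, gy * gy
    if mode == "summed":
        Jxx, Jxy, Jyy = float(jxx.sum()), float(jxy.sum()), float(jyy.sum())
        return _tensor_orientation(Jxx, Jxy, Jyy)
    if mode == "mean_pixel":
        smooth = lambda a: ndimage.gaussian_filter(a, 4.0 * gradient_sigma, mode="reflect")
        sxx, sxy, syy = smooth(jxx), smooth(jxy), smooth(jyy)
        trace = sxx + syy
        disc = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.where(trace > 0, disc / trace, 0.0)
        global_result = _tensor_orientation(float(sxx.sum()), float(sxy.sum()), float(syy.sum()))
        return OrientationResult(
            dominant_direction=global_result.dominant_direction,
            coherency=float(coh.mean()),
            energy=float(trace.sum()),
        )
    raise ValueError(f"unknown mode {mode!r}")


def _tensor_orientation(Jxx: float, Jxy: float, Jyy: float) -> OrientationResult:
    trace = Jxx + Jyy
    if trace <= 0:
        raise UndefinedOrientationError("zero-gradient image")
    disc = np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy**2)
    l1 = 0.5 * (trace + disc)
    l2 = 0.5 * (trace - disc)
    # principal gradient eigenvector (ex, ey); texture runs perpendicular to it
    if disc == 0:
        # perfectly isotropic tensor: no dominant direction, coherency 0
        return OrientationResult(dominant_direction=0.0, coherency=0.0, energy=trace)
    if Jxy != 0.0:
        ex, ey = l1 - Jyy, Jxy
    elif Jxx >= Jyy:
        ex, ey = 1.0, 0.0
    else:
        ex, ey = 0.0, 1.0
    direction = float(np.degrees(np.arctan2(-ex, ey)) % 180.0)
    coherency = float((l1 - l2) / (l1 + l2))
    return OrientationResult(dominant_direction=direction, coherency=coherency, energy=trace)
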