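"""3D air-bubble morphometry from phase-segmented tomography volumes.

Air bubbles (voids) in a 3-phase segmented volume — solid protein
matrix, air, and a "rest" phase that is neither — are labelled as
26-connected components and measured per bubble: volume, isosurface
area, principal-axis extents (length >= breadth >= width), minimum
caliper thickness, orientation of the long axis, and the air anisotropy
length/width.  Per-specimen summaries are unweighted means over bubbles
plus the air and rest volume percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from anisotex._geometry import fibonacci_directions

DEFAULT_VOXEL_SIZE_UM = 6.0
PHASE_BACKGROUND, PHASE_SOLID, PHASE_AIR, PHASE_REST = 0, 1, 2, 3


class SampleMaskError(ValueError):
    """No sample voxels present."""


@dataclass
class LabeledVoidVolume:
    """Phase volume plus per-bubble integer component labels."""

    phases: np.ndarray          # uint8, labels 0..3
    labels: np.ndarray          # int, 0 = not air, 1..n per bubble
    n_components: int
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    boundary_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.phases.shape != self.labels.shape:
            raise ValueError("phases and labels must share a shape")


@dataclass
class BubbleFeatures:
    """Shape descriptors of one air bubble (physical units)."""

    volume3d: float            # um^3
    area3d: float              # um^2 (isosurface mesh area)
    length3d: float            # um, largest principal-axis extent
    breadth3d: float           # um, middle extent
    width3d: float             # um, smallest principal-axis extent
    thickness3d: float         # um, minimum caliper extent over probe directions
    length_orient_theta: float  # deg from the volume z-axis (axis 0), in [0, 90]
    breadth_orient_theta: float
    width_orient_theta: float
    length_orient_phi: float    # deg azimuth in [0, 180)
    anisotropy: float           # length3d / width3d
    touches_boundary: bool = False


@dataclass
class SpecimenMicroSummary:
    """Bubble-feature means plus phase volume percentages for one specimen."""

    means: dict[str, float]
    n_bubbles: int
    pct_air_volume: float
    pct_rest_volume: float


def classify_phases(intensity: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Two-threshold intensity classifier for raw reconstructions.

    air < t1 <= rest < t2 <= solid; thresholds are user-supplied.
    """
    if not t1 < t2:
        raise ValueError("require t1 < t2")
    phases = np.full(intensity.shape, PHASE_SOLID, dtype=np.uint8)
    phases[intensity < t2] = PHASE_REST
    phases[intensity < t1] = PHASE_AIR
    return phases


def label_voids(
    phases: np.ndarray,
    connectivity: int = 26,
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM,
    air_label: int = PHASE_AIR,
) -> LabeledVoidVolume:
    """Label each maximal connected air component (26-connectivity default).

    Components touching the volume boundary are kept and flagged in
    ``boundary_labels`` for optional exclusion downstream.
    """
    phases = np.asarray(phases)
    structure = {26: np.ones((3, 3, 3)), 6: None}.get(connectivity, "bad")
    if isinstance(structure, str):
        raise ValueError("connectivity must be 6 or 26")
    air = phases == air_label
    if not air.any():
        warnings.warn("no air voxels present", stacklevel=2)
        return LabeledVoidVolume(
            phases=phases,
            labels=np.zeros(phases.shape, dtype=np.int32),
            n_components=0,
            voxel_size=voxel_size,
        )
    labels, n = ndimage.label(air, structure=structure)
    boundary = set()
    for ax in range(3):
        for face in (0, -1):
            boundary |= set(np.unique(np.take(labels, face, axis=ax)))
    boundary.discard(0)
    return LabeledVoidVolume(
        phases=phases,
        labels=labels,
        n_components=int(n),
        voxel_size=voxel_size,
        boundary_labels=frozenset(int(b) for b in boundary),
    )


def _angles_from_vector(v: np.ndarray) -> tuple[float, float]:
    """(theta, phi): degrees from the z-axis (axis 0) folded to [0,90] and
    azimuth from the x-axis (axis 2) toward the y-axis (axis 1) in [0,180)."""
    v = v / np.linalg.norm(v)
    theta = float(np.degrees(np.arccos(np.clip(abs(v[0]), 0.0, 1.0))))
    theta = min(theta, 90.0)  # principal axes are unsigned
    phi = float(np.degrees(np.arctan2(v[1], v[2])) % 180.0)
    return theta, phi


def bubble_features(
    mask: np.ndarray,
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM,
    n_probe_directions: int = 162,
    touches_boundary: bool = False,
) -> BubbleFeatures:
    """Shape features of a single bubble given its boolean voxel mask.

    Extents are peak-to-peak projections of voxel centers onto the
    covariance eigenvectors plus one voxel, sorted descending; thickness
    is the minimum projection extent over ``n_probe_directions``
    quasi-uniform directions; orientation angles come from the
    eigenvectors.  A single-voxel component degenerates to all extents
    equal to one voxel with a warning.
    """
    coords = np.argwhere(mask).astype(float)
    n = len(coords)
    if n == 0:
        raise ValueError("empty component")
    volume = n * voxel_size**3
    area = _mesh_area(mask, voxel_size)
    if n == 1:
        warnings.warn("single-voxel component: degenerate extents", stacklevel=2)
        e = voxel_size
        return BubbleFeatures(
            volume3d=volume, area3d=area,
            length3d=e, breadth3d=e, width3d=e, thickness3d=e,
            length_orient_theta=0.0, breadth_orient_theta=90.0,
            width_orient_theta=90.0, length_orient_phi=0.0,
            anisotropy=1.0, touches_boundary=touches_boundary,
        )
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    extents = []
    thetas = []
    phis = []
    for k in range(3):
        v = eigvecs[:, k]
        proj = centered @ v
        extents.append((proj.max() - proj.min() + 1.0) * voxel_size)
        th, ph = _angles_from_vector(v)
        thetas.append(th)
        phis.append(ph)
    sort = np.argsort(extents)[::-1]
    extents_sorted = [extents[i] for i in sort]
    dirs = fibonacci_directions(n_probe_directions)
    projections = centered @ dirs.T
    thickness = float(
        (projections.max(axis=0) - projections.min(axis=0) + 1.0).min() * voxel_size
    )
    return BubbleFeatures(
        volume3d=volume,
        area3d=area,
        length3d=extents_sorted[0],
        breadth3d=extents_sorted[1],
        width3d=extents_sorted[2],
        thickness3d=thickness,
        length_orient_theta=thetas[sort[0]],
        breadth_orient_theta=thetas[sort[1]],
        width_orient_theta=thetas[sort[2]],
        length_orient_phi=phis[sort[0]],
        anisotropy=extents_sorted[0] / extents_sorted[2],
        touches_boundary=touches_boundary,
    )


def _mesh_area(mask: np.ndarray, voxel_size: float) -> float:
    """Isosurface area of a voxel mask in um^2 (marching cubes on a padded mask)."""
    padded = np.pad(mask.astype(np.float32), 1)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5)
    except (ValueError, RuntimeError):
        # degenerate mask (e.g. single voxel thin in one axis at low levels)
        return 6.0 * mask.sum() * voxel_size**2
    return float(mesh_surface_area(verts, faces)) * voxel_size**2


def all_bubble_features(
    volume: LabeledVoidVolume, exclude_boundary: bool = False
) -> list[BubbleFeatures]:
    """Features of every labelled bubble, in label order."""
    out = []
    objects = ndimage.find_objects(volume.labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        touches = lab in volume.boundary_labels
        if exclude_boundary and touches:
            continue
        mask = volume.labels[sl] == lab
        out.append(
            bubble_features(mask, voxel_size=volume.voxel_size, touches_boundary=touches)
        )
    return out


FEATURE_COLUMNS = {
    "Volume3d": "volume3d",
    "Area3d": "area3d",
    "Length3d": "length3d",
    "Breadth3d": "breadth3d",
    "Width3d": "width3d",
    "Thickness3d": "thickness3d",
    "LengthOrientTheta": "length_orient_theta",
    "BreadthOrientTheta": "breadth_orient_theta",
    "WidthOrientTheta": "width_orient_theta",
    "LengthOrientPhi": "length_orient_phi",
    "AirAnisotropy": "anisotropy",
}


def features_table(features: list[BubbleFeatures]) -> pd.DataFrame:
    """Per-bubble feature table using the field vocabulary of the output CSVs."""
    return pd.DataFrame(
        {col: [getattr(f, attr) for f in features] for col, attr in FEATURE_COLUMNS.items()}
    )


def specimen_summary(
    volume: LabeledVoidVolume, features: list[BubbleFeatures]
) -> SpecimenMicroSummary:
    """Unweighted bubble-feature means and air/rest percentages of the sample.

    The sample is the union of solid, air and rest voxels (background
    excluded).
    """
    phases = volume.phases
    sample = np.isin(phases, (PHASE_SOLID, PHASE_AIR, PHASE_REST))
    n_sample = int(sample.sum())
    if n_sample == 0:
        raise SampleMaskError("no sample voxels (solid/air/rest) present")
    pct_air = 100.0 * float((phases == PHASE_AIR).sum()) / n_sample
    pct_rest = 100.0 * float((phases == PHASE_REST).sum()) / n_sample
    means = {}
    if features:
        tbl = features_table(features)
        means = {col: float(tbl[col].mean()) for col in tbl.columns}
    return SpecimenMicroSummary(
        means=means,
        n_bubbles=len(features),
        pct_air_volume=pct_air,
        pct_rest_volume=pct_rest,
    )
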