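"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates one instrument's already-reduced output —
tensile force-displacement records, DIC strain-field series, 3-phase
segmented tomography volumes, stained micrographs, and a multi-product
feature table with a planted latent anisotropy factor — and emits the
exact ground truth beside the raw data, so every downstream recovery
test compares against construction-time truth, never against re-derived
values.  All randomness is seeded; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from anisotex import _geometry
from anisotex.dic import StrainFieldSeries
from anisotex.tensile import (
    DEFAULT_GAUGE_LENGTH_M,
    ForceDisplacementRecord,
    TensileSpecimen,
    TensileSummary,
)

DEFAULT_DEFORMATION_RATE_M_S = 11.4e-3 / 60.0  # constant crosshead speed
DEFAULT_SPECIMEN_WIDTH_M = 20e-3
DEFAULT_SPECIMEN_THICKNESS_M = 3e-3


class PlacementError(RuntimeError):
    """Could not place all requested bubbles without overlap."""


# ---------------------------------------------------------------------------
# tensile curves
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTensileSpec:
    """Ground-truth parameters of an elastic-softening true stress-strain curve.

    The noiseless curve rises bilinearly — exactly linear with slope
    ``youngs_modulus_true`` up to ``linear_fraction`` of the peak stress,
    then linearly at a reduced slope to the peak at
    (``fracture_strain_true``, ``fracture_stress_true``) — and decays
    linearly to zero stress over ``softening_span``.  The exact linear
    segment and the sharp peak make every ground-truth parameter
    recoverable to machine precision from the noiseless record.
    """

    youngs_modulus_true: float = 2e6        # Pa
    fracture_stress_true: float = 2e5       # Pa
    fracture_strain_true: float = 0.5       # true strain at the peak
    softening_span: float = 0.3             # strain from peak to zero stress
    linear_fraction: float = 0.6            # stress fraction where the linear segment ends
    noise_sd: float = 0.0                   # relative force noise
    n_points: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.youngs_modulus_true, self.fracture_stress_true) <= 0:
            raise ValueError("modulus and fracture stress must be positive")
        if not 0 < self.fracture_strain_true:
            raise ValueError("fracture strain must be positive")
        if self.softening_span <= 0:
            raise ValueError("softening span must be positive")
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.youngs_modulus_true * self.fracture_strain_true < self.fracture_stress_true:
            raise ValueError(
                "secant modulus exceeds initial modulus: require E * eps_f >= sigma_f"
            )
        if not 0.0 < self.linear_fraction <= 1.0:
            raise ValueError("linear_fraction must lie in (0, 1]")

    @property
    def failure_strain_true(self) -> float:
        return self.fracture_strain_true + self.softening_span


def _segment_points(spec: SyntheticTensileSpec) -> tuple[float, float]:
    """(eps1, sigma1): end of the exactly linear segment."""
    sigma1 = spec.linear_fraction * spec.fracture_stress_true
    eps1 = min(sigma1 / spec.youngs_modulus_true, spec.fracture_strain_true)
    return eps1, sigma1


def _true_stress_of_strain(spec: SyntheticTensileSpec, eps: np.ndarray) -> np.ndarray:
    """Noiseless sigma(eps): bilinear rise to the peak, then linear decay."""
    E = spec.youngs_modulus_true
    sf = spec.fracture_stress_true
    ef = spec.fracture_strain_true
    eps1, sigma1 = _segment_points(spec)
    sigma = np.zeros_like(eps)
    lin = eps <= eps1
    sigma[lin] = E * eps[lin]
    if ef > eps1:
        s2 = (sf - sigma1) / (ef - eps1)  # <= E by the secant-modulus invariant
        blend = (eps > eps1) & (eps <= ef)
        sigma[blend] = sigma1 + s2 * (eps[blend] - eps1)
    soft = (eps > ef) & (eps <= spec.failure_strain_true)
    sigma[soft] = sf * (1.0 - (eps[soft] - ef) / spec.softening_span)
    sigma[eps > spec.failure_strain_true] = 0.0
    return sigma


def _analytic_toughness(spec: SyntheticTensileSpec) -> float:
    """Closed-form area under the noiseless true stress-strain curve."""
    sf = spec.fracture_stress_true
    ef = spec.fracture_strain_true
    eps1, sigma1 = _segment_points(spec)
    area = 0.5 * sigma1 * eps1
    area += 0.5 * (sigma1 + sf) * (ef - eps1)
    area += 0.5 * sf * spec.softening_span
    return area


def gen_tensile_curve(
    spec: SyntheticTensileSpec,
    direction: str = "parallel",
    width0: float = DEFAULT_SPECIMEN_WIDTH_M,
    thickness0: float = DEFAULT_SPECIMEN_THICKNESS_M,
    gauge_length: float = DEFAULT_GAUGE_LENGTH_M,
    deformation_rate: float = DEFAULT_DEFORMATION_RATE_M_S,
) -> tuple[ForceDisplacementRecord, TensileSpecimen, TensileSummary]:
    """Synthesize a force-displacement record with its exact ground truth.

    The curve is constructed in true stress-strain space, then inverted to
    force and displacement through the incompressible-area relations, so
    the returned :class:`TensileSummary` is exact by construction.
    Multiplicative Gaussian noise of relative SD ``noise_sd`` is applied to
    the force channel only.
    """
    rng = np.random.default_rng(spec.seed)
    specimen = TensileSpecimen(
        width0=width0,
        thickness0=thickness0,
        gauge_length=gauge_length,
        direction=direction,
    )
    ef, efail = spec.fracture_strain_true, spec.failure_strain_true
    eps1, _ = _segment_points(spec)
    n_pre = max(2, int(round(spec.n_points * ef / efail)))
    n_post = max(2, spec.n_points - n_pre)
    n_lin = max(2, int(round(n_pre * eps1 / ef)))
    eps = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, eps1, n_lin),
                np.linspace(eps1, ef, max(2, n_pre - n_lin + 1)),
                np.linspace(ef, efail, n_post + 1),
            ]
        )
    )
    sigma = _true_stress_of_strain(spec, eps)
    h0 = specimen.gauge_length
    h = h0 * np.exp(eps)
    area = (h0 / h) * specimen.area0
    force = sigma * area
    if spec.noise_sd > 0:
        force = force * (1.0 + spec.noise_sd * rng.standard_normal(force.shape))
    displacement = h - h0
    time = displacement / deformation_rate
    record = ForceDisplacementRecord(time=time, force=force, displacement=displacement)
    truth = TensileSummary(
        youngs_modulus=spec.youngs_modulus_true,
        fracture_stress=spec.fracture_stress_true,
        fracture_strain=ef,
        failure_strain=efail,
        fracture_length=spec.softening_span,
        toughness=_analytic_toughness(spec),
    )
    return record, specimen, truth


# ---------------------------------------------------------------------------
# DIC strain-field series
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFieldSpec:
    """Uniaxial-extension strain-field series with controllable heterogeneity.

    The mean axial strain ramps linearly over frames to ``max_axial_strain``;
    the transverse field is exactly ``-nu_true`` times the axial field, so
    ``nu_true = 0.5`` reproduces volume-conserving deformation exactly.
    Setting ``nu_final`` ramps the per-frame Poisson's ratio linearly from
    ``nu_true`` to ``nu_final``, emulating the drop toward failure seen in
    porous specimens.
    Spatial heterogeneity is a smooth zero-mean profile along the axial
    axis (SD ``axial_gradient_sd`` in the final frame) plus, optionally,
    one along the transverse axis.
    """

    nu_true: float = 0.5
    n_frames: int = 20
    grid_shape: tuple[int, int] = (64, 48)  # (rows, cols); rows = axial axis
    axial_gradient_sd: float = 0.0
    grid_spacing: float = 37.0              # um per cell
    seed: int = 0
    max_axial_strain: float = 0.2
    transverse_gradient_sd: float = 0.0
    nu_final: float | None = None           # Poisson's ratio at the last frame

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu_true <= 0.5:
            raise ValueError("nu_true must lie in [0, 0.5]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if min(self.grid_shape) < 2:
            raise ValueError("grid must be at least 2x2")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.axial_gradient_sd < 0 or self.transverse_gradient_sd < 0:
            raise ValueError("heterogeneity SDs must be non-negative")
        if self.max_axial_strain <= 0:
            raise ValueError("max_axial_strain must be positive")
        if self.nu_final is not None and not 0.0 <= self.nu_final <= 0.5:
            raise ValueError("nu_final must lie in [0, 0.5]")


def _smooth_profile(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Smooth zero-mean profile of length n with exact (population) SD sd."""
    from scipy.ndimage import gaussian_filter1d

    if sd == 0.0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=max(2.0, n / 8.0), mode="wrap")
    raw -= raw.mean()
    s = raw.std()
    if s == 0.0:  # pathological draw; fall back to a cosine profile
        raw = np.cos(2.0 * np.pi * np.arange(n) / n)
        raw -= raw.mean()
        s = raw.std()
    return raw * (sd / s)


def gen_strain_field_series(spec: SyntheticFieldSpec) -> StrainFieldSeries:
    """Generate an axial + transverse strain-field series per the spec.

    Frame t (1-based) has mean axial strain t/n_frames * max_axial_strain
    exactly; heterogeneity scales with the same ramp so the final frame's
    spatial SD equals the requested values exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    prof_ax = _smooth_profile(rng, rows, spec.axial_gradient_sd)
    prof_tr = _smooth_profile(rng, cols, spec.transverse_gradient_sd)
    hetero = prof_ax[:, None] + prof_tr[None, :]
    ramp = np.arange(1, spec.n_frames + 1) / spec.n_frames
    axial = ramp[:, None, None] * (spec.max_axial_strain + hetero)[None, :, :]
    nu_end = spec.nu_true if spec.nu_final is None else spec.nu_final
    nu_t = np.linspace(spec.nu_true, nu_end, spec.n_frames)
    # apply nu incrementally so the frame-to-frame strain-increment ratio
    # (what the dynamic estimator measures) equals nu_t exactly; for a
    # constant nu this reduces to transverse = -nu * axial
    d_axial = np.diff(axial, axis=0, prepend=0.0)
    transverse = -np.cumsum(nu_t[:, None, None] * d_axial, axis=0)
    times = np.arange(1, spec.n_frames + 1, dtype=float)
    return StrainFieldSeries(
        axial=axial,
        transverse=transverse,
        axial_axis=0,
        grid_spacing=spec.grid_spacing,
        frame_times=times,
    )


# ---------------------------------------------------------------------------
# tomography volumes
# ---------------------------------------------------------------------------

PHASE_BACKGROUND, PHASE_SOLID, PHASE_AIR, PHASE_REST = 0, 1, 2, 3


@dataclass
class SyntheticVolumeSpec:
    """Ellipsoidal-void phantom for 3D morphometry.

    Non-overlapping ellipsoids (long semi-axis ``aspect_ratio * mean_radius``,
    minor semi-axes ``mean_radius``) are placed in a solid matrix with long
    axes along ``axis_direction`` perturbed by Gaussian angular jitter.
    ``n_bubbles=None`` derives the count from ``target_air_fraction``.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    n_bubbles: int | None = None
    aspect_ratio: float = 3.0
    mean_radius: float = 4.0                 # voxels, minor semi-axis
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    placement_jitter: float = 5.0            # degrees
    target_air_fraction: float = 0.008
    rest_fraction: float = 0.004
    voxel_size: float = 6.0                  # um
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError("volume too small")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.target_air_fraction + self.rest_fraction >= 1:
            raise ValueError("air + rest fractions must be < 1")
        if self.target_air_fraction < 0 or self.rest_fraction < 0:
            raise ValueError("fractions must be non-negative")
        if self.placement_jitter < 0:
            raise ValueError("placement_jitter must be non-negative")
        if np.linalg.norm(self.axis_direction) == 0:
            raise ValueError("axis_direction must be nonzero")

    def bubble_count(self) -> int:
        if self.n_bubbles is not None:
            return self.n_bubbles
        vol_one = 4.0 / 3.0 * np.pi * self.aspect_ratio * self.mean_radius**3
        total = float(np.prod(self.shape))
        return max(0, int(round(self.target_air_fraction * total / vol_one)))


def _rasterize_ellipsoid(
    volume: np.ndarray,
    center: np.ndarray,
    semi_axes: tuple[float, float, float],
    frame: tuple[np.ndarray, np.ndarray, np.ndarray],
    label: int,
) -> int:
    """Fill voxels inside the ellipsoid with ``label``; return the voxel count."""
    a = max(semi_axes)
    lo = np.maximum(np.floor(center - a - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + a + 2).astype(int), volume.shape)
    grids = np.meshgrid(
        *[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij"
    )
    rel = np.stack([g - center[k] for k, g in enumerate(grids)], axis=-1)
    q = np.zeros(rel.shape[:-1])
    for ax, vec in zip(semi_axes, frame):
        q += (rel @ vec) ** 2 / ax**2
    mask = q <= 1.0
    sub = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[mask] = label
    return int(mask.sum())


def gen_void_volume(spec: SyntheticVolumeSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a 3-phase labelled volume and its ground-truth bubble table.

    Returns (phases, truth): ``phases`` is a uint8 volume with labels
    1=solid, 2=air, 3=rest; ``truth`` has one row per bubble with center,
    semi-axes, long-axis direction, analytic volume 4/3*pi*a*b*c (voxel
    units), anisotropy (= aspect ratio by construction) and the realized
    voxel count.  Placement uses rejection sampling with an ellipsoidal
    exclusion region: two identical parallel ellipsoids overlap exactly
    when their center difference lies inside the Minkowski-doubled
    ellipsoid, so for aligned long axes the check is exact; angular
    jitter is absorbed by padding the transverse exclusion semi-axis by
    a * sin(2 * jitter), keeping each bubble one connected component.
    """
    rng = np.random.default_rng(spec.seed)
    phases = np.full(spec.shape, PHASE_SOLID, dtype=np.uint8)
    n = spec.bubble_count()
    a_long = spec.aspect_ratio * spec.mean_radius
    margin = a_long + 1.0
    shape = np.asarray(spec.shape, dtype=float)
    if n > 0 and np.any(shape - 2 * margin <= 0):
        raise PlacementError("bubbles do not fit inside the volume")
    base_dir = np.asarray(spec.axis_direction, dtype=float)
    base_dir = base_dir / np.linalg.norm(base_dir)
    # exclusion semi-axes: Minkowski sum of two ellipsoids + digitization pad
    excl_long = 2.0 * a_long + 2.0
    jitter_pad = a_long * np.sin(np.deg2rad(min(2.0 * spec.placement_jitter, 90.0)))
    excl_perp = 2.0 * (spec.mean_radius + jitter_pad + 1.0)
    centers: list[np.ndarray] = []

    def _separated(c: np.ndarray) -> bool:
        for c0 in centers:
            d = c - c0
            dv = float(d @ base_dir)
            dperp = float(np.linalg.norm(d - dv * base_dir))
            if (dv / excl_long) ** 2 + (dperp / excl_perp) ** 2 < 1.0:
                return False
        return True

    rows = []
    for b in range(n):
        placed = False
        for _ in range(spec.max_retries):
            c = margin + rng.random(3) * (shape - 2 * margin)
            if _separated(c):
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place bubble {b} after {spec.max_retries} tries")
        centers.append(c)
        # angular jitter: rotate the long axis about a random perpendicular axis
        if spec.placement_jitter > 0:
            _, u1, u2 = _geometry.orthonormal_frame(base_dir)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            perp = np.cos(phi) * u1 + np.sin(phi) * u2
            angle = np.deg2rad(rng.normal(0.0, spec.placement_jitter))
            rot = _geometry.rotation_about_axis(perp, angle)
            long_axis = rot @ base_dir
        else:
            long_axis = base_dir
        frame = _geometry.orthonormal_frame(long_axis)
        semi = (a_long, spec.mean_radius, spec.mean_radius)
        count = _rasterize_ellipsoid(phases, c, semi, frame, PHASE_AIR)
        rows.append(
            {
                "center_z": c[0],
                "center_y": c[1],
                "center_x": c[2],
                "semi_a": a_long,
                "semi_b": spec.mean_radius,
                "semi_c": spec.mean_radius,
                "axis_z": long_axis[0],
                "axis_y": long_axis[1],
                "axis_x": long_axis[2],
                "volume_voxels_analytic": 4.0 / 3.0 * np.pi * a_long * spec.mean_radius**2,
                "anisotropy": spec.aspect_ratio,
                "voxel_count": count,
            }
        )
    # rest phase: small spheres avoiding the bubbles
    total = phases.size
    target_rest = spec.rest_fraction * total
    rest_voxels = 0
    r_rest = max(2.0, spec.mean_radius / 2.0)
    attempts = 0
    while rest_voxels < target_rest and attempts < spec.max_retries:
        attempts += 1
        c = r_rest + 1 + rng.random(3) * (shape - 2 * (r_rest + 1))
        if any(np.linalg.norm(c - c0) < margin + r_rest for c0 in centers):
            continue
        frame = _geometry.orthonormal_frame(np.array([0.0, 0.0, 1.0]))
        rest_voxels += _rasterize_ellipsoid(
            phases, c, (r_rest, r_rest, r_rest), frame, PHASE_REST
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "center_z", "center_y", "center_x",
            "semi_a", "semi_b", "semi_c",
            "axis_z", "axis_y", "axis_x",
            "volume_voxels_analytic", "anisotropy", "voxel_count",
        ],
    )
    return phases, truth


# ---------------------------------------------------------------------------
# micrographs
# ---------------------------------------------------------------------------


@dataclass
class SyntheticMicrographSpec:
    """Striped or isotropic grayscale texture with dark elliptical domains.

    The stripe texture is a sinusoid of wavelength 8 px at ``stripe_angle``
    (a single closed-form orientation, so structure-tensor coherency has a
    known limit of 1); ``isotropic_noise`` has no dominant direction.
    Dark elliptical domains emulate non-protein regions in a
    protein-stained section.
    """

    shape: tuple[int, int] = (512, 512)
    texture: str = "stripes"
    stripe_angle: float = 0.0            # degrees in [0, 180)
    stripe_wavelength: float = 8.0       # px
    n_domains: int = 0
    domain_aspect: float = 2.0
    domain_feret_range: tuple[float, float] = (60.0, 120.0)  # um
    domain_angle: float | None = None    # degrees; None = align with stripes
    pixel_size: float = 2.0              # um
    noise_amplitude: float = 0.0         # SD of additive noise over the texture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        if min(self.shape) < 64:
            raise ValueError("image must be at least 64x64")
        if self.texture not in ("stripes", "isotropic_noise"):
            raise ValueError("texture must be 'stripes' or 'isotropic_noise'")
        if not 0.0 <= self.stripe_angle < 180.0:
            raise ValueError("stripe_angle must lie in [0, 180)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.domain_aspect < 1:
            raise ValueError("domain_aspect must be >= 1")
        lo, hi = self.domain_feret_range
        if not 0 < lo <= hi:
            raise ValueError("domain_feret_range must be positive and ordered")
        if hi / self.pixel_size > min(self.shape):
            raise ValueError("domains larger than the image")


def gen_fibrous_micrograph(
    spec: SyntheticMicrographSpec,
) -> tuple[np.ndarray, pd.DataFrame, float | None]:
    """Generate a float image in [0, 1], a domain ground-truth table and
    the ground-truth dominant direction (None for isotropic noise).

    Angle convention: directions are measured in degrees from the column
    (x) axis toward the row (y) axis, modulo 180; stripes at ``stripe_angle``
    run along that direction.
    """
    rng = np.random.default_rng(spec.seed)
    rows_idx, cols_idx = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
    if spec.texture == "stripes":
        theta = np.deg2rad(spec.stripe_angle)
        # stripe direction s = (cos, sin) in (x=col, y=row); phase varies along the normal
        phase = (2.0 * np.pi / spec.stripe_wavelength) * (
            -cols_idx * np.sin(theta) + rows_idx * np.cos(theta)
        )
        image = 0.55 + 0.35 * np.sin(phase)
        truth_direction: float | None = spec.stripe_angle
    else:
        image = 0.55 + 0.15 * rng.standard_normal(spec.shape)
        truth_direction = None
    if spec.noise_amplitude > 0:
        image = image + spec.noise_amplitude * rng.standard_normal(spec.shape)
    image = np.clip(image, 0.0, 1.0)
    rows = []
    for _ in range(spec.n_domains):
        feret_um = rng.uniform(*spec.domain_feret_range)
        major_px = 0.5 * feret_um / spec.pixel_size
        minor_px = major_px / spec.domain_aspect
        ang = spec.domain_angle if spec.domain_angle is not None else (
            spec.stripe_angle if spec.texture == "stripes" else rng.uniform(0, 180)
        )
        t = np.deg2rad(ang)
        cr = rng.uniform(major_px + 2, spec.shape[0] - major_px - 2)
        cc = rng.uniform(major_px + 2, spec.shape[1] - major_px - 2)
        # ellipse axes in (x=col, y=row)
        dx = cols_idx - cc
        dy = rows_idx - cr
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        mask = (u / major_px) ** 2 + (v / minor_px) ** 2 <= 1.0
        image[mask] = 0.05
        rows.append(
            {
                "center_row": cr,
                "center_col": cc,
                "feret_um": feret_um,
                "width_um": feret_um / spec.domain_aspect,
                "aspect": spec.domain_aspect,
                "angle_deg": ang % 180.0,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["center_row", "center_col", "feret_um", "width_um", "aspect", "angle_deg"],
    )
    return image, truth, truth_direction


# ---------------------------------------------------------------------------
# multi-product study table
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudySpec:
    """Product-level feature table driven by one latent anisotropy factor.

    Parameter p of product i is ``loading_p * latent_i + noise_p * eps``,
    with latent and noise standard normal, so the implied Pearson
    correlation between parameters p and q is the product of their
    standardized loadings: r = l_p l_q / sqrt((l_p^2+s_p^2)(l_q^2+s_q^2)).
    """

    n_products: int = 11
    latent_loadings: dict[str, float] = field(
        default_factory=lambda: {"fibre_score": 1.0, "aix_toughness": 0.9, "air_anisotropy": 0.8}
    )
    noise_sd: dict[str, float] | float = 0.3
    product_set_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_products < 4:
            raise ValueError("need at least 4 products")
        if sum(v != 0 for v in self.latent_loadings.values()) < 2:
            raise ValueError("need >= 2 parameters with nonzero loadings")
        if not all(np.isfinite(list(self.latent_loadings.values()))):
            raise ValueError("loadings must be finite")
        if self.product_set_labels is not None and len(self.product_set_labels) != self.n_products:
            raise ValueError("product_set_labels length must equal n_products")

    def noise_for(self, name: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(name, 0.0))
        return float(self.noise_sd)


def implied_correlation(l1: float, s1: float, l2: float, s2: float) -> float:
    """Pearson r implied by two loadings on a shared standard-normal latent."""
    return l1 * l2 / np.sqrt((l1**2 + s1**2) * (l2**2 + s2**2))


def gen_study_table(spec: SyntheticStudySpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the product x parameter table and the latent factor values.

    The returned frame is indexed by product id and carries a
    ``product_set`` label column (first half "A", second half "B" unless
    labels are supplied) ahead of the parameter columns.
    """
    rng = np.random.default_rng(spec.seed)
    latent = rng.standard_normal(spec.n_products)
    data = {}
    for name, loading in spec.latent_loadings.items():
        s = spec.noise_for(name)
        noise = s * rng.standard_normal(spec.n_products) if s > 0 else 0.0
        data[name] = loading * latent + noise
    labels = spec.product_set_labels
    if labels is None:
        half = spec.n_products // 2
        labels = ["A"] * half + ["B"] * (spec.n_products - half)
    index = pd.Index([f"P{i:02d}" for i in range(spec.n_products)], name="product")
    table = pd.DataFrame(data, index=index)
    table.insert(0, "product_set", labels)
    return table, latent
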