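"""True stress-strain conversion and tensile parameter extraction.

A uniaxial tensile record (force F(t), displacement) with specimen
geometry is converted to true stress and true (Hencky) strain under a
volume-conservation assumption (Poisson's ratio 0.5):

    sigma(t) = F(t) / A(t),   A(t) = (h0 / h(t)) * A0,   eps(t) = ln(h(t) / h0)

where h0 is the initial gauge length, h(t) = h0 + displacement and
A0 = width * thickness.  From the curve we extract the Young's modulus
(slope of the linear part), the fracture point (stress maximum), the
failure point (stress back to ~zero), the fracture length
(eps_failure - eps_fracture; short = abrupt fracture), and the toughness
(area under the curve, J/m^3).  Parameters measured parallel and
perpendicular to the shear-flow direction combine into anisotropy
indices AIx = parallel / perpendicular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_GAUGE_LENGTH_M = 8.5e-3     # dog-bone gauge length
DEFAULT_POISSON = 0.5               # volume-conserving assumption
FAILURE_STRESS_FRACTION = 0.02      # "stress reached 0" threshold, fraction of peak


class GeometryError(ValueError):
    """Nonpositive specimen dimensions."""


class DataError(ValueError):
    """Physically impossible record (e.g. nonpositive gauge length)."""


class DegenerateCurveError(ValueError):
    """All-zero stress curve."""


class FitError(ValueError):
    """Too few points for a modulus fit."""


class UndefinedIndexError(ZeroDivisionError):
    """Anisotropy index with a zero perpendicular value."""


@dataclass
class TensileSpecimen:
    """Geometry and orientation of one dog-bone tensile specimen."""

    width0: float                       # m
    thickness0: float                   # m
    gauge_length: float = DEFAULT_GAUGE_LENGTH_M  # m
    direction: str = "parallel"         # relative to the shear-flow direction
    poisson_assumed: float = DEFAULT_POISSON

    def __post_init__(self) -> None:
        if min(self.width0, self.thickness0, self.gauge_length) <= 0:
            raise GeometryError("specimen dimensions must be positive")
        if self.direction not in ("parallel", "perpendicular"):
            raise ValueError("direction must be 'parallel' or 'perpendicular'")
        if not 0.0 <= self.poisson_assumed <= 0.5:
            raise ValueError("poisson_assumed must lie in [0, 0.5]")

    @property
    def area0(self) -> float:
        return self.width0 * self.thickness0


@dataclass
class ForceDisplacementRecord:
    """Raw tensile record: time (s), force (N), displacement (m)."""

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.displacement)):
            raise ValueError("time, force and displacement must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise DataError("force contains non-finite values")


@dataclass
class StressStrainCurve:
    """True stress-strain samples ordered by strain."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must have equal length")
        if len(self.strain) > 1 and np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be non-decreasing")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass
class TensileSummary:
    """Scalar mechanical parameters extracted from one specimen."""

    youngs_modulus: float      # Pa
    fracture_stress: float     # Pa (peak true stress)
    fracture_strain: float     # true strain at the peak
    failure_strain: float      # true strain where stress returns to ~0
    fracture_length: float     # failure_strain - fracture_strain
    toughness: float           # Pa == J/m^3, area under the curve


@dataclass
class DirectionalSummary:
    """Parallel and perpendicular summaries with per-parameter anisotropy indices."""

    parallel: TensileSummary
    perpendicular: TensileSummary
    aix: dict[str, float] = field(default_factory=dict)


def to_true_stress_strain(
    record: ForceDisplacementRecord,
    specimen: TensileSpecimen,
    clip_negative_stress: bool = True,
) -> StressStrainCurve:
    """Convert a force-displacement record to a true stress-strain curve.

    Uses the incompressible cross-section update A(t) = (h0/h(t)) A0 and
    Hencky strain eps = ln(h/h0).  A Poisson's ratio below 0.5 generalizes
    the area update to A(t) = (h0/h(t))^(2 nu) A0.  Negative force readings
    (sensor noise) are clipped to zero stress by default.
    """
    h0 = specimen.gauge_length
    h = h0 + record.displacement
    if np.any(h <= 0):
        raise DataError("gauge length h(t) must stay positive")
    if specimen.area0 <= 0:
        raise GeometryError("initial cross-section area is zero")
    area = (h0 / h) ** (2.0 * specimen.poisson_assumed) * specimen.area0
    stress = record.force / area
    if clip_negative_stress:
        stress = np.clip(stress, 0.0, None)
    strain = np.log(h / h0)
    return StressStrainCurve(strain=strain, stress=stress)


def detect_fracture_point(curve: StressStrainCurve) -> tuple[int, float, float]:
    """Index, strain and stress of the fracture point (global stress maximum).

    The first index wins on exact ties.
    """
    if len(curve) == 0:
        raise DegenerateCurveError("empty curve")
    if np.all(curve.stress == 0):
        raise DegenerateCurveError("all-zero stress curve")
    idx = int(np.argmax(curve.stress))
    return idx, float(curve.strain[idx]), float(curve.stress[idx])


def detect_failure_point(
    curve: StressStrainCurve,
    fracture_index: int,
    stress_fraction: float = FAILURE_STRESS_FRACTION,
) -> float:
    """Strain at the failure point: stress back below a small fraction of the peak.

    Returns the smallest strain after the fracture point where
    sigma <= stress_fraction * sigma_fracture.  Measured force never reaches
    exactly zero, hence the small threshold.  If the record is truncated
    before the threshold is reached, the last sample's strain is returned
    with a warning.
    """
    sigma_f = curve.stress[fracture_index]
    tail = curve.stress[fracture_index + 1 :]
    below = np.flatnonzero(tail <= stress_fraction * sigma_f)
    if len(below) == 0:
        warnings.warn(
            "stress never returned to zero; using the last recorded strain",
            stacklevel=2,
        )
        return float(curve.strain[-1])
    return float(curve.strain[fracture_index + 1 + below[0]])


def fit_youngs_modulus(
    curve: StressStrainCurve,
    fracture_index: int | None = None,
    strain_fraction: float = 0.4,
    min_window_fraction: float = 0.1,
) -> float:
    """Young's modulus: slope of the linear part of the stress-strain curve.

    The linear part is located deterministically: among all contiguous
    windows within the first ``strain_fraction`` of the pre-fracture strain
    whose length is at least ``min_window_fraction`` of the pre-fracture
    points (and at least 10 points), the window maximizing the
    least-squares R^2 is chosen; ties go to the earliest start, then the
    longest window, so a perfectly linear initial segment is fitted over
    its full length rather than a later or global secant.
    """
    if fracture_index is None:
        fracture_index, _, _ = detect_fracture_point(curve)
    n_pre = fracture_index + 1
    if n_pre < 10:
        raise FitError("need at least 10 points before the fracture point")
    eps_limit = strain_fraction * curve.strain[fracture_index]
    m = int(np.searchsorted(curve.strain[:n_pre], eps_limit, side="right"))
    m = max(m, 2)
    w_min = max(10, int(np.ceil(min_window_fraction * n_pre)))
    w_min = min(w_min, m)
    x = curve.strain[:m]
    y = curve.stress[:m]
    # prefix sums give O(1) regression statistics per window
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    tol = 1e-12
    best_r2, best_i, best_w, best_slope = -np.inf, m, 0, 0.0
    for w in range(w_min, m + 1):
        for i in range(0, m - w + 1):
            j = i + w
            sx = cx[j] - cx[i]
            sy = cy[j] - cy[i]
            sxx = cxx[j] - cxx[i]
            syy = cyy[j] - cyy[i]
            sxy = cxy[j] - cxy[i]
            vx = w * sxx - sx * sx
            vy = w * syy - sy * sy
            cov = w * sxy - sx * sy
            if vx <= 0 or vy <= 0:
                continue
            # cancellation in the prefix sums can push r2 marginally above 1
            r2 = min(cov * cov / (vx * vy), 1.0)
            take = r2 > best_r2 + tol or (
                abs(r2 - best_r2) <= tol
                and (i < best_i or (i == best_i and w > best_w))
            )
            if take:
                best_r2, best_i, best_w, best_slope = r2, i, w, cov / vx
    if best_w == 0:
        raise FitError("no window with nonzero variance found")
    return float(best_slope)


def compute_toughness(curve: StressStrainCurve, failure_strain: float) -> float:
    """Area under the stress-strain curve from zero strain to failure (J/m^3).

    Trapezoidal integration; stress is clipped at zero from below and the
    curve is interpolated at the failure strain if it falls between samples.
    """
    if not curve.strain[0] <= failure_strain <= curve.strain[-1]:
        raise ValueError("failure_strain outside the curve's strain range")
    stress = np.clip(curve.stress, 0.0, None)
    mask = curve.strain <= failure_strain
    eps = curve.strain[mask]
    sig = stress[mask]
    if eps[-1] < failure_strain:
        eps = np.append(eps, failure_strain)
        sig = np.append(sig, np.interp(failure_strain, curve.strain, stress))
    return float(np.trapezoid(sig, eps))


def compute_fracture_length(
    fracture_strain: float, failure_strain: float, mode: str = "difference"
) -> float:
    """Strain interval between the fracture point and the failure point.

    Short values indicate abrupt fracture; long values a staged, gradual
    fracture.  ``mode='ratio'`` returns failure/fracture strain instead of
    the default difference.
    """
    if failure_strain < fracture_strain:
        raise ValueError("failure_strain must not precede fracture_strain")
    if mode == "difference":
        return failure_strain - fracture_strain
    if mode == "ratio":
        if fracture_strain == 0:
            raise ZeroDivisionError("ratio undefined for zero fracture strain")
        return failure_strain / fracture_strain
    raise ValueError(f"unknown mode {mode!r}")


def anisotropy_index(
    value_parallel: float, value_perpendicular: float, mode: str = "ratio"
) -> float:
    """Anisotropy index of a parameter measured in the two flow-relative directions.

    Default is the ratio parallel/perpendicular (1 = isotropic; higher =
    more anisotropic).  ``mode='abslog'`` gives the symmetric |ln ratio|.
    """
    if value_perpendicular == 0:
        raise UndefinedIndexError("anisotropy index undefined for zero perpendicular value")
    ratio = value_parallel / value_perpendicular
    if mode == "ratio":
        return ratio
    if mode == "abslog":
        if ratio <= 0:
            raise ValueError("abslog index requires a positive ratio")
        return abs(float(np.log(ratio)))
    raise ValueError(f"unknown mode {mode!r}")


def summarize_curve(
    curve: StressStrainCurve,
    stress_fraction: float = FAILURE_STRESS_FRACTION,
    fracture_length_mode: str = "difference",
) -> TensileSummary:
    """Extract the full set of tensile parameters from one curve."""
    idx, eps_f, sigma_f = detect_fracture_point(curve)
    eps_fail = detect_failure_point(curve, idx, stress_fraction=stress_fraction)
    return TensileSummary(
        youngs_modulus=fit_youngs_modulus(curve, fracture_index=idx),
        fracture_stress=sigma_f,
        fracture_strain=eps_f,
        failure_strain=eps_fail,
        fracture_length=compute_fracture_length(eps_f, eps_fail, mode=fracture_length_mode),
        toughness=compute_toughness(curve, eps_fail),
    )


AIX_PARAMETERS = (
    "youngs_modulus",
    "fracture_stress",
    "fracture_strain",
    "failure_strain",
    "fracture_length",
    "toughness",
)


def directional_summary(
    parallel: TensileSummary, perpendicular: TensileSummary
) -> DirectionalSummary:
    """Pair the two directions and compute per-parameter anisotropy indices."""
    aix = {}
    for name in AIX_PARAMETERS:
        per = getattr(perpendicular, name)
        if per != 0:
            aix[name] = anisotropy_index(getattr(parallel, name), per)
        else:
            aix[name] = float("nan")
    return DirectionalSummary(parallel=parallel, perpendicular=perpendicular, aix=aix)
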