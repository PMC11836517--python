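"""Pipeline configuration: study-default constants, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable settings of the multiscale pipeline with study defaults.

    Defaults encode the measurement conditions: 8.5 mm gauge length,
    11.4 mm/min deformation rate, 37 um DIC grid spacing with Moran
    distances up to 8 along the axis perpendicular to tension, 6 um
    tomography voxels, 40 um CLSM size filter, variance thresholds 0.10
    (combined) / 0.15 (per product set) and top-3 feature selection.
    Every value is overridable from a YAML file.
    """

    # paths per modality (None = modality absent)
    input_dir: str | None = None
    tensile_dir: str | None = None
    dic_dir: str | None = None
    tomo_dir: str | None = None
    clsm_dir: str | None = None
    annotations: str | None = None
    output_dir: str = "results"

    # tensile geometry / protocol
    gauge_length_m: float = 8.5e-3
    specimen_width_m: float = 20e-3
    specimen_thickness_m: float = 3e-3
    deformation_rate_m_s: float = 11.4e-3 / 60.0
    failure_stress_fraction: float = 0.02

    # DIC
    grid_spacing_um: float = 37.0
    moran_d_max: int = 8
    moran_axis: int = 1  # grid axis of adjacency (perpendicular to tension)

    # tomography
    voxel_size_um: float = 6.0

    # CLSM
    clsm_pixel_size_um: float = 2.0
    min_feret_um: float = 40.0

    # integration
    variance_threshold_combined: float = 0.10
    variance_threshold_per_set: float = 0.15
    select_k: int = 3
    selection_targets: list[str] = field(
        default_factory=lambda: ["FibreScore", "AIxToughness", "AirAnisotropy"]
    )

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    _PATH_FIELDS = (
        "input_dir", "tensile_dir", "dic_dir", "tomo_dir", "clsm_dir",
        "annotations", "output_dir",
    )

    def config_hash(self) -> str:
        """Stable short hash of the analysis settings (embedded in outputs).

        Path fields are excluded so the same analysis run from or into a
        different location reproduces byte-identical reports.
        """
        data = {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}
        canonical = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
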