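"""Readers and writers: TIFF stacks, tensile CSV records, annotated tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from anisotex.tensile import ForceDisplacementRecord

TENSILE_COLUMNS = ("time_s", "force_N", "displacement_m")


class FormatError(IOError):
    """Unreadable or malformed input file."""


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a 2D/3D array, dtype preserved."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return tifffile.imread(path)
    except Exception as exc:  # truncated/foreign files
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc


def write_stack(path: str | Path, data: np.ndarray) -> None:
    """Write an array as a (multi-page) TIFF; round-trips bit-identically."""
    tifffile.imwrite(Path(path), np.asarray(data))


def write_tensile_csv(
    path: str | Path, record: ForceDisplacementRecord, config_hash: str | None = None
) -> None:
    frame = pd.DataFrame(
        {
            "time_s": record.time,
            "force_N": record.force,
            "displacement_m": record.displacement,
        }
    )
    _write_csv(path, frame, config_hash)


def read_tensile_csv(path: str | Path) -> ForceDisplacementRecord:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(TENSILE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path} lacks columns {sorted(missing)}")
    return ForceDisplacementRecord(
        time=frame["time_s"].to_numpy(),
        force=frame["force_N"].to_numpy(),
        displacement=frame["displacement_m"].to_numpy(),
    )


def _write_csv(path: str | Path, frame: pd.DataFrame, config_hash: str | None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# anisotex-config-hash: {config_hash}\n")
        # %.17g round-trips doubles exactly
        frame.to_csv(fh, index=index, float_format="%.17g")


def write_table(path: str | Path, frame: pd.DataFrame, config_hash: str | None = None, index: bool = True) -> None:
    """Write an output table, optionally stamped with the config hash."""
    _write_csv(path, frame, config_hash, index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(
        path, comment="#", index_col=index_col, float_precision="round_trip"
    )
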