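"""File formats: pose-stream CSV, angle CSV, plateau tables, reports, config.

CSV numeric columns are written with round-trip precision (17 significant
digits); report tables round only at render time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import BlandAltmanResult, CorrelationResult, ICCResult
from .kinematics import AngleSeries
from .plateau import Plateau
from .rigid import PoseStream
from .simulate import SimConfig, ValidationReport

__all__ = [
    "ParseError",
    "POSE_COLUMNS",
    "read_pose_stream",
    "write_pose_stream",
    "read_angle_series",
    "write_angle_series",
    "write_plateaus",
    "read_measurement_column",
    "load_config",
    "save_config",
    "write_agreement_report",
    "write_validation_report",
]

logger = logging.getLogger(__name__)

POSE_COLUMNS = ["t_s", "sensor_id", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"]
_FLOAT_FMT = "%.17g"

# quaternion-norm read policy: silently renormalize float-serialization
# rounding, warn about sloppier input, reject corrupt data
_QUAT_SILENT = 1e-6
_QUAT_WARN = 1e-3


class ParseError(ValueError):
    """A file failed structural validation; the message names the line."""


def write_pose_stream(stream: PoseStream, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": stream.t,
            "sensor_id": stream.sensor_id,
            "x_mm": stream.positions[:, 0],
            "y_mm": stream.positions[:, 1],
            "z_mm": stream.positions[:, 2],
            "qw": stream.orientations[:, 0],
            "qx": stream.orientations[:, 1],
            "qy": stream.orientations[:, 2],
            "qz": stream.orientations[:, 3],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pose_stream(path, rate_hz: float | None = None) -> PoseStream:
    """Parse a pose-stream CSV, validating structure row by row.

    Line numbers in error messages count the header as line 1. The
    sampling rate is inferred from the median timestamp spacing unless
    given explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")

    num = df[[c for c in POSE_COLUMNS if c != "sensor_id"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(num), axis=1)
    if np.any(bad):
        raise ParseError(f"{path}: non-finite value at line {int(np.argmax(bad)) + 2}")

    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1:
        dec = np.diff(t) <= 0
        if np.any(dec):
            raise ParseError(
                f"{path}: timestamps not strictly increasing at line {int(np.argmax(dec)) + 3}"
            )

    quats = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(quats, axis=1)
    err = np.abs(norms - 1.0)
    if np.any(err > _QUAT_WARN):
        i = int(np.argmax(err > _QUAT_WARN))
        raise ParseError(
            f"{path}: quaternion norm {norms[i]:.6g} at line {i + 2} beyond "
            f"renormalization tolerance {_QUAT_WARN:g}"
        )
    if np.any(err > _QUAT_SILENT):
        logger.warning(
            "%s: %d quaternion(s) off unit norm by more than %g; renormalized",
            path,
            int(np.count_nonzero(err > _QUAT_SILENT)),
            _QUAT_SILENT,
        )

    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 60.0
    sensor_id = str(df["sensor_id"].iloc[0]) if len(df) else "unknown"
    return PoseStream(
        sensor_id=sensor_id,
        t=t,
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        orientations=quats,
        rate_hz=rate_hz,
    )


def write_angle_series(series: AngleSeries, path) -> None:
    pd.DataFrame({"t_s": series.t, "phi_deg": series.phi}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_angle_series(path) -> AngleSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("t_s", "phi_deg"):
        if c not in df.columns:
            raise ParseError(f"{path}: missing column {c}")
    return AngleSeries(t=df["t_s"].to_numpy(dtype=float), phi=df["phi_deg"].to_numpy(dtype=float))


def write_plateaus(plateaus: list[Plateau], path) -> None:
    pd.DataFrame(
        [
            {
                "t_start_s": p.t_start,
                "t_end_s": p.t_end,
                "mean_deg": p.mean_deg,
                "sd_deg": p.sd_deg,
                "n_samples": p.n_samples,
                "nominal_deg": p.nominal_deg,
            }
            for p in plateaus
        ],
        columns=["t_start_s", "t_end_s", "mean_deg", "sd_deg", "n_samples", "nominal_deg"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_measurement_column(path, column: str | None = None) -> np.ndarray:
    """First (or named) numeric column of a CSV as a flat array."""
    df = pd.read_csv(path)
    if column is not None:
        if column not in df.columns:
            raise ParseError(f"{path}: missing column {column}")
        return df[column].to_numpy(dtype=float)
    for c in df.columns:
        if pd.api.types.is_numeric_dtype(df[c]):
            return df[c].to_numpy(dtype=float)
    raise ParseError(f"{path}: no numeric column found")


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def load_config(path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {f.name for f in SimConfig.__dataclass_fields__.values()}
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
    return SimConfig(**data)


def _dump_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_agreement_report(
    path,
    pearson: CorrelationResult | None = None,
    bland_altman: BlandAltmanResult | None = None,
    icc: list[ICCResult] | None = None,
) -> None:
    _dump_json(
        {
            "pearson": pearson.to_dict() if pearson else None,
            "bland_altman": bland_altman.to_dict() if bland_altman else None,
            "icc": [r.to_dict() for r in icc] if icc else [],
        },
        path,
    )


def write_validation_report(report: ValidationReport, out_dir) -> None:
    """Report JSON plus CSV tables mirroring the study's summary layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_json(report.to_dict(), out / "report.json")
    report.summary.to_csv(out / "summary.csv", float_format=_FLOAT_FMT)
    report.measurements.to_csv(out / "measurements.csv", index=False, float_format=_FLOAT_FMT)
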