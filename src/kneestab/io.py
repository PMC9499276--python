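"""CSV readers/writers for sensor streams and ground-truth sidecars.

The IMU dialect is a header-keyed CSV with columns
``t, ax, ay, az, gx, gy, gz, mx, my, mz`` in SI units (s, m/s², rad/s,
µT); column order is irrelevant.  Force-plate files carry ``t, grfv``
(s, N).  Ground truth and events serialise to JSON sidecars.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import SchemaError
from .types import GrfRecording, GroundTruth, ImuRecording

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]

__all__ = ["read_imu_csv", "write_imu_csv", "read_grf_csv", "write_grf_csv",
           "write_ground_truth", "read_ground_truth", "IMU_COLUMNS"]


def _validated_frame(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {', '.join(missing)}")
    out = {}
    for c in columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any() or col.isna().any():
            row = int(np.nonzero(col.isna().to_numpy())[0][0])
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {c!r}, "
                f"data row {row}")
        out[c] = col.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_imu_csv(path, location: str) -> ImuRecording:
    """Read one sensor stream; validates schema, ranges and monotone time."""
    df = _validated_frame(path, IMU_COLUMNS)
    t = df["t"].to_numpy()
    if len(t) > 1:
        fs = 1.0 / np.median(np.diff(t))
    else:
        raise SchemaError(f"{path}: need at least 2 samples")
    return ImuRecording(
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        mag=df[["mx", "my", "mz"]].to_numpy(),
        fs=float(fs), location=location)


def write_imu_csv(rec: ImuRecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.acc, rec.gyro, rec.mag]),
        columns=IMU_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_grf_csv(path, body_mass: float) -> GrfRecording:
    df = _validated_frame(path, ["t", "grfv"])
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    return GrfRecording(t=t, grfv=df["grfv"].to_numpy(), fs=float(fs),
                        body_mass=body_mass)


def write_grf_csv(rec: GrfRecording, path) -> None:
    pd.DataFrame({"t": rec.t, "grfv": rec.grfv}).to_csv(
        path, index=False, float_format="%.9g")


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump({"event_times": gt.event_times,
                   "true_parameter_values": gt.true_parameter_values,
                   "true_icc": gt.true_icc}, fh, indent=2, sort_keys=True,
                  default=float)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(event_times=d.get("event_times", {}),
                       true_parameter_values=d.get(
                           "true_parameter_values", {}),
                       true_icc=d.get("true_icc"))
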