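"""Pose CSV reading/writing and JSON report serialization.

Pose files are delimited text with a header row and columns

    t, r11, r12, r13, tx, r21, r22, r23, ty, r31, r32, r33, tz

(row-major rotation matrix interleaved with the translation column).
Translations may be declared in meters or millimeters; everything is stored
internally in SI.  Rotation blocks are validated on read: orthonormality
error above 1e-6 rejects the row, between 1e-9 and 1e-6 the nearest rotation
(via SVD projection) is substituted and a warning logged.
"""

from __future__ import annotations

import json
import logging
import math

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .screw_kinematics import Pose, PoseSequence

__all__ = ["POSE_COLUMNS", "read_pose_csv", "write_pose_csv", "write_report", "read_report"]

logger = logging.getLogger(__name__)

POSE_COLUMNS = [
    "t",
    "r11", "r12", "r13", "tx",
    "r21", "r22", "r23", "ty",
    "r31", "r32", "r33", "tz",
]

SCHEMA_VERSION = "1.0"

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3}


def _nearest_rotation(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def read_pose_csv(path, units: str = "m") -> PoseSequence:
    """Read a pose sequence from CSV; translations declared in m or mm."""
    if units not in _UNIT_SCALE:
        raise ValidationError(f"unknown translation units {units!r} (use 'm' or 'mm')")
    scale = _UNIT_SCALE[units]
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pose file missing columns: {missing}")
    poses = []
    for idx, row in enumerate(df.itertuples(index=False)):
        vals = [getattr(row, c) for c in POSE_COLUMNS]
        if any(not math.isfinite(float(v)) for v in vals):
            raise ValidationError(f"malformed row {idx}: non-finite value")
        t = float(vals[0])
        R = np.array(vals[1:]).reshape(3, 4)[:, :3]
        p = scale * np.array([vals[4], vals[8], vals[12]], dtype=float)
        err = np.linalg.norm(R.T @ R - np.eye(3))
        if err > 1e-6 or np.linalg.det(R) < 0:
            raise ValidationError(f"row {idx}: invalid rotation (orthonormality error {err:.2e}, det {np.linalg.det(R):.3f})")
        if err > 1e-9:
            logger.warning("row %d: re-orthonormalizing rotation (error %.2e)", idx, err)
            R = _nearest_rotation(R)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = p
        poses.append(Pose(t=t, T=T))
    if len(poses) < 2:
        raise ValidationError("pose file must contain at least 2 samples")
    diffs = np.diff([p.t for p in poses])
    dt = float(np.median(diffs))
    if np.max(np.abs(diffs - dt)) > 1e-9:
        raise ValidationError("non-uniform sampling interval in pose file")
    return PoseSequence(poses=tuple(poses), dt=dt)


def write_pose_csv(ps: PoseSequence, path, units: str = "m") -> None:
    """Write a pose sequence to CSV in the schema read_pose_csv expects."""
    if units not in _UNIT_SCALE:
        raise ValidationError(f"unknown translation units {units!r} (use 'm' or 'mm')")
    scale = 1.0 / _UNIT_SCALE[units]
    rows = []
    for p in ps.poses:
        R = p.R
        tr = scale * p.p
        rows.append(
            [p.t]
            + [R[0, 0], R[0, 1], R[0, 2], tr[0]]
            + [R[1, 0], R[1, 1], R[1, 2], tr[1]]
            + [R[2, 0], R[2, 1], R[2, 2], tr[2]]
        )
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_report(result, report, path, extra: dict | None = None) -> None:
    """Write an ASA estimate plus (optional) dispersion report to one JSON file.

    ``report`` may be None (e.g. too few samples for the dispersion
    analysis); its keys are then present with null values rather than absent.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "asa": None if result is None else result.to_dict(),
        "dispersion": None if report is None else report.to_dict(),
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
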