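"""Spatial calibration of tracked tools and the ultrasound image plane.

Two procedures are covered:

* **Pivot calibration** of a tracked pointer/needle: the tool is rotated
  about a fixed physical point; the tip offset in the tool frame and the
  pivot location in the tracker frame fall out of a joint linear
  least-squares problem over all recorded poses.

* **Needle (image) calibration** of the ultrasound plane: the tip of a
  tracked needle is localised in pixel coordinates while its physical
  position is known in the probe frame; pixel/mm spacings plus a rigid
  image-to-probe transform are fitted from the pairs.

Image-plane convention: pixel ``(u, v)`` has ``u`` = lateral column index
increasing rightward and ``v`` = axial row index increasing with depth; the
image origin is the top-left pixel centre, and the in-plane mm point is
``(u * spacing_lateral, v * spacing_axial, 0)``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rigid_geometry import (
    DegenerateConfigurationError,
    PointSet,
    RigidTransform,
    paired_point_register,
)

__all__ = [
    "PivotResult",
    "ImageCalibration",
    "DegenerateMotionError",
    "pivot_calibrate",
    "needle_calibrate",
    "pixel_to_plane_mm",
    "read_pose_csv",
    "write_pose_csv",
    "read_calibration_json",
    "write_calibration_json",
]


class DegenerateMotionError(ValueError):
    """Pivot poses do not span enough orientations for a unique solution."""


@dataclasses.dataclass(frozen=True)
class PivotResult:
    """Pivot-calibration output: tool-tip offset and pivot point (mm)."""

    tip_offset: np.ndarray      # in the tool frame
    pivot_point: np.ndarray     # in the tracker frame
    rms_mm: float


@dataclasses.dataclass(frozen=True)
class ImageCalibration:
    """Rigid image->probe transform plus pixel spacings (mm/px)."""

    image_to_probe: RigidTransform
    spacing_axial: float
    spacing_lateral: float
    rms_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.spacing_axial <= 0 or self.spacing_lateral <= 0:
            raise ValueError("pixel spacings must be positive")

    def with_axial_spacing(self, spacing_axial: float) -> "ImageCalibration":
        return dataclasses.replace(self, spacing_axial=spacing_axial)


def pixel_to_plane_mm(
    pixels: np.ndarray, spacing_axial: float, spacing_lateral: float
) -> np.ndarray:
    """Convert (N,2) pixel (u,v) coordinates to in-plane mm points (N,3)."""
    px = np.asarray(pixels, dtype=float).reshape(-1, 2)
    out = np.zeros((px.shape[0], 3))
    out[:, 0] = px[:, 0] * spacing_lateral
    out[:, 1] = px[:, 1] * spacing_axial
    return out


def pivot_calibrate(poses: Sequence[RigidTransform]) -> PivotResult:
    """Solve ``R_i p_tip + t_i = p_pivot`` jointly for tip and pivot.

    The stacked linear system ``[R_i | -I] [p_tip; p_pivot] = -t_i`` is
    solved by least squares.  A minimum-orientation-diversity check rejects
    pose sets whose rotations all share one axis (the system is then rank
    deficient and the tip offset is unobservable along that axis).
    """
    if len(poses) < 3:
        raise DegenerateMotionError(
            f"need at least 3 pivot poses, got {len(poses)}"
        )
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, T in enumerate(poses):
        A[3 * i: 3 * i + 3, :3] = T.rotation
        A[3 * i: 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i: 3 * i + 3] = -T.translation
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] < 1e-6:
        raise DegenerateMotionError(
            "pivot poses are rotationally degenerate (all rotations about a "
            f"common axis); smallest singular value {s[-1]:.2e}"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    tip, pivot = x[:3], x[3:]
    residuals = np.array(
        [T.rotation @ tip + T.translation - pivot for T in poses]
    )
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return PivotResult(tip_offset=tip, pivot_point=pivot, rms_mm=rms)


def needle_calibrate(
    pairs: Sequence[tuple[tuple[float, float], np.ndarray]],
    spacing_axial: float | None = None,
    spacing_lateral: float | None = None,
    estimate_spacing: bool = False,
    tol: float = 1e-8,
    max_iterations: int = 100,
) -> ImageCalibration:
    """Fit the rigid image-plane-to-probe transform from needle-tip pairs.

    Each pair is ``((u, v), p_probe)``: the needle tip localised in pixel
    coordinates and its known position in the probe frame (mm).  With known
    spacings the problem reduces to one paired-point rigid fit.  With
    ``estimate_spacing`` the scale fit (linear in the two spacings, with
    rotation/translation held fixed) and the rigid fit alternate until the
    spacings change by less than ``tol`` mm/px.
    """
    if len(pairs) < 4:
        raise DegenerateConfigurationError(
            f"need at least 4 pixel/world pairs, got {len(pairs)}"
        )
    pixels = np.asarray([p[0] for p in pairs], dtype=float)
    world = np.asarray([np.asarray(p[1], dtype=float) for p in pairs])
    # collinearity in pixel space leaves the in-plane rotation unobservable
    centered = pixels - pixels.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(1.0, sv[0]):
        raise DegenerateConfigurationError(
            "needle-tip pixels are collinear; image plane pose is not unique"
        )

    if estimate_spacing:
        sa = 1.0 if spacing_axial is None else float(spacing_axial)
        sl = 1.0 if spacing_lateral is None else float(spacing_lateral)
    else:
        if spacing_axial is None or spacing_lateral is None:
            raise ValueError(
                "spacings must be supplied when estimate_spacing is False"
            )
        sa, sl = float(spacing_axial), float(spacing_lateral)

    T = None
    rms = np.inf
    for iteration in range(max_iterations):
        plane = pixel_to_plane_mm(pixels, sa, sl)
        T, rms = paired_point_register(
            PointSet(plane, frame="image"), PointSet(world, frame="probe")
        )
        if not estimate_spacing:
            break
        # refit spacings with R, t fixed: world ~ R @ diag(sl*u, sa*v, 0) + t
        # residual is linear in (sl, sa)
        R, t = T.rotation, T.translation
        d = world - t
        # columns of the design: R[:,0]*u_i and R[:,1]*v_i
        A = np.zeros((3 * len(pairs), 2))
        A[:, 0] = np.outer(pixels[:, 0], R[:, 0]).ravel()
        A[:, 1] = np.outer(pixels[:, 1], R[:, 1]).ravel()
        sol, *_ = np.linalg.lstsq(A, d.ravel(), rcond=None)
        sl_new, sa_new = sol
        if sl_new <= 0 or sa_new <= 0:
            raise RuntimeError(
                "spacing estimate became non-positive; calibration data are "
                "inconsistent with the image-plane model"
            )
        change = max(abs(sl_new - sl), abs(sa_new - sa))
        sl, sa = float(sl_new), float(sa_new)
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"needle calibration did not converge in {max_iterations} "
            f"iterations (last spacing change {change:.3e} mm/px)"
        )

    assert T is not None
    return ImageCalibration(
        image_to_probe=T, spacing_axial=sa, spacing_lateral=sl,
        rms_mm=float(rms),
    )


# ---------------------------------------------------------------------------
# I/O: pose CSV (12 row-major 3x4 floats + timestamp) and calibration JSON
# ---------------------------------------------------------------------------

def write_pose_csv(
    path: str | Path,
    poses: Sequence[RigidTransform],
    timestamps: Sequence[float] | None = None,
) -> None:
    if timestamps is None:
        timestamps = list(range(len(poses)))
    rows = []
    for T, ts in zip(poses, timestamps):
        flat = np.hstack([T.rotation, T.translation[:, None]]).ravel()
        rows.append(list(flat) + [ts])
    cols = [f"m{i}{j}" for i in range(3) for j in range(4)] + ["timestamp"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_pose_csv(
    path: str | Path, source_frame: str = "tool", target_frame: str = "tracker"
) -> tuple[list[RigidTransform], np.ndarray]:
    df = pd.read_csv(path)
    poses = []
    for _, row in df.iterrows():
        M = row.iloc[:12].to_numpy(dtype=float).reshape(3, 4)
        poses.append(
            RigidTransform(M[:, :3], M[:, 3], source_frame, target_frame)
        )
    return poses, df["timestamp"].to_numpy(dtype=float)


def write_calibration_json(path: str | Path, calib: ImageCalibration) -> None:
    data = {
        "image_to_probe": calib.image_to_probe.matrix.tolist(),
        "source_frame": calib.image_to_probe.source_frame,
        "target_frame": calib.image_to_probe.target_frame,
        "spacing_axial_mm": calib.spacing_axial,
        "spacing_lateral_mm": calib.spacing_lateral,
        "rms_mm": calib.rms_mm,
    }
    Path(path).write_text(json.dumps(data, indent=2))


def read_calibration_json(path: str | Path) -> ImageCalibration:
    data = json.loads(Path(path).read_text())
    M = np.asarray(data["image_to_probe"], dtype=float)
    T = RigidTransform(
        M[:3, :3], M[:3, 3],
        data.get("source_frame", "image"), data.get("target_frame", "probe"),
    )
    return ImageCalibration(
        image_to_probe=T,
        spacing_axial=float(data["spacing_axial_mm"]),
        spacing_lateral=float(data["spacing_lateral_mm"]),
        rms_mm=float(data.get("rms_mm", 0.0)),
    )
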