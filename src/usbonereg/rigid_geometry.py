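"""Rigid-transform algebra, paired-point registration and RMS error.

All coordinates are in millimetres, rotations are proper (det = +1) and
every transform carries explicit frame labels so that mis-chained
compositions fail loudly instead of silently producing garbage poses.
Conventional frame names used throughout the package: ``"image"``,
``"probe"``, ``"reference"``, ``"tracker"``, ``"ct"``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RigidTransform",
    "PointSet",
    "FrameMismatchError",
    "DegenerateConfigurationError",
    "compose",
    "invert",
    "identity",
    "paired_point_register",
    "rms_distance",
    "random_rigid_transform",
    "read_transform",
    "write_transform",
    "read_pointset_csv",
    "write_pointset_csv",
]

_ORTHO_TOL = 1e-9


class FrameMismatchError(ValueError):
    """Raised when transform/point frame labels do not chain."""


class DegenerateConfigurationError(ValueError):
    """Raised for point/pose configurations with no unique rigid solution."""


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """A rigid map ``x_target = R @ x_source + t`` between two named frames.

    Parameters
    ----------
    rotation:
        3x3 proper orthonormal matrix.
    translation:
        3-vector in mm.
    source_frame, target_frame:
        Labels of the frames the transform maps from and to.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str = "source"
    target_frame: str = "target"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform entries")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N,3) or (3,) array of mm coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


@dataclasses.dataclass(frozen=True)
class PointSet:
    """N labelled 3D points (mm) in a named frame."""

    points: np.ndarray
    frame: str = "unknown"
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if p.shape[0] < 1:
            raise ValueError("point set must contain at least one point")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite coordinates")
        if self.names is not None and len(self.names) != p.shape[0]:
            raise ValueError("names length does not match point count")
        object.__setattr__(self, "points", p)
        if self.names is not None:
            object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, T: RigidTransform) -> "PointSet":
        if T.source_frame != self.frame:
            raise FrameMismatchError(
                f"transform maps from '{T.source_frame}' but points are in "
                f"'{self.frame}'"
            )
        return PointSet(T.apply(self.points), frame=T.target_frame, names=self.names)


def identity(frame: str = "world") -> RigidTransform:
    return RigidTransform(np.eye(3), np.zeros(3), frame, frame)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Return the transform applying ``b`` then ``a`` (matrix product a·b)."""
    if a.source_frame != b.target_frame:
        raise FrameMismatchError(
            f"cannot compose: outer transform expects source frame "
            f"'{a.source_frame}' but inner transform targets '{b.target_frame}'"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        source_frame=b.source_frame,
        target_frame=a.target_frame,
    )


def invert(T: RigidTransform) -> RigidTransform:
    Rt = T.rotation.T
    return RigidTransform(
        Rt, -Rt @ T.translation, source_frame=T.target_frame,
        target_frame=T.source_frame,
    )


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # rank >= 2 needed for a unique rotation (up to the det constraint)
    if s.size < 2 or s[1] < 1e-9 * max(1.0, s[0]):
        raise DegenerateConfigurationError(
            "source points are collinear (or coincident); rigid fit is not unique"
        )


def paired_point_register(
    src: PointSet, dst: PointSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform from ``src`` onto ``dst`` (Kabsch/SVD).

    Minimises ``sum ||T·src_i - dst_i||^2`` over proper rigid transforms.
    Reflections are rejected by flipping the singular vector of the smallest
    singular value when the naive solution has negative determinant.

    Returns
    -------
    (transform, rms_mm):
        ``transform`` maps ``src.frame`` to ``dst.frame``; ``rms_mm`` is the
        root-mean-square residual in mm (the fiducial registration error).
    """
    a = src.points
    b = dst.points
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"point counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 point pairs, got {a.shape[0]}"
        )
    _check_not_collinear(a)

    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    T = RigidTransform(R, t, source_frame=src.frame, target_frame=dst.frame)
    residuals = T.apply(a) - b
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return T, rms


def rms_distance(a: PointSet, b: PointSet) -> float:
    """Root-mean-square of per-point Euclidean distances, in mm."""
    if len(a) != len(b):
        raise ValueError(f"point counts differ: {len(a)} vs {len(b)}")
    if a.frame != b.frame:
        raise FrameMismatchError(
            f"point sets are in different frames: '{a.frame}' vs '{b.frame}'"
        )
    d2 = np.sum((a.points - b.points) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def random_rigid_transform(
    rng: np.random.Generator,
    max_rotation_deg: float = 180.0,
    max_translation_mm: float = 100.0,
    source_frame: str = "source",
    target_frame: str = "target",
) -> RigidTransform:
    """Draw a uniformly random rotation (angle capped) and bounded translation."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_translation_mm)
    return RigidTransform(R, t, source_frame, target_frame)


# ---------------------------------------------------------------------------
# On-disk formats: 4x4 plain-text transforms, name/x/y/z CSV point sets
# ---------------------------------------------------------------------------

def write_transform(path: str | Path, T: RigidTransform) -> None:
    """Write a 4x4 row-major whitespace-separated text file ('#' comments)."""
    path = Path(path)
    header = f"# rigid transform {T.source_frame} -> {T.target_frame} (mm)\n"
    rows = "\n".join(
        " ".join(f"{v:.17g}" for v in row) for row in T.matrix
    )
    path.write_text(header + rows + "\n")


def read_transform(
    path: str | Path, source_frame: str = "source", target_frame: str = "target"
) -> RigidTransform:
    values: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values.extend(float(v) for v in line.split())
    M = np.asarray(values, dtype=float).reshape(4, 4)
    return RigidTransform(M[:3, :3], M[:3, 3], source_frame, target_frame)


def write_pointset_csv(path: str | Path, ps: PointSet) -> None:
    names = ps.names or tuple(f"p{i}" for i in range(len(ps)))
    df = pd.DataFrame(
        {"name": names, "x": ps.points[:, 0], "y": ps.points[:, 1],
         "z": ps.points[:, 2]}
    )
    df.to_csv(path, index=False)


def read_pointset_csv(path: str | Path, frame: str = "unknown") -> PointSet:
    df = pd.read_csv(path)
    return PointSet(
        df[["x", "y", "z"]].to_numpy(dtype=float), frame=frame,
        names=tuple(str(n) for n in df["name"]),
    )
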