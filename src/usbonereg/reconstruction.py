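"""Freehand 3D reconstruction of the segmented bone surface.

Every masked pixel of a tracked sweep is pushed through the image
calibration and the per-frame probe pose into the reference frame,
yielding an intraoperative surface point cloud.  The cloud is also binned
into an occupancy voxel grid so detached blobs (outlier frames, spurious
detections) can be removed by 26-connected component analysis — the
automated counterpart of manually keeping the biggest reconstructed
volume.  A speed-of-sound scale operator models (and corrects) the depth
miscalibration that arises when the scanner assumes a sound speed
different from the tissue's.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import (
    ImageCalibration,
    pixel_to_plane_mm,
    read_calibration_json,
    read_pose_csv,
    write_calibration_json,
    write_pose_csv,
)
from .rigid_geometry import FrameMismatchError, RigidTransform, compose

__all__ = [
    "TrackedFrame",
    "SweepRecording",
    "SurfaceModel",
    "OccupancyGrid",
    "EmptyReconstructionError",
    "pixel_to_reference",
    "reconstruct_surface",
    "largest_volume_component",
    "apply_sound_speed_scale",
    "voxelize_and_threshold",
    "point_mesh_distance",
    "load_mesh",
    "save_mesh",
    "save_sweep",
    "load_sweep",
]


class EmptyReconstructionError(RuntimeError):
    """All segmentation masks were empty; no surface to reconstruct."""


@dataclasses.dataclass(frozen=True)
class TrackedFrame:
    """One 2D B-mode frame with its probe->reference pose and timestamp (s)."""

    image: np.ndarray
    pose: RigidTransform
    timestamp: float

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("frame image must be 2D")
        object.__setattr__(self, "image", img)


@dataclasses.dataclass(frozen=True)
class SweepRecording:
    """Ordered tracked frames plus the image calibration of the probe."""

    frames: tuple[TrackedFrame, ...]
    calibration: ImageCalibration

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 1:
            raise ValueError("sweep must contain at least one frame")
        ts = np.array([f.timestamp for f in frames])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.calibration.spacing_axial, self.calibration.spacing_lateral)


@dataclasses.dataclass(frozen=True)
class SurfaceModel:
    """A bone surface: point cloud (N,3 mm) and optionally triangle faces."""

    points: np.ndarray
    faces: np.ndarray | None = None
    frame: str = "unknown"

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite surface coordinates")
        object.__setattr__(self, "points", p)
        if self.faces is not None:
            f = np.asarray(self.faces, dtype=int).reshape(-1, 3)
            if f.size and (f.min() < 0 or f.max() >= p.shape[0]):
                raise ValueError("faces index out-of-range vertices")
            object.__setattr__(self, "faces", f)

    def __len__(self) -> int:
        return self.points.shape[0]

    def as_trimesh(self):
        import trimesh

        if self.faces is None:
            raise ValueError("surface model is a point cloud, not a mesh")
        return trimesh.Trimesh(vertices=self.points, faces=self.faces,
                               process=False)


@dataclasses.dataclass(frozen=True)
class OccupancyGrid:
    """Boolean voxel grid: ``occupied[i,j,k]`` covers ``origin + voxel*(i,j,k)``."""

    occupied: np.ndarray
    origin: np.ndarray
    voxel_mm: float

    def voxel_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices of (N,3) mm points."""
        return np.floor((points - self.origin) / self.voxel_mm).astype(int)


def pixel_to_reference(
    pixel: tuple[float, float],
    frame_pose: RigidTransform,
    calib: ImageCalibration,
) -> np.ndarray:
    """Map one pixel through calibration and pose into the reference frame."""
    T = compose(frame_pose, calib.image_to_probe)
    plane = pixel_to_plane_mm(
        np.asarray(pixel, dtype=float)[None, :],
        calib.spacing_axial, calib.spacing_lateral,
    )
    return T.apply(plane)[0]


def reconstruct_surface(
    sweep: SweepRecording,
    masks: Sequence,
    voxel_mm: float = 1.0,
) -> tuple[SurfaceModel, OccupancyGrid]:
    """Map all masked pixels to the reference frame; bin into a voxel grid.

    Returns the raw point cloud (one point per mask pixel, frame order
    preserved) and its occupancy grid, fitted to the cloud with a
    one-voxel margin.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    if len(masks) != len(sweep):
        raise ValueError(
            f"{len(masks)} masks for {len(sweep)} frames"
        )
    calib = sweep.calibration
    chunks = []
    for tf, fm in zip(sweep.frames, masks):
        mask = fm.mask if hasattr(fm, "mask") else np.asarray(fm, dtype=bool)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        pixels = np.column_stack([cols, rows]).astype(float)  # (u, v)
        plane = pixel_to_plane_mm(pixels, calib.spacing_axial,
                                  calib.spacing_lateral)
        T = compose(tf.pose, calib.image_to_probe)
        chunks.append(T.apply(plane))
    if not chunks:
        raise EmptyReconstructionError("all segmentation masks are empty")
    cloud = np.vstack(chunks)
    frame_label = sweep.frames[0].pose.target_frame

    origin = cloud.min(axis=0) - voxel_mm
    extent = cloud.max(axis=0) + voxel_mm
    shape = np.ceil((extent - origin) / voxel_mm).astype(int) + 1
    grid = np.zeros(shape, dtype=bool)
    idx = np.floor((cloud - origin) / voxel_mm).astype(int)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return (
        SurfaceModel(points=cloud, frame=frame_label),
        OccupancyGrid(occupied=grid, origin=origin, voxel_mm=voxel_mm),
    )


def largest_volume_component(
    volume: OccupancyGrid, cloud: SurfaceModel
) -> SurfaceModel:
    """Keep cloud points whose voxel lies in the largest 26-connected blob.

    Ties on voxel count are broken by (1) the component containing the most
    cloud points, then (2) the component whose cloud centroid has the
    smallest z coordinate.
    """
    if not volume.occupied.any():
        raise ValueError("occupancy grid is empty")
    labels, n = ndimage.label(volume.occupied, structure=np.ones((3, 3, 3)))
    if n <= 1:
        return cloud
    idx = volume.voxel_of(cloud.points)
    point_labels = labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    voxel_counts = np.bincount(labels.ravel(), minlength=n + 1)
    best_lab, best_key = None, None
    for lab in range(1, n + 1):
        in_comp = point_labels == lab
        n_points = int(in_comp.sum())
        centroid_z = (
            float(cloud.points[in_comp, 2].mean()) if n_points else np.inf
        )
        key = (-int(voxel_counts[lab]), -n_points, centroid_z)
        if best_key is None or key < best_key:
            best_key, best_lab = key, lab
    return SurfaceModel(
        points=cloud.points[point_labels == best_lab], frame=cloud.frame
    )


def apply_sound_speed_scale(
    sweep: SweepRecording, c_assumed: float, c_true: float
) -> SweepRecording:
    """Rescale the axial spacing by ``c_true / c_assumed``.

    The scanner converts echo time to depth with an assumed sound speed; if
    the tissue's true speed differs, every depth is off by the ratio.  The
    same operator both injects the artifact in simulation and corrects it
    in the pipeline (pass the speeds the scanner should have used).
    """
    if c_assumed <= 0 or c_true <= 0:
        raise ValueError("sound speeds must be positive")
    scale = c_true / c_assumed
    return SweepRecording(
        frames=sweep.frames,
        calibration=sweep.calibration.with_axial_spacing(
            sweep.calibration.spacing_axial * scale
        ),
    )


def voxelize_and_threshold(
    mesh: SurfaceModel,
    voxel_mm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    threshold: float | None = None,
) -> tuple[np.ndarray, SurfaceModel]:
    """Render a synthetic CT of a closed mesh and re-extract its surface.

    The mesh interior is rasterised at ``voxel_mm`` (interior intensity
    100, background 0), Gaussian intensity noise of ``noise_sd`` is added,
    the volume is thresholded at the midpoint (or ``threshold``), the
    largest component kept, and the boundary voxel centres returned as the
    preoperative surface model — emulating a threshold-segmented CT.
    """
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("mesh is not closed; cannot voxelize an open surface")
    vox = tm.voxelized(pitch=voxel_mm).fill()
    grid = vox.matrix.astype(float) * 100.0
    origin = np.asarray(vox.translation, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
    thr = 50.0 if threshold is None else float(threshold)
    seg = grid > thr
    if not seg.any():
        raise ValueError(
            f"threshold {thr} is above the maximum intensity; empty segmentation"
        )
    labels, n = ndimage.label(seg, structure=np.ones((3, 3, 3)))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        seg = labels == (1 + int(np.argmax(counts)))
    eroded = ndimage.binary_erosion(seg)
    boundary = seg & ~eroded
    centers = np.argwhere(boundary) * voxel_mm + origin
    return grid, SurfaceModel(points=centers, frame=mesh.frame)


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances between paired points p[i] and triangles tri[i]."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def setc(mask, value):
        m = mask & ~done
        closest[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    setc((d1 <= 0) & (d2 <= 0), a)                      # vertex a
    setc((d3 >= 0) & (d4 <= d3), b)                     # vertex b
    setc((d6 >= 0) & (d5 <= d6), c)                     # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    setc((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    setc((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    setc((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
         b + w_bc[:, None] * (c - b))                                # edge bc
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    setc(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return np.linalg.norm(p - closest, axis=1)


def point_mesh_distance(
    points: np.ndarray, mesh: SurfaceModel, k_candidates: int = 48
) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface (mm).

    Candidate triangles are pre-selected by a KD-tree over triangle
    centroids, then scored with the exact point-triangle distance; the
    candidate count is generous relative to triangle size so the true
    nearest face is retained.
    """
    from scipy.spatial import cKDTree

    if mesh.faces is None:
        raise ValueError("point_mesh_distance needs a triangle mesh")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.points[mesh.faces]                       # (F, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(k_candidates, tri.shape[0])
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)
    best = np.full(pts.shape[0], np.inf)
    for j in range(cand.shape[1]):
        d = _point_triangle_distance(pts, tri[cand[:, j]])
        best = np.minimum(best, d)
    return best


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mesh(path: str | Path, frame: str = "ct") -> SurfaceModel:
    """Read an STL/PLY mesh (or PLY point cloud) via trimesh."""
    import trimesh

    obj = trimesh.load(str(path), process=False)
    if isinstance(obj, trimesh.points.PointCloud):
        return SurfaceModel(points=np.asarray(obj.vertices), frame=frame)
    return SurfaceModel(
        points=np.asarray(obj.vertices), faces=np.asarray(obj.faces),
        frame=frame,
    )


def save_mesh(path: str | Path, model: SurfaceModel) -> None:
    import trimesh

    path = str(path)
    if model.faces is not None:
        model.as_trimesh().export(path)
    else:
        trimesh.points.PointCloud(model.points).export(path)


def save_sweep(directory: str | Path, sweep: SweepRecording) -> None:
    """Write sweep as MHA frame stack + pose CSV + calibration JSON."""
    import SimpleITK as sitk

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.image for f in sweep.frames]).astype(np.float32)
    img = sitk.GetImageFromArray(stack)
    img.SetSpacing((sweep.calibration.spacing_lateral,
                    sweep.calibration.spacing_axial, 1.0))
    sitk.WriteImage(img, str(directory / "sweep.mha"))
    write_pose_csv(directory / "poses.csv",
                   [f.pose for f in sweep.frames],
                   [f.timestamp for f in sweep.frames])
    write_calibration_json(directory / "calibration.json", sweep.calibration)


def load_sweep(directory: str | Path) -> SweepRecording:
    import SimpleITK as sitk

    directory = Path(directory)
    stack = sitk.GetArrayFromImage(sitk.ReadImage(str(directory / "sweep.mha")))
    poses, timestamps = read_pose_csv(
        directory / "poses.csv", source_frame="probe", target_frame="reference"
    )
    calib = read_calibration_json(directory / "calibration.json")
    frames = tuple(
        TrackedFrame(image=stack[i], pose=poses[i], timestamp=timestamps[i])
        for i in range(stack.shape[0])
    )
    return SweepRecording(frames=frames, calibration=calib)
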