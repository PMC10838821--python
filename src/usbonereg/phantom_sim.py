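"""Synthetic phantom experiments with full ground truth.

Virtualises a cadaver-style validation study: a tibia-like bone phantom
with ten surgical targets on its surface and a sphere-shaped tumor at the
proximal end, gold-standard landmarks (screw/K-wire analogues), and a
tracked linear-probe sweep along the skin rendered as B-mode-like frames
(bright bone band, acoustic shadow, Rayleigh speckle).  Every quantity the
pipeline estimates — calibrations, poses, the bone surface, the CT-to-
reference transform — has an exact ground-truth counterpart, so each stage
and the end-to-end system can be scored without any external data.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .bone_segmentation import FrameMask
from .calibration import ImageCalibration
from .reconstruction import (
    SweepRecording,
    TrackedFrame,
    apply_sound_speed_scale,
    SurfaceModel,
)
from .rigid_geometry import PointSet, RigidTransform, compose, invert

__all__ = [
    "PhantomTruth",
    "NoiseModel",
    "EmptySweepError",
    "make_phantom",
    "simulate_sweep",
    "simulate_gold_standard",
    "simulate_pivot_poses",
    "default_image_calibration",
    "render_bmode_frame",
    "make_segmentation_dataset",
]

# desk-scale acquisition defaults: 128x128 px frames, 0.3 mm isotropic
# pixels, 200 frames per sweep
DEFAULT_FRAME_SHAPE = (128, 128)
DEFAULT_SPACING_MM = 0.3
DEFAULT_N_FRAMES = 200
_FRAME_RATE_HZ = 20.0
_BAND_SIGMA_PX = 2.0
_SHADOW_ATTENUATION = 0.2
_BAND_PEAK = 220.0


class EmptySweepError(RuntimeError):
    """The simulated probe trajectory never images the bone."""


@dataclasses.dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of one simulated phantom experiment (CT frame, mm)."""

    mesh: SurfaceModel
    targets: PointSet
    tumor_center: np.ndarray
    tumor_radius: float
    landmarks: PointSet
    T_ct_to_ref_true: RigidTransform
    seed: int


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise settings for the simulated experiment.

    Defaults describe a benign, low-noise acquisition: 0.1 mm / 0.1 deg
    optical pose jitter, no outlier frames, speckle SNR 6 (band peak over
    mean speckle), no speed-of-sound miscalibration, 0.5 mm landmark pick
    noise.  Outlier frames model transient tracking interference between
    optical reference bodies and displace a whole frame pose.

    Translational noise magnitudes (``pose_trans_sd_mm``,
    ``outlier_trans_mm``, ``landmark_pick_sd_mm``) are total 3-D RMS
    magnitudes of the error vector, not per-axis standard deviations: a
    value of 1 mm means the drawn error vector has RMS length 1 mm.
    """

    pose_rot_sd_deg: float = 0.1
    pose_trans_sd_mm: float = 0.1
    outlier_frame_fraction: float = 0.0
    outlier_trans_mm: float = 20.0
    speckle_snr: float = 6.0
    sound_speed_ratio: float = 1.0
    landmark_pick_sd_mm: float = 0.5

    def __post_init__(self) -> None:
        if min(self.pose_rot_sd_deg, self.pose_trans_sd_mm,
               self.landmark_pick_sd_mm) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.outlier_frame_fraction <= 1.0):
            raise ValueError("outlier_frame_fraction must be in [0, 1]")
        if self.sound_speed_ratio <= 0 or self.speckle_snr <= 0:
            raise ValueError("sound_speed_ratio and speckle_snr must be > 0")


ZERO_NOISE = NoiseModel(
    pose_rot_sd_deg=0.0, pose_trans_sd_mm=0.0, outlier_frame_fraction=0.0,
    speckle_snr=1e6, sound_speed_ratio=1.0, landmark_pick_sd_mm=0.0,
)


def default_image_calibration(
    spacing_axial: float = DEFAULT_SPACING_MM,
    spacing_lateral: float = DEFAULT_SPACING_MM,
) -> ImageCalibration:
    """A fixed, nontrivial image->probe transform with the given spacings."""
    R = Rotation.from_euler("x", 15, degrees=True).as_matrix()
    T = RigidTransform(R, np.array([5.0, -3.0, 2.0]), "image", "probe")
    return ImageCalibration(image_to_probe=T, spacing_axial=spacing_axial,
                            spacing_lateral=spacing_lateral)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _centerline(x: np.ndarray, length: float) -> np.ndarray:
    """Slightly bowed bone axis: y offset follows a half-sine."""
    y = 4.0 * np.sin(np.pi * x / length)
    return np.column_stack([x, y, np.zeros_like(x)])


def _radius_profile(x: np.ndarray, length: float, shaft_radius: float) -> np.ndarray:
    taper = 1.1 - 0.25 * np.sin(np.pi * x / length)     # slimmer mid-shaft
    flare = 0.9 / (1.0 + np.exp(-(x - 0.82 * length) / (0.04 * length)))
    return shaft_radius * (taper + flare)


def _loft_mesh(length: float, shaft_radius: float,
               n_axial: int = 60, n_circ: int = 36) -> trimesh.Trimesh:
    x = np.linspace(0.0, length, n_axial)
    centers = _centerline(x, length)
    radii = _radius_profile(x, length, shaft_radius)
    theta = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    ring_dirs = np.column_stack(
        [np.zeros_like(theta), np.cos(theta), np.sin(theta)]
    )
    verts = (
        centers[:, None, :] + radii[:, None, None] * ring_dirs[None, :, :]
    ).reshape(-1, 3)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps: fan around the two centreline endpoints
    verts = np.vstack([verts, centers[0], centers[-1]])
    cap0, cap1 = len(verts) - 2, len(verts) - 1
    for j in range(n_circ):
        faces.append([cap0, (j + 1) % n_circ, j])
        base = (n_axial - 1) * n_circ
        faces.append([cap1, base + j, base + (j + 1) % n_circ])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


def _farthest_point_sample(points: np.ndarray, k: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Indices of k well-spread points (greedy farthest-point sampling)."""
    n = points.shape[0]
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def make_phantom(
    seed: int,
    length_mm: float = 180.0,
    shaft_radius_mm: float = 12.0,
    n_targets: int = 10,
    n_landmarks: int = 9,
) -> PhantomTruth:
    """Build a tibia-like phantom with targets, tumor, landmarks and pose.

    The bone is a tapered, slightly bowed loft with an enlarged proximal
    end.  Ten surface targets are drawn by farthest-point sampling, the
    tumor sphere sits in the proximal metaphysis, and the ground-truth
    CT-to-reference transform has rotation <= 30 deg and translation
    <= 50 mm.  Fully deterministic per seed.
    """
    if length_mm <= 0 or shaft_radius_mm <= 0:
        raise ValueError("phantom dimensions must be positive")
    rng = np.random.default_rng(seed)
    tm = _loft_mesh(length_mm, shaft_radius_mm)
    mesh = SurfaceModel(points=np.asarray(tm.vertices),
                        faces=np.asarray(tm.faces), frame="ct")

    samples, _ = trimesh.sample.sample_surface(
        tm, 4000, seed=int(rng.integers(2**31)))
    samples = np.asarray(samples)
    targets = samples[_farthest_point_sample(samples, n_targets, rng)]

    lm_samples, _ = trimesh.sample.sample_surface(
        tm, 4000, seed=int(rng.integers(2**31)))
    lm_samples = np.asarray(lm_samples)
    landmarks = lm_samples[_farthest_point_sample(lm_samples, n_landmarks, rng)]

    tumor_center = _centerline(np.array([0.9 * length_mm]), length_mm)[0]
    tumor_radius = 15.0

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(5.0, 30.0))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(10.0, 50.0)
    T_true = RigidTransform(R, t, "ct", "reference")

    return PhantomTruth(
        mesh=mesh,
        targets=PointSet(targets, frame="ct",
                         names=tuple(f"target{i}" for i in range(n_targets))),
        tumor_center=tumor_center,
        tumor_radius=tumor_radius,
        landmarks=PointSet(landmarks, frame="ct",
                           names=tuple(f"landmark{i}" for i in range(n_landmarks))),
        T_ct_to_ref_true=T_true,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# B-mode rendering
# ---------------------------------------------------------------------------

def render_bmode_frame(
    surface_rows: np.ndarray,
    shape: tuple[int, int],
    speckle_snr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one B-mode-like frame from a per-column surface depth profile.

    ``surface_rows`` gives the (float) row of the bone interface per
    column, NaN where no bone is visible.  Rayleigh speckle fills the soft
    tissue, a Gaussian-profile bright band (sigma 2 px) marks the bone,
    and everything deeper is attenuated to 20 % (acoustic shadow).
    """
    H, W = shape
    mean_speckle = _BAND_PEAK / speckle_snr
    sigma_r = mean_speckle / np.sqrt(np.pi / 2.0)
    img = rng.rayleigh(scale=max(sigma_r, 1e-9), size=(H, W))
    rows = np.arange(H, dtype=float)[:, None]
    sr = np.asarray(surface_rows, dtype=float)[None, :]
    visible = np.isfinite(sr)
    shadow = visible & (rows > sr)
    img[shadow] *= _SHADOW_ATTENUATION
    band = np.where(
        visible,
        _BAND_PEAK * np.exp(-0.5 * ((rows - sr) / _BAND_SIGMA_PX) ** 2),
        0.0,
    )
    return np.clip(img + band, 0.0, 255.0)


def _plane_surface_rows(
    tm: trimesh.Trimesh,
    x_station: float,
    y_origin: float,
    z_top: float,
    shape: tuple[int, int],
    spacing_axial: float,
    spacing_lateral: float,
) -> np.ndarray:
    """Shallowest bone interface row per image column for one frame plane.

    The frame plane is ``x = x_station`` in the CT frame; column u maps to
    ``y = y_origin + u * spacing_lateral`` and row v to ``z = z_top -
    v * spacing_axial``.  Deeper intersections (the far cortex) are in the
    acoustic shadow and therefore not part of the visible surface.
    """
    H, W = shape
    rows = np.full(W, np.nan)
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=[1.0, 0.0, 0.0],
        plane_origin=[x_station, 0.0, 0.0],
    )
    if len(segments) == 0:
        return rows
    min_z = np.full(W, -np.inf)  # shallowest = largest z (closest to probe)
    for seg in segments:
        (y0, z0), (y1, z1) = seg[0][1:], seg[1][1:]
        u0 = (y0 - y_origin) / spacing_lateral
        u1 = (y1 - y_origin) / spacing_lateral
        if u1 < u0:
            u0, u1, z0, z1 = u1, u0, z1, z0
        lo = max(0, int(np.ceil(u0)))
        hi = min(W - 1, int(np.floor(u1)))
        if hi < lo:
            continue
        us = np.arange(lo, hi + 1)
        if abs(u1 - u0) < 1e-12:
            zs = np.full(us.shape, max(z0, z1))
        else:
            zs = z0 + (us - u0) * (z1 - z0) / (u1 - u0)
        upd = zs > min_z[us]
        min_z[us[upd]] = zs[upd]
    seen = np.isfinite(min_z) & (min_z > -np.inf)
    v = (z_top - min_z[seen]) / spacing_axial
    ok = (v >= 0) & (v <= H - 1)
    idx = np.nonzero(seen)[0][ok]
    rows[idx] = v[ok]
    return rows


def _iso_noise(rng: np.random.Generator, sd_total_mm: float,
               shape) -> np.ndarray:
    """Isotropic Gaussian noise whose total 3-D RMS magnitude is ``sd``."""
    return rng.normal(0.0, sd_total_mm / np.sqrt(3.0), size=shape)


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    if sd_deg == 0:
        return np.eye(3)
    rotvec = np.deg2rad(rng.normal(0.0, sd_deg, size=3))
    return Rotation.from_rotvec(rotvec).as_matrix()


def simulate_sweep(
    phantom: PhantomTruth,
    n_frames: int = DEFAULT_N_FRAMES,
    calib: ImageCalibration | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    sweep_span: tuple[float, float] = (0.15, 0.92),
) -> tuple[SweepRecording, list[FrameMask]]:
    """Simulate a tracked linear-probe sweep along the phantom.

    The probe slides along the bone axis imaging transverse planes.  Per
    frame: the true pose is jittered (and occasionally displaced outright,
    modelling tracking interference), the plane-mesh intersection gives
    the visible bone curve and hence the truth mask (shallowest interface
    per column, everything deeper being shadowed), and the frame is
    rendered with speckle, band and shadow.  A speed-of-sound ratio != 1
    mis-scales the *recorded* axial spacing, exactly as a scanner assuming
    the wrong sound speed would.

    Returns the recording (poses in the reference frame) and the per-frame
    ground-truth masks.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    calib = calib or default_image_calibration()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    H, W = frame_shape
    sa, sl = calib.spacing_axial, calib.spacing_lateral
    tm = phantom.mesh.as_trimesh()
    length = float(tm.vertices[:, 0].max() - tm.vertices[:, 0].min())
    x0 = float(tm.vertices[:, 0].min())
    z_top = float(tm.vertices[:, 2].max()) + 6.0
    y_mid = float(tm.vertices[:, 1].mean())
    y_origin = y_mid - (W / 2.0) * sl

    stations = x0 + np.linspace(sweep_span[0], sweep_span[1], n_frames) * length
    T_true = phantom.T_ct_to_ref_true
    calib_inv = invert(calib.image_to_probe)

    # plane basis (image-mm -> ct): e_u = +y, e_v = -z, e_w = -x
    R_plane = np.column_stack(
        [[0.0, 1.0, 0.0], [0.0, 0.0, -1.0], [-1.0, 0.0, 0.0]]
    )

    frames = []
    truth_masks = []
    any_bone = False
    outlier_flags = rng.random(n_frames) < noise.outlier_frame_fraction
    for i, x_station in enumerate(stations):
        surface_rows = _plane_surface_rows(
            tm, x_station, y_origin, z_top, (H, W), sa, sl)
        if np.isfinite(surface_rows).any():
            any_bone = True
        image = render_bmode_frame(surface_rows, (H, W), noise.speckle_snr, rng)
        tmask = np.zeros((H, W), dtype=bool)
        cols = np.nonzero(np.isfinite(surface_rows))[0]
        tmask[np.round(surface_rows[cols]).astype(int), cols] = True
        truth_masks.append(FrameMask(mask=tmask))

        placement = RigidTransform(
            R_plane, np.array([x_station, y_origin, z_top]), "image", "ct")
        pose = compose(compose(T_true, placement), calib_inv)
        # tracking error acts on the probe body: orientation jitter about
        # the probe origin plus translational jitter
        jitter_R = _small_rotation(rng, noise.pose_rot_sd_deg)
        jitter_t = _iso_noise(rng, noise.pose_trans_sd_mm, 3)
        if outlier_flags[i]:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            jitter_t = jitter_t + direction * noise.outlier_trans_mm
        jitter = RigidTransform(jitter_R, jitter_t, "probe", "probe")
        pose = compose(pose, jitter)
        frames.append(TrackedFrame(image=image, pose=pose,
                                   timestamp=i / _FRAME_RATE_HZ))
    if not any_bone:
        raise EmptySweepError("probe trajectory never intersects the bone mesh")

    sweep = SweepRecording(frames=tuple(frames), calibration=calib)
    if noise.sound_speed_ratio != 1.0:
        # scanner records depths assuming the wrong sound speed
        sweep = apply_sound_speed_scale(sweep, 1.0, noise.sound_speed_ratio)
    return sweep, truth_masks


# ---------------------------------------------------------------------------
# gold standard and calibration pose generators
# ---------------------------------------------------------------------------

def simulate_gold_standard(
    phantom: PhantomTruth,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[PointSet, PointSet]:
    """Landmark pairs as picked on the CT and on the physical phantom.

    The physical picks carry independent Gaussian noise of
    ``landmark_pick_sd_mm``; feeding the pair to the paired-point solver
    emulates the gold-standard registration and its RMS error.
    """
    noise = noise or NoiseModel()
    if len(phantom.landmarks) < 3:
        raise ValueError("need at least 3 landmarks")
    rng = np.random.default_rng(seed)
    picked_ct = phantom.landmarks
    physical = phantom.T_ct_to_ref_true.apply(picked_ct.points)
    physical = physical + _iso_noise(
        rng, noise.landmark_pick_sd_mm, physical.shape)
    return picked_ct, PointSet(physical, frame="reference",
                               names=picked_ct.names)


def simulate_pivot_poses(
    tip_offset: np.ndarray,
    pivot_point: np.ndarray,
    n: int = 50,
    trans_noise_sd_mm: float = 0.0,
    seed: int = 0,
    single_axis: bool = False,
) -> list[RigidTransform]:
    """Tool->tracker poses of a stylus pivoting about a fixed point.

    ``single_axis=True`` restricts all rotations to one axis, producing the
    rank-deficient configuration that pivot calibration must reject.
    """
    if n < 3:
        raise ValueError("need at least 3 poses")
    rng = np.random.default_rng(seed)
    tip = np.asarray(tip_offset, dtype=float)
    pivot = np.asarray(pivot_point, dtype=float)
    poses = []
    for _ in range(n):
        if single_axis:
            R = Rotation.from_rotvec(
                [0.0, 0.0, rng.uniform(0, 2 * np.pi)]).as_matrix()
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(
                axis * rng.uniform(0.2, np.pi)).as_matrix()
        t = pivot - R @ tip + rng.normal(0.0, trans_noise_sd_mm, size=3)
        poses.append(RigidTransform(R, t, "tool", "tracker"))
    return poses


# ---------------------------------------------------------------------------
# segmentation training data
# ---------------------------------------------------------------------------

def make_segmentation_dataset(
    n_frames: int = 64,
    shape: tuple[int, int] = (64, 64),
    speckle_snr: float = 6.0,
    band_halfwidth_px: int = 1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Labelled synthetic B-mode frames for training/evaluating segmenters.

    Each frame shows one smooth random bone-surface curve (sine mixture)
    rendered like the sweep frames; the label marks a ribbon of
    ``2*band_halfwidth_px + 1`` rows around the curve.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    cols = np.arange(W)
    out = []
    for _ in range(n_frames):
        base = rng.uniform(0.35, 0.7) * H
        amp1 = rng.uniform(0.0, 0.12) * H
        amp2 = rng.uniform(0.0, 0.05) * H
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        f1 = rng.uniform(0.5, 1.5)
        f2 = rng.uniform(2.0, 4.0)
        curve = (base + amp1 * np.sin(2 * np.pi * f1 * cols / W + ph1)
                 + amp2 * np.sin(2 * np.pi * f2 * cols / W + ph2))
        curve = np.clip(curve, 2, H - 3)
        frame = render_bmode_frame(curve, shape, speckle_snr, rng)
        mask = np.zeros(shape, dtype=bool)
        rows = np.arange(H)[:, None]
        mask[np.abs(rows - curve[None, :]) <= band_halfwidth_px + 0.001] = True
        out.append((frame, mask))
    return out
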