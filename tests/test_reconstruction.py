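"""Freehand surface reconstruction, component cleanup, sound-speed scaling."""

import numpy as np
import pytest
import trimesh

from usbonereg.bone_segmentation import FrameMask
from usbonereg.calibration import ImageCalibration
from usbonereg.phantom_sim import (
    ZERO_NOISE,
    default_image_calibration,
    simulate_sweep,
)
from usbonereg.reconstruction import (
    EmptyReconstructionError,
    OccupancyGrid,
    SurfaceModel,
    SweepRecording,
    TrackedFrame,
    apply_sound_speed_scale,
    largest_volume_component,
    load_mesh,
    load_sweep,
    pixel_to_reference,
    point_mesh_distance,
    reconstruct_surface,
    save_mesh,
    save_sweep,
    voxelize_and_threshold,
)
from usbonereg.rigid_geometry import (
    RigidTransform,
    compose,
    random_rigid_transform,
)


def _identity_calib(sa=1.0, sl=1.0):
    T = RigidTransform(np.eye(3), np.zeros(3), "image", "probe")
    return ImageCalibration(image_to_probe=T, spacing_axial=sa,
                            spacing_lateral=sl)


def _identity_pose(t=(0.0, 0.0, 0.0)):
    return RigidTransform(np.eye(3), np.asarray(t, float),
                          "probe", "reference")


def _single_pixel_sweep(pixel, calib=None, pose=None, shape=(16, 16)):
    calib = calib or _identity_calib()
    pose = pose or _identity_pose()
    img = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    u, v = pixel
    mask[v, u] = True
    sweep = SweepRecording(
        frames=(TrackedFrame(image=img, pose=pose, timestamp=0.0),),
        calibration=calib,
    )
    return sweep, [FrameMask(mask=mask)]


class TestPixelToReference:
    def test_identity_everything(self):
        out = pixel_to_reference((3.0, 4.0), _identity_pose(),
                                 _identity_calib())
        assert np.allclose(out, [3.0, 4.0, 0.0])

    def test_pure_translation_pose(self):
        out = pixel_to_reference((3.0, 4.0), _identity_pose((0, 0, 10)),
                                 _identity_calib())
        assert np.allclose(out, [3.0, 4.0, 10.0])

    def test_matches_explicit_matrix_product(self, rng):
        pose = random_rigid_transform(rng, source_frame="probe",
                                      target_frame="reference")
        Tc = random_rigid_transform(rng, source_frame="image",
                                    target_frame="probe")
        calib = ImageCalibration(image_to_probe=Tc, spacing_axial=0.3,
                                 spacing_lateral=0.4)
        u, v = 17.0, 42.0
        out = pixel_to_reference((u, v), pose, calib)
        h = np.array([u * 0.4, v * 0.3, 0.0, 1.0])
        expected = (pose.matrix @ Tc.matrix @ h)[:3]
        assert np.abs(out - expected).max() < 1e-9


class TestReconstructSurface:
    def test_single_pixel_cloud(self):
        sweep, masks = _single_pixel_sweep((3, 4))
        cloud, grid = reconstruct_surface(sweep, masks, voxel_mm=1.0)
        assert len(cloud) == 1
        expected = pixel_to_reference((3.0, 4.0), sweep.frames[0].pose,
                                      sweep.calibration)
        assert np.allclose(cloud.points[0], expected)
        assert grid.occupied.sum() == 1

    def test_empty_masks_raise(self):
        sweep, _ = _single_pixel_sweep((3, 4))
        with pytest.raises(EmptyReconstructionError):
            reconstruct_surface(sweep, [FrameMask(np.zeros((16, 16), bool))])

    def test_mask_count_mismatch_raises(self):
        sweep, masks = _single_pixel_sweep((3, 4))
        with pytest.raises(ValueError):
            reconstruct_surface(sweep, masks + masks)

    def test_nonpositive_voxel_raises(self):
        sweep, masks = _single_pixel_sweep((3, 4))
        with pytest.raises(ValueError):
            reconstruct_surface(sweep, masks, voxel_mm=0.0)

    def test_cloud_size_equals_mask_pixel_count(self, phantom):
        sweep, truth_masks = simulate_sweep(
            phantom, n_frames=10, noise=ZERO_NOISE, seed=4)
        cloud, _ = reconstruct_surface(sweep, truth_masks, voxel_mm=1.0)
        assert len(cloud) == sum(m.n_pixels for m in truth_masks)

    def test_noiseless_truth_masks_lie_on_mesh(self, phantom):
        # spec bound: >= 99% of points within max(voxel, spacing_axial)
        sweep, truth_masks = simulate_sweep(
            phantom, n_frames=40, noise=ZERO_NOISE, seed=4)
        cloud, _ = reconstruct_surface(sweep, truth_masks, voxel_mm=1.0)
        ref_cloud = phantom.T_ct_to_ref_true.inverse().apply(cloud.points)
        d = point_mesh_distance(ref_cloud, phantom.mesh)
        tol = max(1.0, sweep.calibration.spacing_axial)
        assert np.mean(d <= tol) >= 0.99

    def test_equivariance_under_global_motion(self, phantom, rng):
        sweep, truth_masks = simulate_sweep(
            phantom, n_frames=8, noise=ZERO_NOISE, seed=4)
        cloud, _ = reconstruct_surface(sweep, truth_masks, voxel_mm=1.0)
        G = random_rigid_transform(rng, source_frame="reference",
                                   target_frame="reference")
        moved_frames = tuple(
            TrackedFrame(image=f.image, pose=compose(G, f.pose),
                         timestamp=f.timestamp)
            for f in sweep.frames
        )
        moved = SweepRecording(frames=moved_frames,
                               calibration=sweep.calibration)
        cloud2, _ = reconstruct_surface(moved, truth_masks, voxel_mm=1.0)
        assert np.abs(cloud2.points - G.apply(cloud.points)).max() < 1e-9


class TestLargestVolumeComponent:
    def _grid_from_points(self, pts, voxel=1.0):
        model = SurfaceModel(points=pts, frame="reference")
        origin = pts.min(axis=0) - voxel
        extent = pts.max(axis=0) + voxel
        shape = np.ceil((extent - origin) / voxel).astype(int) + 1
        occ = np.zeros(shape, dtype=bool)
        idx = np.floor((pts - origin) / voxel).astype(int)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return OccupancyGrid(occupied=occ, origin=origin, voxel_mm=voxel), model

    def test_detached_blob_removed(self):
        # dense connected sheet of 300 points + detached 10-point blob
        xs, ys = np.meshgrid(np.arange(20), np.arange(15))
        main = np.column_stack([
            xs.ravel(), ys.ravel(), 0.2 * xs.ravel()]).astype(float)
        blob = np.column_stack([
            np.arange(10), np.zeros(10), np.zeros(10)]) + 45.0  # 20+ mm away
        pts = np.vstack([main, blob])
        grid, cloud = self._grid_from_points(pts)
        out = largest_volume_component(grid, cloud)
        assert len(out) == 300
        assert out.points.max() < 25.0

    def test_single_component_unchanged(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        pts = np.column_stack([
            xs.ravel(), ys.ravel(), np.zeros(100)]).astype(float)
        grid, cloud = self._grid_from_points(pts)
        out = largest_volume_component(grid, cloud)
        assert out is cloud or np.array_equal(out.points, cloud.points)

    def test_equal_components_tie_breaks_to_lower_z(self):
        a = np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])       # low z
        b = np.array([[0.5, 0.5, 40.5], [1.5, 0.5, 40.5]])     # high z
        pts = np.vstack([a, b])
        grid, cloud = self._grid_from_points(pts)
        out = largest_volume_component(grid, cloud)
        assert len(out) == 2
        assert np.all(out.points[:, 2] < 10)

    def test_empty_grid_raises(self):
        grid = OccupancyGrid(occupied=np.zeros((2, 2, 2), bool),
                             origin=np.zeros(3), voxel_mm=1.0)
        with pytest.raises(ValueError):
            largest_volume_component(
                grid, SurfaceModel(points=np.zeros((1, 3))))


class TestSoundSpeedScale:
    def test_equal_speeds_identity(self):
        sweep, _ = _single_pixel_sweep((3, 4))
        out = apply_sound_speed_scale(sweep, 1540.0, 1540.0)
        assert out.calibration.spacing_axial == sweep.calibration.spacing_axial

    def test_round_trip(self):
        sweep, _ = _single_pixel_sweep((3, 4))
        out = apply_sound_speed_scale(sweep, 1540.0, 1480.0)
        back = apply_sound_speed_scale(out, 1480.0, 1540.0)
        assert abs(back.calibration.spacing_axial
                   - sweep.calibration.spacing_axial) < 1e-12

    def test_surface_at_40mm_shifts_1p6mm_shallower(self):
        # ratio 0.96 on a pixel at 40 mm depth: reconstructed point moves
        # 40 * 0.04 = 1.6 mm toward the probe
        sweep, masks = _single_pixel_sweep((0, 40), shape=(64, 64))
        cloud0, _ = reconstruct_surface(sweep, masks)
        scaled = apply_sound_speed_scale(sweep, 1.0, 0.96)
        cloud1, _ = reconstruct_surface(scaled, masks)
        shift = cloud0.points[0] - cloud1.points[0]
        assert np.allclose(shift, [0.0, 1.6, 0.0], atol=1e-9)

    def test_nonpositive_speed_raises(self):
        sweep, _ = _single_pixel_sweep((3, 4))
        with pytest.raises(ValueError):
            apply_sound_speed_scale(sweep, -1.0, 1540.0)


class TestVoxelizeAndThreshold:
    def _sphere(self, radius=20.0):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=radius)
        return SurfaceModel(points=np.asarray(tm.vertices),
                            faces=np.asarray(tm.faces), frame="ct")

    def test_sphere_surface_within_one_voxel(self):
        _, surface = voxelize_and_threshold(self._sphere(), voxel_mm=1.0)
        r = np.linalg.norm(surface.points, axis=1)
        assert np.abs(r - 20.0).max() <= 1.0 + 1e-9

    def test_threshold_above_max_raises(self):
        with pytest.raises(ValueError):
            voxelize_and_threshold(self._sphere(), voxel_mm=2.0,
                                   threshold=500.0)

    def test_open_mesh_raises(self):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
        open_model = SurfaceModel(points=np.asarray(tm.vertices),
                                  faces=np.asarray(tm.faces)[:-5], frame="ct")
        with pytest.raises(ValueError):
            voxelize_and_threshold(open_model, voxel_mm=2.0)

    def test_coarser_voxels_not_more_accurate(self):
        sphere = self._sphere()
        errs = []
        for voxel in (1.0, 2.0):
            _, surface = voxelize_and_threshold(sphere, voxel_mm=voxel)
            r = np.linalg.norm(surface.points, axis=1)
            errs.append(float(np.mean(np.abs(r - 20.0))))
        assert errs[1] >= errs[0]


class TestPointMeshDistance:
    def test_matches_brute_force_over_all_triangles(self, rng):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
        mesh = SurfaceModel(points=np.asarray(tm.vertices),
                            faces=np.asarray(tm.faces), frame="ct")
        pts = rng.uniform(-15, 15, (50, 3))
        got = point_mesh_distance(pts, mesh, k_candidates=len(mesh.faces))
        tri = mesh.points[mesh.faces]
        for i, p in enumerate(pts):
            best = np.inf
            for f in range(tri.shape[0]):
                from usbonereg.reconstruction import _point_triangle_distance
                d = _point_triangle_distance(p[None], tri[f][None])[0]
                best = min(best, d)
            assert abs(got[i] - best) < 1e-9

    def test_vertices_have_zero_distance(self):
        tm = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
        mesh = SurfaceModel(points=np.asarray(tm.vertices),
                            faces=np.asarray(tm.faces), frame="ct")
        d = point_mesh_distance(mesh.points, mesh)
        assert d.max() < 1e-9

    def test_point_cloud_input_rejected(self):
        cloud = SurfaceModel(points=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            point_mesh_distance(np.zeros((1, 3)), cloud)


class TestIO:
    def test_mesh_roundtrip_stl(self, tmp_path, phantom):
        path = tmp_path / "bone.stl"
        save_mesh(path, phantom.mesh)
        back = load_mesh(path, frame="ct")
        # STL stores float32 and may reorder; compare via distances
        d = point_mesh_distance(phantom.mesh.points, back)
        assert d.max() < 1e-4

    def test_sweep_roundtrip(self, tmp_path, phantom):
        sweep, _ = simulate_sweep(phantom, n_frames=5, seed=9)
        save_sweep(tmp_path / "sweep", sweep)
        back = load_sweep(tmp_path / "sweep")
        assert len(back) == 5
        assert abs(back.calibration.spacing_axial
                   - sweep.calibration.spacing_axial) < 1e-9
        for a, b in zip(sweep.frames, back.frames):
            assert np.abs(a.pose.matrix - b.pose.matrix).max() < 1e-9
            assert np.abs(a.image - b.image).max() < 1e-3  # float32 on disk

    def test_sweep_timestamps_must_increase(self):
        calib = _identity_calib()
        f = TrackedFrame(image=np.zeros((4, 4)), pose=_identity_pose(),
                         timestamp=0.0)
        with pytest.raises(ValueError):
            SweepRecording(frames=(f, f), calibration=calib)
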