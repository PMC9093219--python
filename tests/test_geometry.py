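"""Siddon projector: exact chord lengths, matched adjoint pair, linearity."""

import math

import numpy as np
import pytest

from cbctrec.geometry import (ConeBeamGeometry, GeometryError, ProjectionSet,
                              SiddonProjector, Volume, VolumeGrid,
                              back_project, forward_project, row_sums,
                              trace_ray)


def _axis_geometry():
    """Single view along +x with a 5x5 panel of 1 mm pixels."""
    return ConeBeamGeometry(1040.0, 570.0, np.array([0.0]), (5, 5), (1.0, 1.0))


def _dense_ray_oracle(src, dst, grid, n_samples=2_000_000):
    """Independent chord-length oracle: dense sampling locates the voxel
    transitions along the segment, bisection refines each boundary to
    ~1e-12 of the parameter, and lengths are accumulated per flat index."""
    lower = grid.lower_corner
    vox = np.asarray(grid.voxel_size)
    nx, ny, nz = grid.shape
    d = dst - src
    L = np.linalg.norm(d)

    def cell(t):
        p = src + t * d
        idx = np.floor((p - lower) / vox).astype(int)
        if np.all(idx >= 0) and np.all(idx < grid.shape):
            return (idx[0] * ny + idx[1]) * nz + idx[2]
        return -1

    ts = np.linspace(0.0, 1.0, n_samples)
    cells = np.array([cell(t) for t in ts])
    lengths: dict[int, float] = {}
    seg_start = ts[0]
    for k in range(1, n_samples):
        if cells[k] != cells[k - 1]:
            lo, hi = ts[k - 1], ts[k]
            for _ in range(60):  # bisect the boundary crossing
                mid = 0.5 * (lo + hi)
                if cell(mid) == cells[k - 1]:
                    lo = mid
                else:
                    hi = mid
            boundary = 0.5 * (lo + hi)
            if cells[k - 1] >= 0:
                lengths[cells[k - 1]] = lengths.get(cells[k - 1], 0.0) \
                    + (boundary - seg_start) * L
            seg_start = boundary
    if cells[-1] >= 0:
        lengths[cells[-1]] = lengths.get(cells[-1], 0.0) + (1.0 - seg_start) * L
    return lengths


class TestTraceRay:
    def test_miss_returns_empty(self):
        geom = _axis_geometry()
        grid = VolumeGrid((8, 8, 8), origin=(0.0, 300.0, 0.0))  # far off-axis
        ri = trace_ray(geom, grid, 0, (2, 2))
        assert ri.voxel_indices.size == 0

    def test_axis_aligned_central_ray_chord(self):
        grid = VolumeGrid((64, 64, 64))
        ri = trace_ray(_axis_geometry(), grid, 0, (2, 2))
        assert ri.voxel_indices.size == 64
        assert np.allclose(ri.lengths, 1.0, atol=1e-9)
        assert ri.total_length() == pytest.approx(64.0, abs=1e-9)

    def test_oblique_ray_matches_dense_sampling_oracle(self):
        grid = VolumeGrid((16, 16, 16))
        geom = ConeBeamGeometry.circular(
            n_views=3, detector_shape=(24, 24), detector_pixel=(5.0, 5.0))
        view, pixel = 1, (7, 15)  # off-centre: oblique in all three axes
        ri = trace_ray(geom, grid, view, pixel)
        src = geom.source_position(view)
        dst = geom.detector_pixel_positions(view)[pixel[0] * 24 + pixel[1]]
        oracle = _dense_ray_oracle(src, dst, grid, n_samples=200_000)
        got = dict(zip(ri.voxel_indices.tolist(), ri.lengths.tolist()))
        assert set(got) == set(oracle)
        for j, length in oracle.items():
            assert got[j] == pytest.approx(length, abs=1e-6)

    def test_out_of_range_indices_raise(self):
        geom = _axis_geometry()
        grid = VolumeGrid((8, 8, 8))
        with pytest.raises(IndexError):
            trace_ray(geom, grid, 5, (2, 2))
        with pytest.raises(IndexError):
            trace_ray(geom, grid, 0, (9, 2))

    def test_lengths_positive_and_bounded_by_chord(self, small_setup):
        geom, grid = small_setup
        diag = np.linalg.norm(grid.extent)
        for pixel in [(0, 0), (11, 11), (5, 20)]:
            ri = trace_ray(geom, grid, 2, pixel)
            assert np.all(ri.lengths > 0)
            assert ri.total_length() <= diag + 1e-9


class TestForwardBackProject:
    def test_zero_volume_projects_to_zero(self, small_setup):
        geom, grid = small_setup
        ps = forward_project(Volume.zeros(grid), geom)
        assert np.all(ps.frames == 0)

    def test_unit_cube_central_ray_value(self):
        grid = VolumeGrid((64, 64, 64))
        vol = Volume(grid, np.ones(grid.shape))
        ps = forward_project(vol, _axis_geometry())
        assert ps.frames[0, 2, 2] == pytest.approx(64.0, abs=1e-9)

    def test_matches_explicit_sparse_matrix_oracle(self, small_setup, rng):
        geom, grid = small_setup
        x = rng.random(grid.shape)
        ps = forward_project(Volume(grid, x), geom)
        flat = x.ravel()
        rows, cols = geom.detector_shape
        for v in range(geom.n_views):
            for r in range(0, rows, 5):
                for c in range(0, cols, 5):
                    ri = trace_ray(geom, grid, v, (r, c))
                    expect = float(flat[ri.voxel_indices] @ ri.lengths)
                    assert ps.frames[v, r, c] == pytest.approx(expect, abs=1e-9)

    def test_linearity(self, small_projector, rng):
        P = small_projector
        n = P.grid.n_voxels
        x1, x2 = rng.random(n), rng.random(n)
        lhs = P.forward_full(2.5 * x1 + x2)
        rhs = 2.5 * P.forward_full(x1) + P.forward_full(x2)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_back_project_single_ray_support(self, small_setup):
        geom, grid = small_setup
        rows, cols = geom.detector_shape
        frames = np.zeros((geom.n_views, rows, cols))
        frames[1, 10, 12] = 3.0
        vol = back_project(ProjectionSet(geom, frames), grid)
        ri = trace_ray(geom, grid, 1, (10, 12))
        expect = np.zeros(grid.n_voxels)
        expect[ri.voxel_indices] = 3.0 * ri.lengths
        np.testing.assert_allclose(vol.values.ravel(), expect, atol=1e-12)

    def test_adjointness_identity(self, rng):
        grid = VolumeGrid((32, 32, 32))
        geom = ConeBeamGeometry.circular(
            n_views=8, detector_shape=(24, 24), detector_pixel=(4.5, 4.5))
        P = SiddonProjector(geom, grid)
        x = rng.random(grid.n_voxels)
        y = rng.random(geom.n_views * 24 * 24)
        Ax = P.forward_full(x)
        ATy = P.back_full(y)
        err = abs(Ax @ y - x @ ATy) / (np.linalg.norm(Ax) * np.linalg.norm(y))
        assert err < 1e-10

    def test_rotation_symmetry_spherical_phantom(self):
        # four views at multiples of 90 degrees: the voxelized ball is
        # exactly symmetric under these rotations of the scan
        grid = VolumeGrid((32, 32, 32))
        geom = ConeBeamGeometry.circular(
            n_views=4, detector_shape=(32, 32), detector_pixel=(3.5, 3.5))
        xs = grid.voxel_centers_1d(0)
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        ball = (X**2 + Y**2 + Z**2 <= 10.0**2).astype(float)
        ps = forward_project(Volume(grid, ball), geom)
        ref = ps.frames[0]
        scale = np.abs(ref).max()
        for v in range(1, geom.n_views):
            np.testing.assert_allclose(ps.frames[v], ref, atol=1e-6 * scale)


class TestRowSums:
    def test_ray_sums_equal_projection_of_ones(self, small_setup):
        geom, grid = small_setup
        rs, vs = row_sums(geom, grid)
        ones = forward_project(Volume(grid, np.ones(grid.shape)), geom)
        np.testing.assert_allclose(rs, ones.frames, rtol=1e-12)
        assert np.all(rs >= 0) and np.all(vs >= 0)

    def test_central_ray_row_sum_is_chord(self):
        grid = VolumeGrid((64, 64, 64))
        rs, _ = row_sums(_axis_geometry(), grid)
        assert rs[0, 2, 2] == pytest.approx(64.0, abs=1e-9)

    def test_missing_ray_has_zero_row_sum(self):
        geom = _axis_geometry()
        grid = VolumeGrid((4, 4, 4))  # tiny volume, corner pixels miss
        rs, _ = row_sums(geom, grid)
        ri = trace_ray(geom, grid, 0, (0, 0))
        if ri.voxel_indices.size == 0:
            assert rs[0, 0, 0] == 0.0


class TestChordConservation:
    def test_siddon_lengths_sum_to_entry_exit_chord(self, rng):
        grid = VolumeGrid((32, 32, 32))
        geom = ConeBeamGeometry.circular(
            n_views=8, detector_shape=(24, 24), detector_pixel=(4.5, 4.5))
        lower = grid.lower_corner
        upper = lower + grid.extent
        checked = 0
        for v in range(geom.n_views):
            src = geom.source_position(v)
            pts = geom.detector_pixel_positions(v)
            for k in rng.choice(pts.shape[0], size=40, replace=False):
                ri = trace_ray(geom, grid, v, (int(k) // 24, int(k) % 24))
                if ri.voxel_indices.size == 0:
                    continue
                d = pts[k] - src
                t0, t1 = 0.0, 1.0
                for ax in range(3):
                    if d[ax] != 0:
                        ta = (lower[ax] - src[ax]) / d[ax]
                        tb = (upper[ax] - src[ax]) / d[ax]
                        ta, tb = min(ta, tb), max(ta, tb)
                        t0, t1 = max(t0, ta), min(t1, tb)
                chord = (t1 - t0) * np.linalg.norm(d)
                assert ri.total_length() == pytest.approx(chord, rel=1e-9)
                checked += 1
        assert checked > 100


class TestValidation:
    def test_geometry_invariants(self):
        with pytest.raises(GeometryError):
            ConeBeamGeometry(500.0, 570.0, np.array([0.0]), (4, 4), (1.0, 1.0))
        with pytest.raises(GeometryError):
            VolumeGrid((0, 4, 4))
        with pytest.raises(GeometryError):
            Volume(VolumeGrid((2, 2, 2)), np.full((2, 2, 2), np.nan))

    def test_truncating_detector_warns(self):
        grid = VolumeGrid((64, 64, 64))
        geom = ConeBeamGeometry.circular(
            n_views=2, detector_shape=(8, 8), detector_pixel=(1.0, 1.0))
        with pytest.warns(UserWarning, match="truncate"):
            SiddonProjector(geom, grid)
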