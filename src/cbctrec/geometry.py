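"""Circular cone-beam scan geometry and a matched Siddon projector pair.

The scan is modelled as the linear system ``y = A x`` where ``x`` holds the
linear attenuation coefficients of the object on a voxel lattice and ``y``
holds line integrals measured on a flat-panel detector, one 2-D frame per
view angle.  Each matrix entry ``a_ij`` is the exact intersection length (in
mm) of ray ``i`` with voxel ``j``, computed with Siddon's parametric
traversal.  ``A`` and its adjoint are never materialised: both directions
re-trace rays on the fly, which keeps them an exactly matched pair.

Conventions (fixed for reproducibility):

* world coordinates are in mm with the isocenter at the origin;
* the source orbits in the ``z = 0`` plane, at angle ``theta`` it sits at
  ``(D_so cos(theta), D_so sin(theta), 0)``;
* the flat panel is perpendicular to the source-isocenter line, centred on
  it unless detector offsets are given; panel axis ``u`` (columns) lies in
  the orbital plane, axis ``v`` (rows) is along ``z``;
* voxel indexing is 0-based C-order, ``j = (ix * ny + iy) * nz + iz``, with
  the grid centred on ``origin`` (default: the isocenter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ConeBeamGeometry",
    "VolumeGrid",
    "Volume",
    "ProjectionSet",
    "RayIntersection",
    "SiddonProjector",
    "MatrixProjector",
    "trace_ray",
    "forward_project",
    "back_project",
    "row_sums",
]


class GeometryError(ValueError):
    """Inconsistent scan description or grid/geometry mismatch."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular-trajectory cone-beam scan description.

    Parameters
    ----------
    dist_source_detector, dist_source_origin:
        Source-to-panel and source-to-isocenter distances in mm.
    view_angles:
        Gantry angles in radians, one per view.
    detector_shape:
        ``(rows, cols)`` of the flat panel.
    detector_pixel:
        ``(du, dv)`` pixel pitch in mm (``du`` along columns/u, ``dv`` along
        rows/v).
    detector_offset:
        ``(u0, v0)`` panel-centre offset in mm.
    """

    dist_source_detector: float
    dist_source_origin: float
    view_angles: np.ndarray
    detector_shape: tuple[int, int]
    detector_pixel: tuple[float, float]
    detector_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.dist_source_detector > self.dist_source_origin > 0:
            raise GeometryError(
                "require dist_source_detector > dist_source_origin > 0, got "
                f"{self.dist_source_detector} and {self.dist_source_origin}"
            )
        angles = np.atleast_1d(np.asarray(self.view_angles, dtype=np.float64))
        if angles.size < 1:
            raise GeometryError("need at least one view angle")
        if np.any(angles < 0) or np.any(angles >= 2 * np.pi):
            raise GeometryError("view angles must lie in [0, 2*pi)")
        object.__setattr__(self, "view_angles", angles)
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise GeometryError("detector must have at least one pixel")
        du, dv = self.detector_pixel
        if du <= 0 or dv <= 0:
            raise GeometryError("detector pixel pitch must be positive")

    @property
    def n_views(self) -> int:
        return int(self.view_angles.size)

    @classmethod
    def circular(
        cls,
        n_views: int = 32,
        dist_source_detector: float = 1040.0,
        dist_source_origin: float = 570.0,
        detector_shape: tuple[int, int] = (96, 96),
        detector_pixel: tuple[float, float] = (2.5, 2.5),
        detector_offset: tuple[float, float] = (0.0, 0.0),
    ) -> "ConeBeamGeometry":
        """Equispaced full-circle scan; distances default to a clinical
        C-arm setup (source-detector 1040 mm, source-origin 570 mm)."""
        angles = np.arange(n_views, dtype=np.float64) * (2 * np.pi / n_views)
        return cls(
            dist_source_detector,
            dist_source_origin,
            angles,
            detector_shape,
            detector_pixel,
            detector_offset,
        )

    def source_position(self, view: int) -> np.ndarray:
        th = float(self.view_angles[view])
        d = self.dist_source_origin
        return np.array([d * math.cos(th), d * math.sin(th), 0.0])

    def detector_pixel_positions(self, view: int) -> np.ndarray:
        """World coordinates of all pixel centres for one view,
        shape ``(rows*cols, 3)`` in row-major (row, col) order."""
        th = float(self.view_angles[view])
        w = np.array([math.cos(th), math.sin(th), 0.0])
        u_ax = np.array([-math.sin(th), math.cos(th), 0.0])
        v_ax = np.array([0.0, 0.0, 1.0])
        center = -(self.dist_source_detector - self.dist_source_origin) * w
        rows, cols = self.detector_shape
        du, dv = self.detector_pixel
        u0, v0 = self.detector_offset
        u = (np.arange(cols) - (cols - 1) / 2.0) * du + u0
        v = (np.arange(rows) - (rows - 1) / 2.0) * dv + v0
        vv, uu = np.meshgrid(v, u, indexing="ij")
        pts = (
            center[None, :]
            + uu.reshape(-1, 1) * u_ax[None, :]
            + vv.reshape(-1, 1) * v_ax[None, :]
        )
        return np.ascontiguousarray(pts, dtype=np.float64)


@dataclass(frozen=True)
class VolumeGrid:
    """3-D voxel lattice: shape ``(nx, ny, nz)``, voxel size in mm, and the
    mm offset of the grid centre from the isocenter."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(int(n) < 1 for n in self.shape):
            raise GeometryError(f"grid shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.voxel_size):
            raise GeometryError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths (mm)."""
        return np.asarray(self.shape, float) * np.asarray(self.voxel_size, float)

    @property
    def lower_corner(self) -> np.ndarray:
        return np.asarray(self.origin, float) - self.extent / 2.0

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        s = self.voxel_size[axis]
        return self.lower_corner[axis] + (np.arange(n) + 0.5) * s

    def bounding_radius(self) -> float:
        """Radius of the bounding sphere about the isocenter."""
        half = self.extent / 2.0
        return float(np.linalg.norm(np.abs(np.asarray(self.origin, float)) + half))


@dataclass
class Volume:
    """Attenuation values on a grid (unitless linear attenuation per voxel)."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {vals.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise GeometryError("volume values must be finite")
        self.values = vals

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "Volume":
        return cls(grid, np.zeros(grid.shape))

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy())


@dataclass
class ProjectionSet:
    """Per-view detector frames (line integrals, mm * attenuation)."""

    geometry: ConeBeamGeometry
    frames: np.ndarray  # (n_views, rows, cols)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.float64)
        rows, cols = self.geometry.detector_shape
        expect = (self.geometry.n_views, rows, cols)
        if frames.shape != expect:
            raise GeometryError(f"frames shape {frames.shape}, expected {expect}")
        if not np.all(np.isfinite(frames)):
            raise GeometryError("projection frames must be finite")
        self.frames = frames

    @property
    def n_rays(self) -> int:
        return int(self.frames.size)


@dataclass
class RayIntersection:
    """Voxels crossed by one source-to-pixel segment, with exact chord
    lengths in mm.  ``voxel_indices`` are flat C-order indices."""

    voxel_indices: np.ndarray
    lengths: np.ndarray

    def total_length(self) -> float:
        return float(self.lengths.sum())


# ---------------------------------------------------------------------------
# Siddon traversal kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trace_core(sx, sy, sz, ex, ey, ez,
                x0, y0, z0, vx, vy, vz, nx, ny, nz,
                idx_out, len_out):  # pragma: no cover - exercised via wrappers
    """Siddon traversal of the segment source->detector pixel.

    Writes flat voxel indices and chord lengths into the output buffers and
    returns the number of voxels crossed.  The segment is parametrised by
    t in [0, 1]; slab clipping yields [t0, t1] and the loop advances t to
    consecutive plane crossings, so the recorded lengths exactly partition
    the in-grid chord.
    """
    dx = ex - sx
    dy = ey - sy
    dz = ez - sz
    L = math.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= 0.0:
        return 0
    t0 = 0.0
    t1 = 1.0
    # slab clipping per axis
    if dx != 0.0:
        ta = (x0 - sx) / dx
        tb = (x0 + nx * vx - sx) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sx < x0 or sx > x0 + nx * vx:
        return 0
    if dy != 0.0:
        ta = (y0 - sy) / dy
        tb = (y0 + ny * vy - sy) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sy < y0 or sy > y0 + ny * vy:
        return 0
    if dz != 0.0:
        ta = (z0 - sz) / dz
        tb = (z0 + nz * vz - sz) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sz < z0 or sz > z0 + nz * vz:
        return 0
    span = t1 - t0
    if span <= 1e-14:
        return 0
    # entry cell (nudged inward to dodge boundary round-off)
    tm = t0 + 1e-9 * span
    ix = int(math.floor((sx + tm * dx - x0) / vx))
    iy = int(math.floor((sy + tm * dy - y0) / vy))
    iz = int(math.floor((sz + tm * dz - z0) / vz))
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1
    # next plane-crossing parameter and per-cell increment, each axis
    stepx = 0
    tx = math.inf
    dtx = math.inf
    if dx > 0.0:
        stepx = 1
        tx = (x0 + (ix + 1) * vx - sx) / dx
        dtx = vx / dx
    elif dx < 0.0:
        stepx = -1
        tx = (x0 + ix * vx - sx) / dx
        dtx = -vx / dx
    stepy = 0
    ty = math.inf
    dty = math.inf
    if dy > 0.0:
        stepy = 1
        ty = (y0 + (iy + 1) * vy - sy) / dy
        dty = vy / dy
    elif dy < 0.0:
        stepy = -1
        ty = (y0 + iy * vy - sy) / dy
        dty = -vy / dy
    stepz = 0
    tz = math.inf
    dtz = math.inf
    if dz > 0.0:
        stepz = 1
        tz = (z0 + (iz + 1) * vz - sz) / dz
        dtz = vz / dz
    elif dz < 0.0:
        stepz = -1
        tz = (z0 + iz * vz - sz) / dz
        dtz = -vz / dz

    t = t0
    n = 0
    eps = 1e-12 * span
    while True:
        tnext = tx
        if ty < tnext:
            tnext = ty
        if tz < tnext:
            tnext = tz
        if tnext > t1:
            tnext = t1
        seg = (tnext - t) * L
        if seg > 0.0:
            idx_out[n] = (ix * ny + iy) * nz + iz
            len_out[n] = seg
            n += 1
        t = tnext
        if t >= t1 - eps:
            break
        adv = t + eps
        moved = False
        if tx <= adv:
            ix += stepx
            tx += dtx
            moved = True
        if ty <= adv:
            iy += stepy
            ty += dty
            moved = True
        if tz <= adv:
            iz += stepz
            tz += dtz
            moved = True
        if not moved:
            break
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            break
    return n


@njit(cache=True)
def _forward_kernel(values, x0, y0, z0, vx, vy, vz, nx, ny, nz,
                    sx, sy, sz, pts, out):  # pragma: no cover
    cap = nx + ny + nz + 8
    idx = np.empty(cap, np.int64)
    ln = np.empty(cap, np.float64)
    for k in range(pts.shape[0]):
        n = _trace_core(sx, sy, sz, pts[k, 0], pts[k, 1], pts[k, 2],
                        x0, y0, z0, vx, vy, vz, nx, ny, nz, idx, ln)
        s = 0.0
        for m in range(n):
            s += values[idx[m]] * ln[m]
        out[k] = s


@njit(cache=True)
def _back_kernel(vol, x0, y0, z0, vx, vy, vz, nx, ny, nz,
                 sx, sy, sz, pts, weights):  # pragma: no cover
    cap = nx + ny + nz + 8
    idx = np.empty(cap, np.int64)
    ln = np.empty(cap, np.float64)
    for k in range(pts.shape[0]):
        w = weights[k]
        if w == 0.0:
            continue
        n = _trace_core(sx, sy, sz, pts[k, 0], pts[k, 1], pts[k, 2],
                        x0, y0, z0, vx, vy, vz, nx, ny, nz, idx, ln)
        for m in range(n):
            vol[idx[m]] += w * ln[m]


# ---------------------------------------------------------------------------
# projector objects
# ---------------------------------------------------------------------------

def _check_fov(geometry: ConeBeamGeometry, grid: VolumeGrid) -> None:
    r = grid.bounding_radius()
    dso = geometry.dist_source_origin
    if r >= dso:
        warnings.warn("volume bounding sphere reaches the source orbit", stacklevel=3)
        return
    proj_r = geometry.dist_source_detector * r / math.sqrt(dso * dso - r * r)
    rows, cols = geometry.detector_shape
    du, dv = geometry.detector_pixel
    u0, v0 = geometry.detector_offset
    half_u = cols * du / 2.0 - abs(u0)
    half_v = rows * dv / 2.0 - abs(v0)
    if proj_r > min(half_u, half_v):
        warnings.warn(
            "detector may truncate the volume: projected bounding-sphere radius "
            f"{proj_r:.1f} mm exceeds panel half-extent {min(half_u, half_v):.1f} mm",
            stacklevel=3,
        )


class SiddonProjector:
    """Matched forward/back projector pair for one geometry + grid.

    ``forward_view``/``back_view`` operate per view on flat ray vectors so
    iterative solvers can cycle view subsets; ``forward_full``/``back_full``
    stack all views.  Per-view ray sums (``sum_j a_ij``) and voxel sums
    (``sum_{i in view} a_ij``) are cached on first use — these are the SART
    normalisation denominators.
    """

    def __init__(self, geometry: ConeBeamGeometry, grid: VolumeGrid,
                 check_fov: bool = True):
        self.geometry = geometry
        self.grid = grid
        if check_fov:
            _check_fov(geometry, grid)
        nx, ny, nz = grid.shape
        self._dims = (nx, ny, nz)
        self._corner = tuple(grid.lower_corner)
        self._vox = grid.voxel_size
        self._src = [geometry.source_position(v) for v in range(geometry.n_views)]
        self._pts = [geometry.detector_pixel_positions(v)
                     for v in range(geometry.n_views)]
        self._ray_sums: dict[int, np.ndarray] = {}
        self._voxel_sums: dict[int, np.ndarray] = {}

    # -- per view -----------------------------------------------------------
    @property
    def n_views(self) -> int:
        return self.geometry.n_views

    @property
    def rays_per_view(self) -> int:
        rows, cols = self.geometry.detector_shape
        return rows * cols

    def forward_view(self, values: np.ndarray, view: int) -> np.ndarray:
        """A_phi x for one view; returns a flat (rows*cols,) ray vector."""
        pts = self._pts[view]
        out = np.empty(pts.shape[0])
        s = self._src[view]
        x0, y0, z0 = self._corner
        vx, vy, vz = self._vox
        nx, ny, nz = self._dims
        _forward_kernel(np.ascontiguousarray(values.ravel()),
                        x0, y0, z0, vx, vy, vz, nx, ny, nz,
                        s[0], s[1], s[2], pts, out)
        return out

    def back_view(self, ray_values: np.ndarray, view: int,
                  out: np.ndarray | None = None) -> np.ndarray:
        """Accumulate A_phi^T y into a flat volume (allocated if absent)."""
        if out is None:
            out = np.zeros(self.grid.n_voxels)
        pts = self._pts[view]
        s = self._src[view]
        x0, y0, z0 = self._corner
        vx, vy, vz = self._vox
        nx, ny, nz = self._dims
        _back_kernel(out, x0, y0, z0, vx, vy, vz, nx, ny, nz,
                     s[0], s[1], s[2], pts,
                     np.ascontiguousarray(ray_values.ravel(), dtype=np.float64))
        return out

    # -- full system --------------------------------------------------------
    def forward_full(self, values: np.ndarray) -> np.ndarray:
        """A x over all views, flat (n_views*rows*cols,)."""
        return np.concatenate(
            [self.forward_view(values, v) for v in range(self.n_views)]
        )

    def back_full(self, ray_values: np.ndarray) -> np.ndarray:
        """A^T y over all views, flat volume."""
        out = np.zeros(self.grid.n_voxels)
        per = self.rays_per_view
        for v in range(self.n_views):
            self.back_view(ray_values[v * per:(v + 1) * per], v, out)
        return out

    # -- SART normalisations ------------------------------------------------
    def ray_sums(self, view: int) -> np.ndarray:
        """sum_j a_ij per ray of one view (projection of the ones volume)."""
        if view not in self._ray_sums:
            ones = np.ones(self.grid.n_voxels)
            self._ray_sums[view] = self.forward_view(ones, view)
        return self._ray_sums[view]

    def voxel_sums(self, view: int) -> np.ndarray:
        """sum_{i in I_phi} a_ij per voxel (backprojection of unit rays)."""
        if view not in self._voxel_sums:
            ones = np.ones(self.rays_per_view)
            self._voxel_sums[view] = self.back_view(ones, view)
        return self._voxel_sums[view]


class MatrixProjector:
    """Explicit-matrix stand-in with the same interface as SiddonProjector.

    Useful for small exactly-solvable systems; ``view_slices`` partitions the
    rows of ``A`` into the per-view update subsets.
    """

    def __init__(self, A: np.ndarray, view_slices: list[slice] | None = None):
        self.A = np.asarray(A, dtype=np.float64)
        if view_slices is None:
            view_slices = [slice(i, i + 1) for i in range(self.A.shape[0])]
        self.view_slices = view_slices

    @property
    def n_views(self) -> int:
        return len(self.view_slices)

    def forward_view(self, values, view):
        return self.A[self.view_slices[view]] @ values.ravel()

    def back_view(self, ray_values, view, out=None):
        if out is None:
            out = np.zeros(self.A.shape[1])
        out += self.A[self.view_slices[view]].T @ ray_values
        return out

    def forward_full(self, values):
        return self.A @ values.ravel()

    def back_full(self, ray_values):
        return self.A.T @ ray_values

    def ray_sums(self, view):
        return self.A[self.view_slices[view]].sum(axis=1)

    def voxel_sums(self, view):
        return self.A[self.view_slices[view]].sum(axis=0)


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def trace_ray(geometry: ConeBeamGeometry, grid: VolumeGrid, view: int,
              det_pixel: tuple[int, int]) -> RayIntersection:
    """Exact Siddon intersection of one source->pixel segment with the grid."""
    if not 0 <= view < geometry.n_views:
        raise IndexError(f"view {view} out of range [0, {geometry.n_views})")
    rows, cols = geometry.detector_shape
    r, c = det_pixel
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"detector pixel {det_pixel} outside {geometry.detector_shape}")
    src = geometry.source_position(view)
    pts = geometry.detector_pixel_positions(view)
    dst = pts[r * cols + c]
    nx, ny, nz = grid.shape
    cap = nx + ny + nz + 8
    idx = np.empty(cap, np.int64)
    ln = np.empty(cap, np.float64)
    x0, y0, z0 = grid.lower_corner
    vx, vy, vz = grid.voxel_size
    n = _trace_core(src[0], src[1], src[2], dst[0], dst[1], dst[2],
                    x0, y0, z0, vx, vy, vz, nx, ny, nz, idx, ln)
    return RayIntersection(idx[:n].copy(), ln[:n].copy())


def forward_project(volume: Volume, geometry: ConeBeamGeometry) -> ProjectionSet:
    """y = A x: simulate all detector frames for one volume."""
    proj = SiddonProjector(geometry, volume.grid)
    rows, cols = geometry.detector_shape
    frames = proj.forward_full(volume.values).reshape(geometry.n_views, rows, cols)
    return ProjectionSet(geometry, frames)


def back_project(projections: ProjectionSet, grid: VolumeGrid) -> Volume:
    """A^T y with exactly the same a_ij as forward_project (matched pair)."""
    proj = SiddonProjector(projections.geometry, grid)
    vals = proj.back_full(projections.frames.ravel())
    return Volume(grid, vals.reshape(grid.shape))


def row_sums(geometry: ConeBeamGeometry, grid: VolumeGrid
             ) -> tuple[np.ndarray, np.ndarray]:
    """SART normalisation sums.

    Returns ``(ray_sums, voxel_sums)`` with shapes
    ``(n_views, rows, cols)`` — ``sum_j a_ij`` per ray — and
    ``(n_views, nx, ny, nz)`` — ``sum_{i in I_phi} a_ij`` per voxel and view.
    Rays with zero row sum miss the volume and are excluded from updates.
    """
    proj = SiddonProjector(geometry, grid)
    rows, cols = geometry.detector_shape
    rs = np.stack([proj.ray_sums(v).reshape(rows, cols)
                   for v in range(geometry.n_views)])
    vs = np.stack([proj.voxel_sums(v).reshape(grid.shape)
                   for v in range(geometry.n_views)])
    return rs, vs
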