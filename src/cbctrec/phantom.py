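"""Piecewise-constant ellipsoid phantoms and sparse-angle projection simulation.

The built-in phantom is a 3-D Shepp-Logan-style head: ten nested ellipsoids
with additive attenuation contrasts chosen so the composite values lie in
[0, 1].  Its gradient-magnitude image is nonzero only on ellipsoid surfaces,
i.e. the phantom satisfies the gradient-sparsity assumption that TV/TpV
regularisation exploits.

Projection simulation applies the Siddon forward projector, optionally
followed by a Poisson photon-counting noise model:

    I ~ Poisson(I0 * exp(-y)),   y_noisy = -ln(max(I, 1) / I0)

with I0 photons per ray.  The default is noiseless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    ConeBeamGeometry,
    ProjectionSet,
    Volume,
    VolumeGrid,
    forward_project,
)

__all__ = [
    "EllipsoidSpec",
    "SimulationConfig",
    "make_phantom",
    "shepp_logan_specs",
    "default_head_phantom",
    "simulate",
]


@dataclass(frozen=True)
class EllipsoidSpec:
    """One ellipsoid: centre/semi-axes in mm, intrinsic ZYZ-style Euler
    rotation angles in radians, and an additive attenuation contrast."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_delta: float = 1.0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def rotation(self) -> np.ndarray:
        phi, theta, psi = self.euler_angles

        def rz(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

        def ry(a):
            c, s = np.cos(a), np.sin(a)
            return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])

        return rz(phi) @ ry(theta) @ rz(psi)


@dataclass
class SimulationConfig:
    """Phantom + scan description for one simulated acquisition."""

    phantom: list[EllipsoidSpec]
    grid: VolumeGrid
    geometry: ConeBeamGeometry
    noise: float | None = None  # photons per ray for Poisson, None = noiseless
    seed: int = 0

    def __post_init__(self):
        if self.noise is not None and self.noise <= 0:
            raise ValueError("photons_per_ray must be > 0 for Poisson noise")


# Kak-Slaney 3-D head phantom geometry with the "modified" (high-contrast)
# intensities; coordinates are in the unit ball, scaled to mm by the caller.
# columns: a, b, c, x0, y0, z0, phi(deg), delta
_HEAD_TABLE = [
    (0.69, 0.92, 0.81, 0.0, 0.0, 0.0, 0.0, 1.0),
    (0.6624, 0.874, 0.78, 0.0, -0.0184, 0.0, 0.0, -0.8),
    (0.11, 0.31, 0.22, 0.22, 0.0, 0.0, -18.0, -0.2),
    (0.16, 0.41, 0.28, -0.22, 0.0, 0.0, 18.0, -0.2),
    (0.21, 0.25, 0.41, 0.0, 0.35, 0.0, 0.0, 0.1),
    (0.046, 0.046, 0.05, 0.0, 0.1, 0.0, 0.0, 0.1),
    (0.046, 0.046, 0.05, 0.0, -0.1, 0.0, 0.0, 0.1),
    (0.046, 0.023, 0.05, -0.08, -0.605, 0.0, 0.0, 0.1),
    (0.023, 0.023, 0.02, 0.0, -0.606, 0.0, 0.0, 0.1),
    (0.023, 0.046, 0.02, 0.06, -0.605, 0.0, 0.0, 0.1),
]


def shepp_logan_specs(radius_mm: float) -> list[EllipsoidSpec]:
    """Head-phantom ellipsoid list scaled so the outer skull ellipsoid's
    largest semi-axis equals ``0.92 * radius_mm``."""
    specs = []
    for a, b, c, x0, y0, z0, phi, delta in _HEAD_TABLE:
        specs.append(
            EllipsoidSpec(
                center=(x0 * radius_mm, y0 * radius_mm, z0 * radius_mm),
                semi_axes=(a * radius_mm, b * radius_mm, c * radius_mm),
                euler_angles=(np.deg2rad(phi), 0.0, 0.0),
                value_delta=delta,
            )
        )
    return specs


def default_head_phantom(grid: VolumeGrid) -> list[EllipsoidSpec]:
    """Head phantom scaled to 90% of the grid's smallest half-extent."""
    radius = 0.9 * float(min(grid.extent)) / 2.0
    return shepp_logan_specs(radius)


def make_phantom(specs: list[EllipsoidSpec], grid: VolumeGrid) -> Volume:
    """Sum ellipsoid contrasts at every voxel centre, clipped to >= 0.

    An empty spec list gives the zero volume.
    """
    vals = np.zeros(grid.shape)
    if specs:
        xs = grid.voxel_centers_1d(0)
        ys = grid.voxel_centers_1d(1)
        zs = grid.voxel_centers_1d(2)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        for spec in specs:
            R = spec.rotation()
            dx = X - spec.center[0]
            dy = Y - spec.center[1]
            dz = Z - spec.center[2]
            # body-frame coordinates: rows of R^T
            u = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
            v = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
            w = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz
            a, b, c = spec.semi_axes
            inside = (u / a) ** 2 + (v / b) ** 2 + (w / c) ** 2 <= 1.0
            vals[inside] += spec.value_delta
    np.clip(vals, 0.0, None, out=vals)
    return Volume(grid, vals)


def simulate(config: SimulationConfig) -> tuple[Volume, ProjectionSet]:
    """Simulate one sparse-angle acquisition.

    Returns the ground-truth phantom and its (optionally noisy) projections.
    Noiseless output is exactly ``forward_project(phantom)``; with Poisson
    noise the result is reproducible under ``config.seed``.
    """
    truth = make_phantom(config.phantom, config.grid)
    projections = forward_project(truth, config.geometry)
    if config.noise is not None:
        i0 = float(config.noise)
        rng = np.random.default_rng(config.seed)
        expected = i0 * np.exp(-projections.frames)
        counts = rng.poisson(expected).astype(np.float64)
        noisy = -np.log(np.maximum(counts, 1.0) / i0)
        projections = ProjectionSet(config.geometry, noisy)
    return truth, projections
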