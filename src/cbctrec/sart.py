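"""Simultaneous Algebraic Reconstruction Technique (SART).

One update processes all rays of a single view angle phi:

    x_j <- x_j + lam * c_j
    c_j = sum_{i in I_phi} mu_i a_ij / sum_{i in I_phi} a_ij
    mu_i = (y_i - [A x]_i) / sum_j a_ij

i.e. the ray residuals are normalised by the ray lengths, backprojected,
and normalised by the per-view voxel weights.  One "iteration" is one full
pass over all view angles (ascending angle order); the relaxation factor
lam decays by lam_red after every full pass.  Rays whose row sum is zero
miss the volume and are excluded.  Iterates are clamped to >= 0 after each
view update by default, consistent with attenuation being nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import ProjectionSet, SiddonProjector, Volume, VolumeGrid

__all__ = ["SartParams", "SartState", "sart_view_update", "sart_sweep",
           "sart_reconstruct"]

_ZERO_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SartParams:
    """Relaxation lam in (0, 2], per-pass decay lam_red in (0, 1], number of
    full passes, and the nonnegativity clamp flag."""

    lam: float = 1.0
    lam_red: float = 0.99
    n_iterations: int = 50
    nonneg: bool = True

    def __post_init__(self):
        if not 0 < self.lam <= 2:
            raise ValueError(f"lam must be in (0, 2], got {self.lam}")
        if not 0 < self.lam_red <= 1:
            raise ValueError(f"lam_red must be in (0, 1], got {self.lam_red}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


@dataclass
class SartState:
    """Iterate bookkeeping: current estimate, pass counter, effective
    relaxation and data residual norm ||y - A x||_2."""

    estimate: Volume
    iteration: int = 0
    current_lam: float = 1.0
    residual_norm: float = np.inf


def sart_view_update(x: np.ndarray, projector, y_view: np.ndarray, view: int,
                     lam: float, nonneg: bool = True) -> np.ndarray:
    """Apply the SART correction for one view subset I_phi, in place.

    ``x`` is the flat volume vector, ``y_view`` the measured flat ray vector
    of that view.
    """
    ray_sum = projector.ray_sums(view)
    vox_sum = projector.voxel_sums(view)
    active = ray_sum > _ZERO_SUM_TOL
    if not np.any(active):
        warnings.warn(f"all rays of view {view} miss the volume; update skipped",
                      stacklevel=2)
        return x
    residual = y_view - projector.forward_view(x, view)
    mu = np.where(active, residual / np.where(active, ray_sum, 1.0), 0.0)
    numer = projector.back_view(mu, view)
    c = np.divide(numer, vox_sum, out=np.zeros_like(numer),
                  where=vox_sum > _ZERO_SUM_TOL)
    x += lam * c
    if nonneg:
        np.maximum(x, 0.0, out=x)
    return x


def sart_sweep(x: np.ndarray, projector, frames_flat: np.ndarray, lam: float,
               nonneg: bool = True) -> np.ndarray:
    """One full pass over all views (ascending angle order), in place."""
    per = frames_flat.size // projector.n_views
    for v in range(projector.n_views):
        sart_view_update(x, projector, frames_flat[v * per:(v + 1) * per], v,
                         lam, nonneg)
    return x


def sart_reconstruct(projections: ProjectionSet, grid: VolumeGrid,
                     params: SartParams = SartParams(),
                     initial: Volume | None = None,
                     projector: SiddonProjector | None = None,
                     callback=None) -> Volume:
    """Run ``params.n_iterations`` full SART passes.

    ``callback(state)`` is invoked after every pass with a `SartState`
    (useful for residual monitoring).  Deterministic: identical inputs give
    bitwise-identical output.
    """
    if projections.n_rays == 0:
        raise ValueError("empty projection set")
    if projector is None:
        projector = SiddonProjector(projections.geometry, grid)
    x = (initial.values if initial is not None else np.zeros(grid.shape))
    x = np.ascontiguousarray(x, dtype=np.float64).ravel().copy()
    y = projections.frames.ravel()
    lam = params.lam
    for k in range(params.n_iterations):
        sart_sweep(x, projector, y, lam, params.nonneg)
        if callback is not None:
            res = float(np.linalg.norm(y - projector.forward_full(x)))
            callback(SartState(Volume(grid, x.reshape(grid.shape).copy()),
                               iteration=k + 1, current_lam=lam,
                               residual_norm=res))
        lam *= params.lam_red
    return Volume(grid, x.reshape(grid.shape))
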