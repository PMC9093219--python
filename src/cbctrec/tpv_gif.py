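"""TpV-GIF: SART reconstruction fused with a TpV prior through guided image
filtering with a linearly scheduled guidance image.

The idea: SART preserves edges but is noisy under sparse-view sampling;
TpV minimization suppresses noise and streak artifacts but can over-smooth.
The guided filter transfers the guidance image's structure to the filter
input, so blending the two reconstructions through the guidance schedule
gets both behaviours:

  1. I_initial = TpV reconstruction of the data (the initial guidance);
  2. for n = 1..N:
       f_sart^(n) = one full SART pass started from f^(n-1);
       I_guide    = I_initial * (N-n)/N + f_sart^(n) * (n/N);
       f^(n)      = guided_filter(guide=I_guide, input=f_sart^(n));
  3. return f^(N).

Early iterations are steered by the denoised TpV image; by n = N the
guidance is entirely the evolving SART image, avoiding over-smoothing and
recovering texture.  One "SART reconstruction" inside the loop is exactly
one pass over all views, so the filter acts every pass and the schedule is
meaningful; the SART relaxation keeps decaying by lam_red across outer
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, ProjectionSet, SiddonProjector, Volume, VolumeGrid
from .guided_filter import GuidedFilterParams, guided_filter_volume
from .sart import SartParams, sart_sweep
from .tpv import TpVParams, tpv_reconstruct

__all__ = ["TpvGifParams", "GuidanceState", "update_guidance",
           "tpv_gif_reconstruct"]


@dataclass(frozen=True)
class TpvGifParams:
    """Outer iteration count N plus the sub-algorithm parameter blocks.

    ``gif=None`` disables filtering (the filter becomes a pass-through),
    which degenerates the loop to SART initialised from the TpV chain.

    ``tol`` terminates the loop once the fused iterate is quasi-stationary
    (relative change of f between outer iterations below tol); 0 disables
    early termination and all N iterations run.
    """

    n_outer: int = 50
    sart: SartParams = field(default_factory=SartParams)
    tpv: TpVParams = field(default_factory=TpVParams)
    gif: GuidedFilterParams | None = field(default_factory=GuidedFilterParams)
    tol: float = 1e-3

    def __post_init__(self):
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class GuidanceState:
    """Per-outer-iteration volumes of the TpV-GIF loop."""

    initial_guidance: Volume
    current_guidance: Volume
    sart_result: Volume
    filtered: Volume
    current_estimate: Volume
    outer_index: int


def update_guidance(initial_guidance: Volume, sart_result: Volume,
                    n: int, n_total: int) -> Volume:
    """Guidance schedule: voxelwise convex combination
    I_guide = I_initial * (N-n)/N + f_sart * (n/N)."""
    if initial_guidance.grid != sart_result.grid:
        raise GeometryError("guidance volumes must share a grid")
    if not 1 <= n <= n_total:
        raise ValueError(f"outer index n={n} outside [1, N={n_total}]")
    w = n / n_total
    vals = initial_guidance.values * (1.0 - w) + sart_result.values * w
    return Volume(initial_guidance.grid, vals)


def tpv_gif_reconstruct(projections: ProjectionSet, grid: VolumeGrid,
                        params: TpvGifParams = TpvGifParams(),
                        initial_guidance: Volume | None = None,
                        f0: Volume | None = None,
                        projector: SiddonProjector | None = None,
                        callback=None) -> Volume:
    """Run the full TpV-GIF loop.

    ``initial_guidance`` may be supplied to reuse an already computed TpV
    reconstruction (it must equal ``tpv_reconstruct`` under ``params.tpv``
    for equivalent results); ``f0`` overrides the zero-volume start of the
    SART chain.  ``callback(state)`` receives a `GuidanceState` after each
    outer iteration.  Deterministic given inputs and config.
    """
    if projections.n_rays == 0:
        raise ValueError("empty projection set")
    if projector is None:
        projector = SiddonProjector(projections.geometry, grid)
    if initial_guidance is None:
        initial_guidance = tpv_reconstruct(projections, grid, params.tpv,
                                           projector=projector)
    elif initial_guidance.grid != grid:
        raise GeometryError("initial guidance grid does not match")

    y = projections.frames.ravel()
    f = (f0.copy() if f0 is not None else Volume.zeros(grid))
    n_total = params.n_outer
    lam = params.sart.lam
    for n in range(1, n_total + 1):
        flat = np.ascontiguousarray(f.values, dtype=np.float64).ravel().copy()
        sart_sweep(flat, projector, y, lam, params.sart.nonneg)
        lam *= params.sart.lam_red
        f_sart = Volume(grid, flat.reshape(grid.shape))
        guidance = update_guidance(initial_guidance, f_sart, n, n_total)
        if params.gif is not None:
            filtered = guided_filter_volume(guidance, f_sart, params.gif)
            filtered = Volume(grid, np.maximum(filtered.values, 0.0))
        else:
            filtered = f_sart
        f_prev = f
        f = filtered
        if callback is not None:
            callback(GuidanceState(initial_guidance, guidance, f_sart,
                                   filtered, f, n))
        if params.tol > 0 and n >= 2:
            denom = float(np.linalg.norm(f_prev.values))
            change = float(np.linalg.norm(f.values - f_prev.values))
            if change <= params.tol * max(denom, 1e-30):
                break
    return f
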