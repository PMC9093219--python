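"""Total p-variation (TpV) reconstruction by alternating direction
minimization with generalized p-shrinkage.

Model:  minimize G_p(z)  s.t.  z = grad(x),  y - A x = e,  ||e||_2^2 <= eps,
        x >= 0,

where G_p is the l_p quasi-norm (0 < p <= 1) of the per-voxel gradient
magnitude.  The augmented Lagrangian is split into z-, x- and e-subproblems
with multiplier ascent:

  z:  z <- S_{beta1,p}(grad(x) + lam1/beta1)                (p-shrinkage)
  x:  (beta1 grad^T grad + beta2 tau I) x =
          grad^T(beta1 z - lam1) - A^T lam2 + beta2 tau x - beta2 d,
      d = A^T(A x + e - y),  then x <- pos(x)               (FFT solve)
  e:  e <- r * min(1, sqrt(eps)/||r||),  r = y - A x        (ball projection)
  lam1 <- lam1 - eta beta1 (z - grad x)
  lam2 <- lam2 - eta beta2 (y - A x - e)

The x-subproblem linearises the data-fidelity term proximally with weight
tau >= ||A^T A|| (power-iteration estimate), which makes the linear system
diagonal in Fourier space: grad uses forward differences with periodic
boundaries, so grad^T grad is the periodic Laplacian with eigenvalue field
Lambda = sum_axis 4 sin^2(pi k / n), and J = beta1 Lambda + beta2 tau.

The generalized p-shrinkage s_{beta,p}(t) = max(t - beta^(p-2) t^(p-1), 0)
is a single-step surrogate for the exact (nonconvex) l_p proximal mapping;
it reduces to soft thresholding with threshold 1/beta at p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ProjectionSet, SiddonProjector, Volume, VolumeGrid

__all__ = [
    "TpVParams",
    "TpVState",
    "p_shrink",
    "p_shrink_signed",
    "shrink_gradient",
    "grad",
    "div",
    "laplacian_eigenvalues",
    "estimate_operator_norm",
    "tpv_reconstruct",
]


@dataclass(frozen=True)
class TpVParams:
    """ADM solver constants.

    p is the gradient-sparsity exponent (default 0.9); beta1/beta2 are the
    gradient- and data-constraint penalty weights; eta the multiplier step
    (stable for 0 < eta < (1+sqrt(5))/2); eps_data the data-fidelity ball
    size for ||e||_2^2 (0 for noiseless data); tau the proximal
    linearization weight (None = 1.1 * power-iteration estimate of
    ||A^T A||); tol an optional relative-change stopping tolerance
    (0 disables it).
    """

    p: float = 0.9
    beta1: float = 10.0
    beta2: float = 1.0
    eta: float = 1.5
    eps_data: float = 0.0
    tau: float | None = None
    n_iterations: int = 50
    tol: float = 0.0

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("beta1 and beta2 must be > 0")
        if not 0 < self.eta < (1 + np.sqrt(5)) / 2:
            raise ValueError("eta must be in (0, (1+sqrt(5))/2)")
        if self.eps_data < 0:
            raise ValueError("eps_data must be >= 0")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class TpVState:
    """All ADM iterates plus the resolved solver constants."""

    x: np.ndarray          # (nx, ny, nz)
    z: np.ndarray          # (3, nx, ny, nz)
    e: np.ndarray          # (M,)
    lam1: np.ndarray       # (3, nx, ny, nz)
    lam2: np.ndarray       # (M,)
    J: np.ndarray          # (nx, ny, nz), > 0 everywhere
    tau: float
    iteration: int = 0
    feas_grad: list = field(default_factory=list)  # ||z - grad x||
    feas_data: list = field(default_factory=list)  # ||y - A x - e||


# ---------------------------------------------------------------------------
# p-shrinkage
# ---------------------------------------------------------------------------

def p_shrink(t, beta: float, p: float):
    """Generalized p-shrinkage of nonnegative magnitudes:
    max(t - beta^(p-2) * t^(p-1), 0)."""
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("p_shrink expects nonnegative magnitudes")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.maximum(tp - beta ** (p - 2) * tp ** (p - 1), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def p_shrink_signed(x, beta: float, p: float):
    """Signed shrinkage S_{beta,p}(x) = s_{beta,p}(|x|) * sign(x)."""
    x = np.asarray(x, dtype=np.float64)
    return p_shrink(np.abs(x), beta, p) * np.sign(x)


def shrink_gradient(field3: np.ndarray, beta: float, p: float) -> np.ndarray:
    """Isotropic shrinkage of a 3-component gradient field through its
    per-voxel Euclidean magnitude (direction preserved)."""
    mag = np.sqrt(np.sum(field3 * field3, axis=0))
    shrunk = p_shrink(mag, beta, p)
    scale = np.divide(shrunk, mag, out=np.zeros_like(mag), where=mag > 0)
    return field3 * scale[None]


# ---------------------------------------------------------------------------
# gradient operators (periodic boundaries, unit voxel spacing)
# ---------------------------------------------------------------------------

def grad(x: np.ndarray) -> np.ndarray:
    """Forward differences with periodic boundaries; output (3, *x.shape)."""
    return np.stack([np.roll(x, -1, axis=a) - x for a in range(3)])


def div(z: np.ndarray) -> np.ndarray:
    """Backward-difference divergence, the negative adjoint of `grad`:
    <grad x, z> = -<x, div z> exactly."""
    return sum(z[a] - np.roll(z[a], 1, axis=a) for a in range(3))


def laplacian_eigenvalues(shape: tuple[int, int, int]) -> np.ndarray:
    """Eigenvalue field of grad^T grad under the 3-D DFT:
    sum_axis 4 sin^2(pi k / n)."""
    lams = [4 * np.sin(np.pi * np.fft.fftfreq(n)) ** 2 for n in shape]
    return (lams[0][:, None, None] + lams[1][None, :, None]
            + lams[2][None, None, :])


def solve_x_subproblem(rhs: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Solve (beta1 grad^T grad + beta2 tau I) x = rhs by 3-D FFT
    diagonalization (before the nonnegativity projection)."""
    return np.real(np.fft.ifftn(np.fft.fftn(rhs) / J))


def project_data_ball(r: np.ndarray, eps: float) -> np.ndarray:
    """Euclidean projection of r onto {e : ||e||_2^2 <= eps}."""
    if eps <= 0:
        return np.zeros_like(r)
    nrm = float(np.linalg.norm(r))
    if nrm * nrm <= eps:
        return r.copy()
    return r * (np.sqrt(eps) / nrm)


def estimate_operator_norm(projector, n_voxels: int, n_iter: int = 10,
                           seed: int = 0) -> float:
    """Power-iteration estimate of ||A^T A|| (largest eigenvalue)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n_voxels)
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = projector.back_full(projector.forward_full(v))
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 1.0
        v = w / lam
    return lam


# ---------------------------------------------------------------------------
# ADM iteration
# ---------------------------------------------------------------------------

def _init_state(grid_shape, n_rays, params: TpVParams, tau: float,
                x0: np.ndarray) -> TpVState:
    J = params.beta1 * laplacian_eigenvalues(grid_shape) + params.beta2 * tau
    if np.any(J <= 0):
        raise ValueError("FFT denominator J must be positive everywhere")
    return TpVState(
        x=x0.copy(),
        z=np.zeros((3,) + tuple(grid_shape)),
        e=np.zeros(n_rays),
        lam1=np.zeros((3,) + tuple(grid_shape)),
        lam2=np.zeros(n_rays),
        J=J,
        tau=tau,
    )


def tpv_step(state: TpVState, params: TpVParams, projector, y: np.ndarray,
             Ax: np.ndarray) -> np.ndarray:
    """One full ADM cycle (z, x, e, multipliers), mutating ``state``.

    ``Ax`` is the forward projection of the current x (reused between
    iterations); the updated A x^{k+1} is returned.
    """
    b1, b2, eta = params.beta1, params.beta2, params.eta
    # z-step: isotropic p-shrinkage
    gx = grad(state.x)
    state.z = shrink_gradient(gx + state.lam1 / b1, b1, params.p)
    # x-step: linearized data term, FFT solve, nonnegativity projection
    combined = state.lam2 + b2 * (Ax + state.e - y)  # lam2 + beta2*(Ax+e-y)
    At = projector.back_full(combined).reshape(state.x.shape)
    rhs = -div(b1 * state.z - state.lam1) - At + b2 * state.tau * state.x
    state.x = np.maximum(solve_x_subproblem(rhs, state.J), 0.0)
    Ax = projector.forward_full(state.x.ravel())
    # e-step: projection onto the data-fidelity ball
    r = y - Ax
    state.e = project_data_ball(r, params.eps_data)
    # multiplier ascent
    state.lam1 = state.lam1 - eta * b1 * (state.z - grad(state.x))
    state.lam2 = state.lam2 - eta * b2 * (r - state.e)
    state.iteration += 1
    state.feas_grad.append(float(np.linalg.norm(state.z - grad(state.x))))
    state.feas_data.append(float(np.linalg.norm(r - state.e)))
    return Ax


def tpv_reconstruct(projections: ProjectionSet, grid: VolumeGrid,
                    params: TpVParams = TpVParams(),
                    initial: Volume | None = None,
                    projector: SiddonProjector | None = None,
                    return_state: bool = False):
    """Run the TpV ADM solver for ``params.n_iterations`` cycles (or until
    the relative change of x drops below ``params.tol`` if set).

    Raises on divergence (data residual growing 10x over a 10-iteration
    window).  Returns the nonnegative `Volume` (and the final `TpVState`
    when ``return_state`` is set).
    """
    if projections.n_rays == 0:
        raise ValueError("empty projection set")
    if projector is None:
        projector = SiddonProjector(projections.geometry, grid)
    y = projections.frames.ravel()
    tau = params.tau
    if tau is None:
        tau = 1.1 * estimate_operator_norm(projector, grid.n_voxels)
    x0 = (initial.values if initial is not None else np.zeros(grid.shape))
    state = _init_state(grid.shape, y.size, params, tau,
                        np.ascontiguousarray(x0, dtype=np.float64))
    Ax = projector.forward_full(state.x.ravel())
    res_hist: list[float] = []
    for _ in range(params.n_iterations):
        x_prev = state.x
        Ax = tpv_step(state, params, projector, y, Ax)
        res = state.feas_data[-1]
        res_hist.append(res)
        # flag only genuine blow-ups: transient rises near a tiny residual
        # (multiplier oscillation at convergence) are not divergence
        if len(res_hist) > 10:
            base = min(res_hist[-11:-1])
            if base > 0 and res > 10 * base and res > res_hist[0]:
                raise RuntimeError(
                    "TpV ADM diverging: data residual grew from "
                    f"{base:.3e} to {res:.3e} within 10 iterations "
                    f"(iteration {state.iteration})"
                )
        if params.tol > 0:
            denom = max(float(np.linalg.norm(x_prev)), 1e-30)
            if float(np.linalg.norm(state.x - x_prev)) / denom < params.tol:
                break
    vol = Volume(grid, state.x)
    if return_state:
        return vol, state
    return vol
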