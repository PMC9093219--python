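"""Independently written TV (p=1) alternating-direction reconstruction.

Cross-check oracle for the TpV solver at p = 1: classical isotropic TV
with plain soft thresholding, written with its own gradient/divergence
(slicing, not roll), its own Fourier symbol (FFT of the explicit Laplacian
stencil) and its own update arithmetic, mirroring the same split
(z, x, e, multipliers) so that iterates are comparable one-to-one.
"""

import numpy as np


def _grad(x):
    g = np.zeros((3,) + x.shape)
    for a in range(3):
        idx_fwd = [slice(None)] * 3
        idx_fwd[a] = list(range(1, x.shape[a])) + [0]  # periodic shift
        g[a] = x[tuple(idx_fwd)] - x
    return g


def _div(z):
    out = np.zeros(z.shape[1:])
    for a in range(3):
        idx_bwd = [slice(None)] * 3
        idx_bwd[a] = [z.shape[1 + a] - 1] + list(range(z.shape[1 + a] - 1))
        out += z[a] - z[a][tuple(idx_bwd)]
    return out


def _laplacian_symbol(shape):
    """Fourier transform of the explicit 7-point periodic Laplacian."""
    stencil = np.zeros(shape)
    stencil[0, 0, 0] = 6.0
    for a, n in enumerate(shape):
        idx = [0, 0, 0]
        idx[a] = 1
        stencil[tuple(idx)] = -1.0
        idx[a] = n - 1
        stencil[tuple(idx)] = -1.0
    return np.real(np.fft.fftn(stencil))


def _soft_threshold_iso(v, thresh):
    mag = np.sqrt((v ** 2).sum(axis=0))
    shrunk = np.maximum(mag - thresh, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > 0, shrunk / np.where(mag > 0, mag, 1.0), 0.0)
    return v * scale[None]


def tv_admm_reconstruct(projector, y, shape, beta1, beta2, eta, tau,
                        n_iterations, eps_data=0.0):
    """Run the TV-ADM iteration and return the volume array."""
    x = np.zeros(shape)
    lam1 = np.zeros((3,) + shape)
    lam2 = np.zeros(y.size)
    e = np.zeros(y.size)
    symbol = beta1 * _laplacian_symbol(shape) + beta2 * tau
    Ax = projector.forward_full(x.ravel())
    for _ in range(n_iterations):
        z = _soft_threshold_iso(_grad(x) + lam1 / beta1, 1.0 / beta1)
        backterm = projector.back_full(
            lam2 + beta2 * (Ax + e - y)).reshape(shape)
        rhs = -_div(beta1 * z - lam1) - backterm + beta2 * tau * x
        x = np.fft.ifftn(np.fft.fftn(rhs) / symbol).real
        x = np.maximum(x, 0.0)
        Ax = projector.forward_full(x.ravel())
        r = y - Ax
        if eps_data <= 0:
            e = np.zeros_like(r)
        else:
            nrm = np.linalg.norm(r)
            e = r if nrm ** 2 <= eps_data else r * np.sqrt(eps_data) / nrm
        lam1 = lam1 - eta * beta1 * (z - _grad(x))
        lam2 = lam2 - eta * beta2 * (r - e)
    return x
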