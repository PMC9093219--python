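"""Guided image filtering, applied slice-by-slice to volumes.

The guided filter fits a local linear model Q = a*I + b in every
(2R+1)^2 window of the guide image I and averages the per-window
coefficients, so edges present in the guide are transferred to the output
while flat regions are smoothed:

    mean_I  = f_mean(I)         mean_P  = f_mean(P)
    corr_I  = f_mean(I*I)       corr_IP = f_mean(I*P)
    var_I   = corr_I - mean_I^2
    cov_IP  = corr_IP - mean_I*mean_P
    a = cov_IP / (var_I + eps)  b = mean_P - a*mean_I
    Q = f_mean(a)*I + f_mean(b)

f_mean is a box mean with windows truncated at the image border (mean over
the valid pixels only), which keeps the constant-image identity exact at
borders.  eps is meant for images on the [0, 1] intensity scale; the
default eps = 0.0016 = 0.04^2 together with window radius 4 are the values
used throughout the reconstruction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, Volume

__all__ = [
    "GuidedFilterParams",
    "box_mean",
    "guided_filter_2d",
    "guided_filter_volume",
]


@dataclass(frozen=True)
class GuidedFilterParams:
    """Window radius R (pixels) and regularisation eps (intensity^2,
    on images scaled to [0, 1])."""

    radius: int = 4
    epsilon_gif: float = 0.0016

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.epsilon_gif < 0:
            raise ValueError("epsilon must be >= 0")


def _window_sum_1d(a: np.ndarray, radius: int, axis: int) -> np.ndarray:
    """Sliding-window sum along one axis via cumulative sums (truncated
    windows at the borders)."""
    n = a.shape[axis]
    c = np.cumsum(a, axis=axis)
    c = np.concatenate([np.zeros_like(np.take(c, [0], axis=axis)), c], axis=axis)
    hi = np.minimum(np.arange(n) + radius + 1, n)
    lo = np.maximum(np.arange(n) - radius, 0)
    return np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)


def _window_counts(shape: tuple[int, int], radius: int) -> np.ndarray:
    def counts(n):
        i = np.arange(n)
        return np.minimum(i + radius, n - 1) - np.maximum(i - radius, 0) + 1

    return np.outer(counts(shape[0]), counts(shape[1])).astype(np.float64)


def box_mean(image: np.ndarray, radius: int) -> np.ndarray:
    """Mean over the (2R+1)^2 window around each pixel, truncated at the
    border (mean over valid pixels), so constants are preserved exactly."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if radius < 1:
        raise ValueError("window radius must be >= 1")
    sums = _window_sum_1d(_window_sum_1d(image, radius, 0), radius, 1)
    return sums / _window_counts(image.shape, radius)


def guided_filter_2d(guide: np.ndarray, image: np.ndarray,
                     params: GuidedFilterParams) -> np.ndarray:
    """Filter one 2-D image ``P = image`` steered by ``I = guide``."""
    guide = np.asarray(guide, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if guide.shape != image.shape:
        raise ValueError(f"guide shape {guide.shape} != input shape {image.shape}")
    if not (np.all(np.isfinite(guide)) and np.all(np.isfinite(image))):
        raise ValueError("guide and input images must be finite")
    r, eps = params.radius, params.epsilon_gif
    mean_i = box_mean(guide, r)
    mean_p = box_mean(image, r)
    corr_i = box_mean(guide * guide, r)
    corr_ip = box_mean(guide * image, r)
    var_i = corr_i - mean_i * mean_i
    cov_ip = corr_ip - mean_i * mean_p
    denom = var_i + eps
    # eps = 0 on a locally constant guide: cov is 0 there too, take a = 0
    a = np.divide(cov_ip, denom, out=np.zeros_like(cov_ip), where=denom > 0)
    b = mean_p - a * mean_i
    return box_mean(a, r) * guide + box_mean(b, r)


def guided_filter_volume(guide: Volume, image: Volume,
                         params: GuidedFilterParams, axis: int = 2,
                         normalize: bool = True) -> Volume:
    """Apply the guided filter independently to each slice along ``axis``
    (default: axial/z).

    With ``normalize=True`` the two volumes are jointly min-max scaled to
    [0, 1] before filtering and the output is rescaled back, so that the
    default eps is on its intended intensity scale regardless of the
    volumes' physical attenuation range.
    """
    if guide.grid != image.grid:
        raise GeometryError("guide and input volumes must share a grid")
    g = guide.values
    p = image.values
    if normalize:
        lo = min(g.min(), p.min())
        hi = max(g.max(), p.max())
        scale = hi - lo
        if scale <= 0:  # both volumes constant: filtering is the identity
            return image.copy()
        g = (g - lo) / scale
        p = (p - lo) / scale
    out = np.empty_like(p)
    for k in range(p.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        sl = tuple(sl)
        out[sl] = guided_filter_2d(g[sl], p[sl], params)
    if normalize:
        out = out * scale + lo
    return Volume(image.grid, out)
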