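"""Reconstruction quality metrics: RMSE, PSNR, SSIM, profile curves and
absolute-difference maps.

All three scalar metrics are computed from global volume statistics:

    MSE  = sum((xh_i - x_i)^2) / N,    RMSE = sqrt(MSE)
    PSNR = 10 log10((2^l - 1)^2 / MSE)      [dB; l = bit depth, l = 1 for
                                             images on the 0-1 range]
    SSIM = (2 mu_xh mu_x + c1)(2 cov + c2) /
           ((mu_xh^2 + mu_x^2 + c1)(var_xh + var_x + c2))

with c1 = (0.01 L)^2, c2 = (0.03 L)^2, L = 2^l - 1.  SSIM uses global
moments by default (a sliding-window variant is available behind the
``windowed`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "ProfileCurve", "rmse", "psnr", "ssim",
           "evaluate_volumes", "profile", "profile_curve", "abs_diff"]


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    psnr: float
    ssim: float
    bit_depth_l: int = 1


@dataclass
class ProfileCurve:
    """1-D line of voxel values through a slice, for reference and
    reconstruction."""

    description: str
    positions: np.ndarray
    reference: np.ndarray
    reconstruction: np.ndarray

    def __post_init__(self):
        if not (len(self.positions) == len(self.reference)
                == len(self.reconstruction)):
            raise ValueError("profile arrays must have equal lengths")


def _as_pair(recon, reference):
    a = recon.values if hasattr(recon, "values") else recon
    b = reference.values if hasattr(reference, "values") else reference
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(recon, reference) -> float:
    """Root-mean-square error over all voxels."""
    a, b = _as_pair(recon, reference)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(recon, reference, l: int = 1) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical volumes."""
    a, b = _as_pair(recon, reference)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    peak = (2.0 ** l - 1.0) ** 2
    return float(10 * np.log10(peak / mse))


def ssim(recon, reference, l: int = 1, windowed: bool = False) -> float:
    """Structural similarity index.

    Global-moment form by default; ``windowed=True`` uses the standard
    sliding-window mean SSIM (scikit-image).
    """
    a, b = _as_pair(recon, reference)
    L = 2.0 ** l - 1.0
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(a, b, data_range=L))
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mu_a = a.mean()
    mu_b = b.mean()
    var_a = a.var()
    var_b = b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def evaluate_volumes(recon, reference, l: int = 1) -> MetricsReport:
    return MetricsReport(rmse(recon, reference), psnr(recon, reference, l),
                         ssim(recon, reference, l), l)


def _extract_line(values: np.ndarray, slice_axis: int, slice_index: int,
                  line_axis: int, line_index: int) -> np.ndarray:
    """Fix slice_axis at slice_index, then fix line_axis (an axis of the
    resulting 2-D slice, 0 or 1) at line_index."""
    if not 0 <= slice_index < values.shape[slice_axis]:
        raise IndexError(f"slice index {slice_index} out of range")
    sl = np.take(values, slice_index, axis=slice_axis)
    if line_axis not in (0, 1):
        raise IndexError("line_axis must be 0 or 1 (axis within the slice)")
    if not 0 <= line_index < sl.shape[line_axis]:
        raise IndexError(f"line index {line_index} out of range")
    return np.take(sl, line_index, axis=line_axis)


def profile(volume, slice_axis: int, slice_index: int,
            line_axis: int, line_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Voxel positions and values along one line of one slice."""
    values = volume.values if hasattr(volume, "values") else np.asarray(volume)
    line = _extract_line(values, slice_axis, slice_index, line_axis, line_index)
    return np.arange(line.size), line.copy()


def profile_curve(recon, reference, slice_axis: int = 2, slice_index: int = 0,
                  line_axis: int = 0, line_index: int = 0) -> ProfileCurve:
    """Paired gray-value curve of reconstruction vs reference along a line."""
    pos, rec = profile(recon, slice_axis, slice_index, line_axis, line_index)
    _, ref = profile(reference, slice_axis, slice_index, line_axis, line_index)
    desc = (f"slice axis {slice_axis} index {slice_index}, "
            f"line axis {line_axis} index {line_index}")
    return ProfileCurve(desc, pos, ref, rec)


def abs_diff(recon, reference):
    """Voxelwise absolute difference |xh - x| (array or Volume in kind)."""
    a, b = _as_pair(recon, reference)
    d = np.abs(a - b)
    if hasattr(recon, "grid"):
        from .geometry import Volume

        return Volume(recon.grid, d)
    return d
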