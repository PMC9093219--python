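"""End-to-end comparison harness: simulate one sparse-view acquisition and
reconstruct it with every requested algorithm at a matched outer-iteration
budget, collecting RMSE/PSNR/SSIM against the ground truth."""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np

from .baselines import asd_pocs_reconstruct, sart_tv_reconstruct
from .config import RunConfig
from .geometry import ProjectionSet, SiddonProjector, Volume
from .metrics import MetricsReport, abs_diff, evaluate_volumes, profile_curve
from .phantom import simulate
from .sart import sart_reconstruct
from .tpv import TpVParams, estimate_operator_norm, tpv_reconstruct
from .tpv_gif import tpv_gif_reconstruct

__all__ = ["ComparisonResult", "run_comparison", "write_report"]


@dataclass
class ComparisonResult:
    config: RunConfig
    truth: Volume
    projections: ProjectionSet
    reconstructions: dict[str, Volume]
    metrics: dict[str, MetricsReport]

    def metrics_rows(self) -> list[list]:
        rows = [["algorithm", "RMSE", "PSNR", "SSIM"]]
        for name in self.config.algorithms:
            if name in self.metrics:
                m = self.metrics[name]
                rows.append([name, f"{m.rmse:.6f}", f"{m.psnr:.4f}",
                             f"{m.ssim:.6f}"])
        return rows


def run_comparison(config: RunConfig, projections: ProjectionSet | None = None,
                   truth: Volume | None = None, verbose: bool = False
                   ) -> ComparisonResult:
    """Run the comparison experiment defined by ``config``.

    Projections are simulated from the configured phantom unless supplied.
    The TpV reconstruction is reused as the TpV-GIF initial guidance when
    both algorithms run (they are deterministic functions of the same
    parameters).  Fully deterministic under a fixed config and seed.
    """
    if projections is None:
        truth, projections = simulate(config.simulation())
    projector = SiddonProjector(config.geometry, config.grid)
    # resolve tau once so TpV and TpV-GIF share the same solver constants
    tpv_params = config.tpv
    if tpv_params.tau is None and any(
            a in config.algorithms for a in ("tpv", "tpv-gif")):
        tau = 1.1 * estimate_operator_norm(projector, config.grid.n_voxels,
                                           seed=config.seed)
        tpv_params = TpVParams(tpv_params.p, tpv_params.beta1,
                               tpv_params.beta2, tpv_params.eta,
                               tpv_params.eps_data, tau,
                               tpv_params.n_iterations, tpv_params.tol)

    recons: dict[str, Volume] = {}
    for name in config.algorithms:
        if verbose:
            print(f"[cbctrec] reconstructing with {name} ...", flush=True)
        if name == "sart":
            recons[name] = sart_reconstruct(projections, config.grid,
                                            config.sart, projector=projector)
        elif name == "sart-tv":
            recons[name] = sart_tv_reconstruct(projections, config.grid,
                                               config.baseline,
                                               projector=projector)
        elif name == "asd-pocs":
            recons[name] = asd_pocs_reconstruct(projections, config.grid,
                                                config.baseline,
                                                projector=projector)
        elif name == "tpv":
            recons[name] = tpv_reconstruct(projections, config.grid,
                                           tpv_params, projector=projector)
        elif name == "tpv-gif":
            params = config.tpv_gif_params()
            guidance = recons.get("tpv")
            params = type(params)(params.n_outer, params.sart, tpv_params,
                                  params.gif, params.tol)
            recons[name] = tpv_gif_reconstruct(
                projections, config.grid, params,
                initial_guidance=guidance, projector=projector)
    metrics = {}
    if truth is not None:
        metrics = {name: evaluate_volumes(vol, truth)
                   for name, vol in recons.items()}
    return ComparisonResult(config, truth, projections, recons, metrics)


def write_report(result: ComparisonResult, outdir: str,
                 write_volumes: bool = True) -> str:
    """Write the metrics table, profile curves, difference maps and volumes
    plus the resolved config; returns the metrics CSV path."""
    from .config import save_config
    from .io import write_volume

    os.makedirs(outdir, exist_ok=True)
    save_config(os.path.join(outdir, "config.yaml"), result.config)
    csv_path = os.path.join(outdir, "metrics.csv")
    with open(csv_path, "w", newline="") as fh:
        csv.writer(fh).writerows(result.metrics_rows())
    if result.truth is not None:
        mid = result.config.grid.shape[2] // 2
        row = result.config.grid.shape[0] // 2
        if write_volumes:
            write_volume(os.path.join(outdir, "ground_truth.mhd"), result.truth)
        for name, vol in result.reconstructions.items():
            tag = name.replace("-", "_")
            if write_volumes:
                write_volume(os.path.join(outdir, f"recon_{tag}.mhd"), vol)
                write_volume(os.path.join(outdir, f"absdiff_{tag}.mhd"),
                             abs_diff(vol, result.truth))
            curve = profile_curve(vol, result.truth, slice_axis=2,
                                  slice_index=mid, line_axis=0,
                                  line_index=row)
            with open(os.path.join(outdir, f"profile_{tag}.csv"), "w",
                      newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["position", "reference", "reconstruction"])
                for i in range(len(curve.positions)):
                    w.writerow([int(curve.positions[i]),
                                f"{curve.reference[i]:.9g}",
                                f"{curve.reconstruction[i]:.9g}"])
    return csv_path
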