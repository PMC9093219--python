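"""Run configuration: YAML-serialisable description of one experiment.

The demo defaults reproduce the shipped sparse-view study: a 64^3 head
phantom at 1 mm voxels, 32 equispaced views on a full circle with the
clinical distances (source-detector 1040 mm, source-origin 570 mm), and
the printed algorithm parameters (SART lam=1, lam_red=0.99; ASD-POCS
alpha=0.002; SART-TV lam_TV=15; TpV p=0.9; guided filter R=4,
eps=0.0016).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .baselines import TvBaselineParams
from .geometry import ConeBeamGeometry, VolumeGrid
from .guided_filter import GuidedFilterParams
from .phantom import EllipsoidSpec, SimulationConfig, default_head_phantom
from .sart import SartParams
from .tpv import TpVParams
from .tpv_gif import TpvGifParams

__all__ = ["ALGORITHMS", "RunConfig", "default_demo_config", "load_config",
           "save_config"]

ALGORITHMS = ("sart", "sart-tv", "asd-pocs", "tpv", "tpv-gif")


@dataclass
class RunConfig:
    """Everything needed to simulate and reconstruct one dataset."""

    geometry: ConeBeamGeometry
    grid: VolumeGrid
    algorithms: tuple[str, ...] = ALGORITHMS
    n_iterations: int = 50           # matched outer-iteration budget
    sart: SartParams = field(default_factory=SartParams)
    baseline: TvBaselineParams = field(default_factory=TvBaselineParams)
    tpv: TpVParams = field(default_factory=TpVParams)
    gif: GuidedFilterParams = field(default_factory=GuidedFilterParams)
    phantom: list[EllipsoidSpec] | None = None  # None = built-in head
    noise: float | None = None
    seed: int = 0

    def __post_init__(self):
        for name in self.algorithms:
            if name not in ALGORITHMS:
                raise ValueError(
                    f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
        n = self.n_iterations
        if self.sart.n_iterations != n:
            self.sart = SartParams(self.sart.lam, self.sart.lam_red, n,
                                   self.sart.nonneg)
        if self.baseline.n_iterations != n:
            self.baseline = TvBaselineParams(
                self.baseline.lam, self.baseline.lam_red, self.baseline.alpha,
                self.baseline.lam_tv, self.baseline.n_tv_steps, n,
                self.baseline.nonneg)
        if self.tpv.n_iterations != n:
            self.tpv = TpVParams(self.tpv.p, self.tpv.beta1, self.tpv.beta2,
                                 self.tpv.eta, self.tpv.eps_data, self.tpv.tau,
                                 n, self.tpv.tol)

    def phantom_specs(self) -> list[EllipsoidSpec]:
        if self.phantom is not None:
            return self.phantom
        return default_head_phantom(self.grid)

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(self.phantom_specs(), self.grid,
                                self.geometry, self.noise, self.seed)

    def tpv_gif_params(self) -> TpvGifParams:
        return TpvGifParams(self.n_iterations, self.sart, self.tpv, self.gif)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        g = self.geometry
        return {
            "geometry": {
                "dist_source_detector": g.dist_source_detector,
                "dist_source_origin": g.dist_source_origin,
                "view_angles": [float(a) for a in g.view_angles],
                "detector_shape": list(g.detector_shape),
                "detector_pixel": list(g.detector_pixel),
                "detector_offset": list(g.detector_offset),
            },
            "grid": {
                "shape": list(self.grid.shape),
                "voxel_size": list(self.grid.voxel_size),
                "origin": list(self.grid.origin),
            },
            "algorithms": list(self.algorithms),
            "n_iterations": self.n_iterations,
            "sart": {"lam": self.sart.lam, "lam_red": self.sart.lam_red,
                     "nonneg": self.sart.nonneg},
            "baseline": {"alpha": self.baseline.alpha,
                         "lam_tv": self.baseline.lam_tv,
                         "n_tv_steps": self.baseline.n_tv_steps},
            "tpv": {"p": self.tpv.p, "beta1": self.tpv.beta1,
                    "beta2": self.tpv.beta2, "eta": self.tpv.eta,
                    "eps_data": self.tpv.eps_data, "tau": self.tpv.tau,
                    "tol": self.tpv.tol},
            "gif": {"radius": self.gif.radius,
                    "epsilon_gif": self.gif.epsilon_gif},
            "phantom": None if self.phantom is None else [
                {"center": list(s.center), "semi_axes": list(s.semi_axes),
                 "euler_angles": list(s.euler_angles),
                 "value_delta": s.value_delta} for s in self.phantom],
            "noise": self.noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        g = d["geometry"]
        geometry = ConeBeamGeometry(
            float(g["dist_source_detector"]), float(g["dist_source_origin"]),
            np.asarray(g["view_angles"], dtype=np.float64),
            tuple(int(v) for v in g["detector_shape"]),
            tuple(float(v) for v in g["detector_pixel"]),
            tuple(float(v) for v in g.get("detector_offset", (0.0, 0.0))))
        gr = d["grid"]
        grid = VolumeGrid(tuple(int(v) for v in gr["shape"]),
                          tuple(float(v) for v in gr["voxel_size"]),
                          tuple(float(v) for v in gr.get("origin", (0, 0, 0))))
        n = int(d.get("n_iterations", 50))
        s = d.get("sart", {})
        sart = SartParams(float(s.get("lam", 1.0)),
                          float(s.get("lam_red", 0.99)), n,
                          bool(s.get("nonneg", True)))
        b = d.get("baseline", {})
        baseline = TvBaselineParams(
            sart.lam, sart.lam_red, float(b.get("alpha", 0.002)),
            float(b.get("lam_tv", 15.0)), int(b.get("n_tv_steps", 20)), n,
            sart.nonneg)
        t = d.get("tpv", {})
        tau = t.get("tau")
        tpv = TpVParams(float(t.get("p", 0.9)), float(t.get("beta1", 10.0)),
                        float(t.get("beta2", 1.0)), float(t.get("eta", 1.5)),
                        float(t.get("eps_data", 0.0)),
                        None if tau is None else float(tau), n,
                        float(t.get("tol", 0.0)))
        gf = d.get("gif", {})
        gif = GuidedFilterParams(int(gf.get("radius", 4)),
                                 float(gf.get("epsilon_gif", 0.0016)))
        ph = d.get("phantom")
        phantom = None if ph is None else [
            EllipsoidSpec(tuple(e["center"]), tuple(e["semi_axes"]),
                          tuple(e.get("euler_angles", (0, 0, 0))),
                          float(e.get("value_delta", 1.0))) for e in ph]
        return cls(geometry, grid,
                   tuple(d.get("algorithms", ALGORITHMS)), n, sart, baseline,
                   tpv, gif, phantom, d.get("noise"), int(d.get("seed", 0)))


def default_demo_config(seed: int = 0, n_views: int = 32,
                        grid_side: int = 64, n_iterations: int = 100
                        ) -> RunConfig:
    """Desk-scale demo: 64^3 head phantom, 32 equispaced views, clinical
    distances, all shipped defaults.

    The detector (128x128 pixels at 2 mm pitch) is sized so its pixel
    footprint at the isocenter (~1.1 mm at magnification 1040/570) matches
    the 1 mm voxels — per-view sampling does not limit resolution — and so
    the panel covers the grid's projected bounding sphere.
    """
    geometry = ConeBeamGeometry.circular(
        n_views=n_views, detector_shape=(128, 128), detector_pixel=(2.0, 2.0))
    grid = VolumeGrid((grid_side,) * 3, (1.0, 1.0, 1.0))
    return RunConfig(geometry, grid, n_iterations=n_iterations, seed=seed)


def load_config(path: str) -> RunConfig:
    with open(path, "r") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
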