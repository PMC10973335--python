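"""Config-driven orchestration of simulations and video analyses.

A run config (YAML) holds exactly one command section among
``simulate``, ``sweep``, ``analyze_motion``, ``cardio``, ``vessels``
and ``synth``, plus an output directory and a global seed.  Every run
writes its artifacts together with a JSON manifest listing the files,
their roles and SHA-256 hashes, the config hash, the seed and the
package version, so identical configs and seeds reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .geometry import GeometryConfig, write_vtk
from .solver import (LoadSpec, MaterialParams, SimulationConfig, TensionMode,
                     run_simulation)
from .morphometrics import allometry_curve, regime_breakpoint
from .motion import PivConfig, VideoStack, fit_rigid_motion, piv_field, \
    strain_rates
from .hemodynamics import beat_stats, roi_trace, vessel_cast
from . import synthetic

log = logging.getLogger("morphoflex")

COMMANDS = ("simulate", "sweep", "analyze_motion", "cardio", "vessels",
            "synth")

#: tension-schedule presets: stepwise shell tensions of the stimulation
#: sweep, and the single blood-mode tension
ELECTRIC_TENSION_STEPS = (0.0, 0.02, 0.04, 0.06, 0.08)
BLOOD_TENSION = 0.02


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    command: str
    params: Dict[str, Any]
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        present = [c for c in COMMANDS if c in d]
        if len(present) != 1:
            raise ConfigError(
                f"config must contain exactly one command section among "
                f"{COMMANDS}, found {present}"
            )
        cmd = present[0]
        return cls(
            command=cmd,
            params=d[cmd] or {},
            out_dir=Path(d.get("out_dir", "morphoflex_out")),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class Manifest:
    config_hash: str
    seed: int
    version: str
    files: List[Dict[str, str]] = field(default_factory=list)
    failure: Optional[str] = None

    def add(self, path: Path, role: str) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files.append({"path": path.name, "role": role,
                           "sha256": digest})

    def write(self, path: Path) -> None:
        with open(path, "w") as f:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "version": self.version, "files": self.files,
                       "failure": self.failure}, f, indent=1)


def _sim_config(params: Dict[str, Any], tension: Optional[Any] = None,
                n_vesicles: Optional[int] = None) -> SimulationConfig:
    geo = GeometryConfig(**{**params.get("geometry", {}),
                            **({"n_vesicles": n_vesicles}
                               if n_vesicles is not None else {})})
    mat = MaterialParams(**params.get("material", {}))
    lp = dict(params.get("loads", {}))
    if tension is None:
        tension = lp.pop("shell_tension", 0.0)
    if np.iterable(tension):
        loads = [LoadSpec(**{**lp, "shell_tension": float(T)})
                 for T in tension]
    else:
        loads = LoadSpec(**{**lp, "shell_tension": float(tension)})
    kw = {}
    for key in ("timestep", "n_steps", "burn_in_steps"):
        if key in params:
            kw[key] = params[key]
    return SimulationConfig(geometry=geo, material=mat, loads=loads, **kw)


def _run_simulate(cfg: RunConfig, manifest: Manifest) -> None:
    params = cfg.params
    sim = _sim_config(params)
    traj = run_simulation(sim)
    csv = cfg.out_dir / "trajectory.csv"
    traj.to_csv(csv)
    manifest.add(csv, "morphometrics")
    if params.get("write_vtk", False):
        stride = int(params.get("vtk_stride", 10))
        for i in range(0, traj.n_steps, stride):
            p = cfg.out_dir / f"mesh_{i:04d}.vtk"
            write_vtk(traj.meshes[i], p)
            manifest.add(p, "mesh")
    fit = allometry_curve(traj)
    bp = regime_breakpoint(traj.times, np.abs(traj.angles_deg))
    summary = cfg.out_dir / "summary.json"
    with open(summary, "w") as f:
        json.dump({
            "final_angle_deg": float(traj.angles_deg[-1]),
            "final_diameters": traj.diameters[-1].tolist(),
            "allometry_slope": fit.slope,
            "allometry_correlation": fit.correlation,
            "breakpoint_time": bp.time,
            "slope_before": bp.slope_before,
            "slope_after": bp.slope_after,
        }, f, indent=1)
    manifest.add(summary, "summary")


def _run_sweep(cfg: RunConfig, manifest: Manifest) -> None:
    params = cfg.params
    n_list = params.get("n_vesicles", [1, 2, 3, 4, 5, 10])
    tension = params.get("tension", 0.0)
    rows = []
    for n in n_list:
        sim = _sim_config(params, tension=tension, n_vesicles=int(n))
        traj = run_simulation(sim)
        csv = cfg.out_dir / f"trajectory_n{n}.csv"
        traj.to_csv(csv)
        manifest.add(csv, "morphometrics")
        fit = allometry_curve(traj)
        rows.append({"n_vesicles": int(n),
                     "final_angle_deg": float(traj.angles_deg[-1]),
                     "final_mean_diameter": float(traj.diameters[-1].mean()),
                     "allometry_slope": fit.slope,
                     "allometry_correlation": fit.correlation})
    summary = cfg.out_dir / "sweep_summary.json"
    with open(summary, "w") as f:
        json.dump(rows, f, indent=1)
    manifest.add(summary, "summary")


def _load_stack(params: Dict[str, Any]) -> VideoStack:
    return VideoStack.from_tiff(
        params["stack"],
        frame_interval=float(params.get("frame_interval", 10.0)),
    )


def _run_analyze_motion(cfg: RunConfig, manifest: Manifest) -> None:
    params = cfg.params
    stack = _load_stack(params)
    piv_cfg = PivConfig(**params.get("piv", {}))
    rates = []
    for k in range(len(stack) - 1):
        f = piv_field(stack.frames[k], stack.frames[k + 1], piv_cfg,
                      frame_pair_interval=stack.frame_interval)
        rm = fit_rigid_motion(f)
        sr = strain_rates(f, stack.frame_interval)
        rates.append({"pair": k,
                      "rotation_deg_per_min": rm.rate_deg_per_min,
                      "linear_strain_per_min": sr.linear_rate_per_min,
                      "areal_strain_per_min": sr.areal_rate_per_min})
        csv = cfg.out_dir / f"piv_{k:04d}.csv"
        f.to_frame().to_csv(csv, index=False)
        manifest.add(csv, "displacement_field")
    out = cfg.out_dir / "motion_summary.json"
    with open(out, "w") as f:
        json.dump({
            "angle_convention": "counterclockwise-positive, y up (visual)",
            "mean_rotation_deg_per_min": float(np.mean(
                [r["rotation_deg_per_min"] for r in rates])),
            "mean_linear_strain_per_min": float(np.mean(
                [r["linear_strain_per_min"] for r in rates])),
            "pairs": rates,
        }, f, indent=1)
    manifest.add(out, "summary")


def _run_cardio(cfg: RunConfig, manifest: Manifest) -> None:
    params = cfg.params
    stack = _load_stack(params)
    trace = roi_trace(stack, tuple(params["roi"]))
    csvp = cfg.out_dir / "trace.csv"
    trace.to_csv(csvp)
    manifest.add(csvp, "trace")
    stats = beat_stats(trace)
    out = cfg.out_dir / "beats.json"
    with open(out, "w") as f:
        json.dump({"rate_bpm": stats.rate_bpm,
                   "thrust_proxy": stats.thrust_proxy,
                   "n_beats": stats.n_beats}, f, indent=1)
    manifest.add(out, "summary")


def _run_vessels(cfg: RunConfig, manifest: Manifest) -> None:
    import tifffile
    params = cfg.params
    stack = _load_stack(params)
    cast = vessel_cast(stack,
                       frame_window=int(params.get("frame_window", 300)),
                       register=bool(params.get("register", True)))
    out = cfg.out_dir / "vessel_cast.tiff"
    tifffile.imwrite(out, cast)
    manifest.add(out, "cast")


def _run_synth(cfg: RunConfig, manifest: Manifest) -> None:
    params = dict(cfg.params)
    kind = params.pop("kind")
    seed = int(params.pop("seed", cfg.seed))
    gens = {
        "rotation": synthetic.gen_rotation_video,
        "contraction": synthetic.gen_contraction_video,
        "heart": synthetic.gen_heart_video,
        "vessel": synthetic.gen_vessel_video,
    }
    if kind == "episode":
        segs = [synthetic.EpisodeSegment(**s) for s in params.pop("schedule")]
        stack, gt = synthetic.gen_stimulation_episode(segs, seed=seed,
                                                      **params)
    elif kind in gens:
        if "shape" in params:
            params["shape"] = tuple(params["shape"])
        stack, gt = gens[kind](seed=seed, **params)
    else:
        raise ConfigError(f"unknown synth kind {kind!r}")
    tif = cfg.out_dir / f"synth_{kind}.tiff"
    stack.to_tiff(tif)
    manifest.add(tif, "stack")
    gtp = cfg.out_dir / f"synth_{kind}_truth.json"
    gt.to_json(gtp)
    manifest.add(gtp, "ground_truth")


_RUNNERS = {
    "simulate": _run_simulate,
    "sweep": _run_sweep,
    "analyze_motion": _run_analyze_motion,
    "cardio": _run_cardio,
    "vessels": _run_vessels,
    "synth": _run_synth,
}


def run_pipeline(config: RunConfig) -> Manifest:
    """Validate and execute one configured stage; write the manifest."""
    if config.command not in _RUNNERS:
        raise ConfigError(f"unknown command {config.command!r}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps({"command": config.command, "params": config.params,
                    "seed": config.seed}, sort_keys=True, default=str)
        .encode()).hexdigest()
    manifest = Manifest(config_hash=cfg_hash, seed=config.seed,
                        version=__version__)
    try:
        _RUNNERS[config.command](config, manifest)
    except Exception as exc:            # record partial manifest
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.write(config.out_dir / "manifest.json")
        raise
    manifest.write(config.out_dir / "manifest.json")
    return manifest
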