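"""End-to-end orchestration: trajectories -> fitted distribution -> simulation.

The pipeline mirrors the study protocol: obtain a trajectory ensemble
(synthetic or from disk), fit the velocity distribution (mean magnitude +
power-law tail), solve the normalization constraints, then run the
device-scale deposition experiment with the fitted law.  Every run writes a
manifest recording the full parameter set and seeds, so outputs are
reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import write_distribution, write_result_csv, read_trajectories, write_trajectories
from .stochastic_sim import WalkConfig, simulate_walk
from .synthetic_data import SynthConfig, synth_trajectories
from .trajectory_analysis import (
    exclusion_filter,
    extract_velocities,
    fit_tail,
    mean_abs_velocity,
)
from .velocity_model import VelocityDistribution

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    """Provenance record written alongside every pipeline output."""

    command: str
    params: dict
    seeds: dict
    inputs: list
    outputs: list
    version: str = __version__
    timestamp: str = ""

    def write(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _validate(cfg: dict) -> None:
    for section in ("synth", "distribution"):
        params = cfg.get(section) or {}
        if "alpha" in params and params["alpha"] <= 1:
            raise PipelineError(f"validation: {section}.alpha must exceed 1")
        for key in ("v_min", "v_moy"):
            if key in params and params[key] <= 0:
                raise PipelineError(f"validation: {section}.{key} must be positive")
    if "synth" not in cfg and "input" not in cfg and "distribution" not in cfg:
        raise PipelineError(
            "validation: need a 'synth', 'input' or 'distribution' section"
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("acquire")
def _acquire(cfg: dict, seeds: dict, inputs: list):
    if "input" in cfg:
        path = cfg["input"]["trajectories"]
        inputs.append(str(path))
        return read_trajectories(path)
    s = dict(cfg["synth"])
    dist = VelocityDistribution.from_constraints(
        s.pop("alpha"), s.pop("v_min"), s.pop("v_moy")
    )
    config = SynthConfig(dist=dist, **s)
    seeds["synth"] = config.seed
    return synth_trajectories(config)


@_stage("fit")
def _fit(cfg: dict, traj) -> VelocityDistribution:
    f = dict(cfg.get("fit") or {})
    margin = f.get("margin", 1e-5)
    stride = f.get("stride", 1)
    filtered = exclusion_filter(traj, margin=margin) if margin > 0 else traj
    series, _ = extract_velocities(filtered, stride=stride)
    v_moy_hat = mean_abs_velocity(series)
    import numpy as np

    magnitudes = np.abs(np.concatenate(series))
    tail = fit_tail(magnitudes[magnitudes > 0], min_tail=f.get("min_tail", 50))
    return VelocityDistribution.from_constraints(tail.alpha_hat, tail.v_min_hat, v_moy_hat)


@_stage("simulate")
def _simulate(cfg: dict, dist, seeds: dict):
    sim = dict(cfg.get("simulate") or {})
    sim.setdefault("L", 0.82e-3)
    sim.setdefault("N", 4800)
    sim.setdefault("dt_step", 0.5e-3)
    sim.setdefault("t_end", 20.0)
    sim.setdefault("seed", 0)
    config = WalkConfig(**sim)
    seeds["simulate"] = config.seed
    _, curve = simulate_walk(config, dist, record="deposition")
    return config, curve


def run_pipeline(config, out_dir) -> dict:
    """Execute the fit -> normalize -> simulate sequence.

    ``config`` is a YAML path or a dict with sections ``synth`` (generate
    input trajectories) or ``input`` (load a TSV), optional ``distribution``
    (skip fitting and use the given alpha/v_min/v_moy), ``fit`` and
    ``simulate``.  All stage parameters and seeds are recorded in
    ``manifest.json`` in ``out_dir``.

    Returns a dict with the fitted distribution, the deposition curve and
    the paths of everything written.
    """
    cfg = _load_config(config)
    _validate(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds: dict = {}
    inputs: list = []
    outputs: list = []

    if "distribution" in cfg:
        d = cfg["distribution"]
        dist = VelocityDistribution.from_constraints(d["alpha"], d["v_min"], d["v_moy"])
        traj = None
    else:
        traj = _acquire(cfg, seeds, inputs)
        if cfg.get("write_trajectories"):
            traj_path = out_dir / "trajectories.tsv"
            write_trajectories(traj, traj_path)
            outputs.append(str(traj_path))
        dist = _fit(cfg, traj)

    dist_path = out_dir / "fitted_distribution.txt"
    write_distribution(dist, dist_path)
    outputs.append(str(dist_path))

    sim_config, curve = _simulate(cfg, dist, seeds)
    depo_path = out_dir / "deposition.csv"
    write_result_csv(
        pd.DataFrame(
            {
                "t": curve.times,
                "absorbed": curve.cumulative_absorbed,
                "survivors": curve.survivors,
            }
        ),
        depo_path,
        params={
            "L": sim_config.L,
            "N": sim_config.N,
            "dt_step": sim_config.dt_step,
            "t_end": sim_config.t_end,
            "seed": sim_config.seed,
            "bottom": sim_config.bottom,
            "top": sim_config.top,
        },
    )
    outputs.append(str(depo_path))

    manifest = RunManifest(
        command="run",
        params=cfg,
        seeds=seeds,
        inputs=inputs,
        outputs=outputs,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    return {
        "distribution": dist,
        "deposition": curve,
        "manifest": manifest_path,
        "outputs": outputs,
    }
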