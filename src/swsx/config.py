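"""YAML/JSON configuration for simulations and experiments."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .cell import UnitCell
from .experiments import ExperimentConfig
from .sim_core import WedgePlan, generate_ground_truth, make_polymorphs, simulate_wedges

__all__ = ["load_config", "simulation_from_config", "experiment_from_config"]

_SIM_KEYS = {
    "cell", "pointgroup", "d_min", "mode", "n_wedges", "wedge_deg", "frame_deg",
    "dose_total", "n0", "sigma_sys", "sigma_g", "sigma_B", "bg_rate",
    "bijvoet_ratio", "C", "B_true", "polymorphs", "seed",
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def simulation_from_config(cfg: dict):
    """Build (polymorph set, wedge list) from a structured config mapping."""
    unknown = set(cfg) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    cell = UnitCell(*cfg["cell"])
    seed = int(cfg.get("seed", 0))
    gt = generate_ground_truth(
        cell,
        str(cfg.get("pointgroup", "1")),
        float(cfg["d_min"]),
        mode=str(cfg.get("mode", "wilson")),
        params={
            "C": float(cfg.get("C", 1.0)),
            "B_true": float(cfg.get("B_true", 0.0)),
            "bijvoet_ratio": float(cfg.get("bijvoet_ratio", 0.0)),
        },
        seed=seed,
    )
    pcfg = cfg.get("polymorphs", {}) or {}
    poly = make_polymorphs(
        gt,
        int(pcfg.get("n", 1)),
        float(pcfg.get("target_cc", 1.0)),
        proportions=pcfg.get("proportions"),
        seed=seed,
    )
    plan = WedgePlan(
        wedge_deg=float(cfg.get("wedge_deg", 5.0)),
        frame_deg=float(cfg.get("frame_deg", 0.2)),
        dose_total=float(cfg.get("dose_total", 1.0e7)),
        n0=float(cfg.get("n0", 2.5e-4)),
        sigma_sys=float(cfg.get("sigma_sys", 0.03)),
        bg_rate=float(cfg.get("bg_rate", 1.0)),
    )
    wedges = simulate_wedges(
        poly,
        int(cfg.get("n_wedges", 10)),
        plan,
        seed=seed,
        sigma_g=float(cfg.get("sigma_g", 0.3)),
        sigma_b=float(cfg.get("sigma_B", 3.0)),
    )
    return poly, wedges


def experiment_from_config(cfg: dict, seed: int | None = None) -> ExperimentConfig:
    preset = cfg["preset"]
    params = {k: v for k, v in cfg.items() if k not in ("preset", "seed")}
    return ExperimentConfig(
        preset=preset, seed=int(cfg.get("seed", 0) if seed is None else seed),
        params=params,
    )
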