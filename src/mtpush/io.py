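"""Configuration files, tabular I/O, and run manifests.

The internal unit system is micrometers-seconds-piconewtons throughout
(viscosity in pN s / um^2; 1 Pa s = 1 pN s / um^2).  Units are spelled out in
every config key and file header.  Config files are YAML with nested sections
mirroring :class:`mtpush.simulator.SimConfig`; unknown keys are rejected by
name, and every loaded value is tracked as user-supplied or default.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mtpush
from mtpush.bayes import CatastropheDataset
from mtpush.mechanics import CellGeometry, DragEnvironment
from mtpush.mt_dynamics import CatastropheModel, KineticParams
from mtpush.simulator import SimConfig, Trajectory

__all__ = [
    "config_to_dict",
    "config_hash",
    "load_config",
    "load_config_detailed",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "read_xy_series",
    "read_catastrophe_dataset",
    "write_catastrophe_dataset",
    "read_offsets",
    "write_manifest",
]


def config_to_dict(cfg: SimConfig) -> dict:
    """Flat, unit-annotated nested dict representation of a config."""
    k = cfg.kinetics
    return {
        "geometry": {
            "cell_length_um": 2.0 * cfg.geometry.half_length,
            "cell_width_um": 2.0 * cfg.geometry.half_width,
        },
        "kinetics": {
            "v_grow_um_s": k.v_grow,
            "v_contact_um_s": k.v_contact,
            "v_shrink_um_s": k.v_shrink,
            "stall_force_pN": k.stall_force,
            "flexural_rigidity_pN_um2": k.flexural_rigidity,
        },
        "catastrophe": {
            "step_parameter": k.catastrophe.step_parameter,
            "timescale_s": k.catastrophe.timescale_parameter,
            "tau0_s": k.catastrophe.tau0,
        },
        "drag": {
            "viscosity_pN_s_um2": cfg.drag.viscosity,
            "nucleus_radius_um": cfg.drag.nucleus_radius,
            "mt_radius_um": cfg.drag.mt_radius,
        },
        "mts": {
            "n_right": cfg.n_right,
            "n_left": cfg.n_left,
            "lr_mode": cfg.lr_mode,
            "theta_spread_rad": cfg.theta_spread,
        },
        "run": {
            "duration_s": cfg.duration,
            "dt_s": cfg.dt,
            "burn_in_s": cfg.burn_in,
            "out_dt_s": cfg.out_dt,
            "seed": cfg.seed,
        },
    }


def config_hash(cfg: SimConfig) -> str:
    payload = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _dict_to_config(d: dict) -> SimConfig:
    defaults = config_to_dict(SimConfig())
    provenance: dict[str, str] = {}
    merged: dict[str, dict] = {}
    for section, keys in defaults.items():
        user = d.get(section, {}) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config section '{section}' must be a mapping")
        for key in user:
            if key not in keys:
                raise ValueError(f"unknown config key '{section}.{key}'")
        merged[section] = {}
        for key, dflt in keys.items():
            if key in user:
                merged[section][key] = user[key]
                provenance[f"{section}.{key}"] = "user"
            else:
                merged[section][key] = dflt
                provenance[f"{section}.{key}"] = "default"
    for section in d:
        if section not in defaults:
            raise ValueError(f"unknown config section '{section}'")
    g, k, c, dr, m, r = (
        merged["geometry"],
        merged["kinetics"],
        merged["catastrophe"],
        merged["drag"],
        merged["mts"],
        merged["run"],
    )
    cfg = SimConfig(
        geometry=CellGeometry(g["cell_length_um"] / 2.0, g["cell_width_um"] / 2.0),
        kinetics=KineticParams(
            v_grow=k["v_grow_um_s"],
            v_contact=k["v_contact_um_s"],
            v_shrink=k["v_shrink_um_s"],
            stall_force=k["stall_force_pN"],
            flexural_rigidity=k["flexural_rigidity_pN_um2"],
            catastrophe=CatastropheModel(
                step_parameter=c["step_parameter"],
                timescale_parameter=c["timescale_s"],
                tau0=c["tau0_s"],
            ),
        ),
        drag=DragEnvironment(
            viscosity=dr["viscosity_pN_s_um2"],
            nucleus_radius=dr["nucleus_radius_um"],
            mt_radius=dr["mt_radius_um"],
        ),
        n_right=m["n_right"],
        n_left=m["n_left"],
        lr_mode=m["lr_mode"],
        theta_spread=m["theta_spread_rad"],
        duration=r["duration_s"],
        dt=r["dt_s"],
        burn_in=r["burn_in_s"],
        out_dt=r["out_dt_s"],
        seed=r["seed"],
    )
    cfg.__dict__["_provenance"] = provenance  # frozen dataclass: stash via __dict__
    return cfg


def load_config_detailed(path) -> tuple[SimConfig, dict[str, str]]:
    """Load a YAML config; returns the config and a key -> user/default map."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    cfg = _dict_to_config(data)
    return cfg, cfg.__dict__["_provenance"]


def load_config(path) -> SimConfig:
    """Load a YAML config file, applying documented defaults for absent keys."""
    return load_config_detailed(path)[0]


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path, cfg: SimConfig | None = None) -> None:
    """Tab-separated trajectory with '# key: value' header lines."""
    path = Path(path)
    header = [
        "# format: mtpush trajectory v1 (units: um, s, rad)",
        f"# seed: {traj.seed}",
        f"# dt_out_s: {traj.dt_out}",
        f"# clamp_events: {traj.clamp_events}",
    ]
    if cfg is not None:
        header.append(f"# config_hash: {config_hash(cfg)}")
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        traj.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_meta(path) -> dict[str, str]:
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_trajectory(path) -> Trajectory:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_s", "x_um", "y_um", "omega_rad", "spb_x_um", "spb_y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file missing columns {sorted(required - set(df.columns))}")
    times = df["time_s"].to_numpy()
    dt_out = float(meta.get("dt_out_s", times[1] - times[0] if len(times) > 1 else 1.0))
    seed = meta.get("seed")
    return Trajectory(
        times=times,
        x=df["x_um"].to_numpy(),
        y=df["y_um"].to_numpy(),
        omega=df["omega_rad"].to_numpy(),
        spb_x=df["spb_x_um"].to_numpy(),
        spb_y=df["spb_y_um"].to_numpy(),
        dt_out=dt_out,
        seed=None if seed in (None, "None") else int(seed),
        clamp_events=int(meta.get("clamp_events", 0)),
    )


def read_xy_series(path, delimiter: str | None = None) -> Trajectory:
    """Generic 2/3-column delimited reader: time, x[, y] -> Trajectory."""
    arr = np.loadtxt(path, delimiter=delimiter, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError("need at least time and x columns")
    times, x = arr[:, 0], arr[:, 1]
    y = arr[:, 2] if arr.shape[1] > 2 else np.zeros_like(x)
    dt_out = float(times[1] - times[0]) if len(times) > 1 else 1.0
    z = np.zeros_like(x)
    return Trajectory(times=times, x=x, y=y, omega=z, spb_x=x, spb_y=y, dt_out=dt_out)


# ---------------------------------------------------------------------------
# event lists


def write_catastrophe_dataset(data: CatastropheDataset, path) -> None:
    a, b = data.window
    lines = ["# catastrophe times, seconds, one per row"]
    lines.append(f"# min_window: {a}")
    if np.isfinite(b):
        lines.append(f"# max_window: {b}")
    lines += [f"{t:.6g}" for t in data.times]
    Path(path).write_text("\n".join(lines) + "\n")


def read_catastrophe_dataset(path) -> CatastropheDataset:
    """One catastrophe time (s) per row; optional '# min_window/max_window' keys."""
    meta = _read_meta(path)
    times = np.loadtxt(path, comments="#", ndmin=1)
    lo = float(meta.get("min_window", 0.0))
    hi = float(meta.get("max_window", np.inf))
    return CatastropheDataset(times=times, window=(lo, hi))


def read_offsets(path) -> np.ndarray:
    """Septum offsets (um), one per row."""
    return np.loadtxt(path, comments="#", ndmin=1)


def write_manifest(out_dir, seeds, outputs, cfg: SimConfig | None = None, extra: dict | None = None) -> Path:
    """Write run metadata so any run can be reproduced from its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "mtpush",
        "version": mtpush.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds,
        "outputs": [str(p) for p in outputs],
    }
    if cfg is not None:
        manifest["config_hash"] = config_hash(cfg)
        manifest["config"] = config_to_dict(cfg)
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path
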