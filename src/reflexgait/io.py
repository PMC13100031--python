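"""Configuration files, serialization and run manifests.

Conventions: YAML for configurations, CSV for parameter vectors and speed
datasets (canonical column order everywhere), JSON for results and models,
HDF5 or CSV for trajectories.  Angles are degrees at I/O boundaries and
radians internally.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .controller import ConnectionMatrix, ParameterVector, parameter_names
from .episode import EpisodeConfig, EpisodeResult
from .key_params import KeySelection
from .smf import SMFModel
from .speed_opt import CmaConfig, SpeedDataset


class ConfigError(ValueError):
    """A configuration file failed validation."""


# ----------------------------------------------------------------------
# parameter vectors
# ----------------------------------------------------------------------
def save_params_csv(params: ParameterVector, path: str | Path) -> None:
    df = pd.DataFrame([params.encode()], columns=params.names())
    df.to_csv(path, index=False)


def load_params_csv(path: str | Path, matrix: ConnectionMatrix) -> ParameterVector:
    df = pd.read_csv(path)
    cols = parameter_names(matrix)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"parameter CSV misses columns: {missing[:5]} ...")
    return ParameterVector.decode(matrix, df[cols].iloc[0].to_numpy(float))


def save_params_json(params: ParameterVector, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dict(zip(params.names(), params.encode().tolist())), indent=1)
    )


def load_params_json(path: str | Path, matrix: ConnectionMatrix) -> ParameterVector:
    data = json.loads(Path(path).read_text())
    cols = parameter_names(matrix)
    try:
        vec = np.array([data[c] for c in cols], dtype=float)
    except KeyError as err:
        raise ConfigError(f"parameter JSON misses key {err}") from None
    return ParameterVector.decode(matrix, vec)


# ----------------------------------------------------------------------
# speed datasets / key selections / SMF models
# ----------------------------------------------------------------------
def save_dataset_csv(ds: SpeedDataset, matrix: ConnectionMatrix, path: str | Path) -> None:
    ds.to_frame(matrix).to_csv(path, index=False)


def load_dataset_csv(path: str | Path, matrix: ConnectionMatrix) -> SpeedDataset:
    return SpeedDataset.from_frame(pd.read_csv(path), matrix)


def save_keys_json(keys: KeySelection, matrix: ConnectionMatrix, path: str | Path) -> None:
    names = parameter_names(matrix)
    Path(path).write_text(
        json.dumps(
            {
                "n_key": keys.n_key,
                "indices": list(keys.indices),
                "kinds": list(keys.kinds),
                "names": [names[i] for i in keys.indices],
            },
            indent=1,
        )
    )


def load_keys_json(path: str | Path) -> KeySelection:
    data = json.loads(Path(path).read_text())
    return KeySelection(
        n_key=int(data["n_key"]),
        indices=tuple(int(i) for i in data["indices"]),
        kinds=tuple(data.get("kinds", ["?"] * len(data["indices"]))),
    )


def save_smf_json(model: SMFModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "degree": model.degree,
                "keys": {
                    "n_key": model.keys.n_key,
                    "indices": list(model.keys.indices),
                    "kinds": list(model.keys.kinds),
                },
                "beta": model.beta.tolist(),
                "p_init": model.p_init.encode().tolist(),
                "stable_range": list(model.stable_range)
                if model.stable_range
                else None,
            },
            indent=1,
        )
    )


def load_smf_json(path: str | Path, matrix: ConnectionMatrix) -> SMFModel:
    d = json.loads(Path(path).read_text())
    keys = KeySelection(
        n_key=int(d["keys"]["n_key"]),
        indices=tuple(int(i) for i in d["keys"]["indices"]),
        kinds=tuple(d["keys"]["kinds"]),
    )
    model = SMFModel(
        degree=int(d["degree"]),
        keys=keys,
        beta=np.asarray(d["beta"], dtype=float),
        p_init=ParameterVector.decode(matrix, np.asarray(d["p_init"], dtype=float)),
        stable_range=tuple(d["stable_range"]) if d["stable_range"] else None,
    )
    return model


# ----------------------------------------------------------------------
# episode results
# ----------------------------------------------------------------------
def export_episode(result: EpisodeResult, out_dir: str | Path, stem: str = "episode") -> None:
    """Write scalars as JSON and trajectories as CSV (or HDF5 if h5py picks
    up a ``.h5`` stem suffix)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalars = {
        "t_max": result.t_max,
        "t_sim": result.t_sim,
        "stable": bool(result.stable),
        "d_sim": result.d_sim,
        "v_mean": result.v_mean,
        "v_act": result.v_act,
        "gait": result.gait,
        "switch_times": list(result.switch_times),
        "diagnostic": result.diagnostic,
    }
    (out / f"{stem}.json").write_text(json.dumps(scalars, indent=1))
    if stem.endswith(".h5"):
        import h5py

        with h5py.File(out / stem, "w") as fh:
            for k, v in result.trajectories.items():
                fh.create_dataset(k, data=v)
        return
    traj = result.trajectories
    cols: dict[str, np.ndarray] = {"t": traj["t"]}
    for name in ("com_x", "com_y", "torso_x", "torso_vx"):
        cols[name] = traj[name]
    fy = np.atleast_2d(traj["contact_fy"])
    for i in range(fy.shape[1]):
        cols[f"contact_fy_{i}"] = fy[:, i]
    ja = np.atleast_2d(traj["joint_angles"])
    if ja.size:
        for i in range(ja.shape[1]):
            cols[f"joint_angle_deg_{i}"] = np.degrees(ja[:, i])
    pd.DataFrame(cols).to_csv(out / f"{stem}_trajectories.csv", index=False)


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    plant: str = "toy"  # "toy" | "biped"
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    cma: CmaConfig = field(default_factory=CmaConfig)
    n_key: int = 30
    degree: int = 3
    grid_min: float = 0.5
    grid_max: float = 3.5
    grid_step: float = 0.025

    def to_dict(self) -> dict[str, Any]:
        return {
            "plant": self.plant,
            "episode": {
                "t_max": self.episode.t_max,
                "fall_height": self.episode.fall_height,
                "transient": self.episode.transient,
                "record_dt": self.episode.record_dt,
                "contact_threshold": self.episode.contact_threshold,
            },
            "cma": {
                "sigma0": self.cma.sigma0,
                "n_seeds": self.cma.n_seeds,
                "improve_tol": self.cma.improve_tol,
                "improve_window": self.cma.improve_window,
                "max_generations": self.cma.max_generations,
                "popsize": self.cma.popsize,
            },
            "smf": {
                "n_key": self.n_key,
                "degree": self.degree,
                "grid_min": self.grid_min,
                "grid_max": self.grid_max,
                "grid_step": self.grid_step,
            },
        }


_SCHEMA = {
    "plant": {"plant": str},
    "episode": {
        "t_max": float,
        "fall_height": float,
        "transient": float,
        "record_dt": float,
        "contact_threshold": float,
    },
    "cma": {
        "sigma0": float,
        "n_seeds": int,
        "improve_tol": float,
        "improve_window": int,
        "max_generations": int,
        "popsize": int,
    },
    "smf": {
        "n_key": int,
        "degree": int,
        "grid_min": float,
        "grid_max": float,
        "grid_step": float,
    },
}
_POSITIVE = {
    "t_max", "fall_height", "record_dt", "sigma0", "n_seeds", "improve_tol",
    "improve_window", "max_generations", "popsize", "n_key", "degree",
    "grid_step",
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys, missing types and non-positive values where positivity is
    required raise :class:`ConfigError` naming the offending key.  Absent
    keys take the documented defaults (t_max 50 s, sigma0 0.01, grid step
    0.025, ...).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    known_sections = set(_SCHEMA) | {"plant"}
    flat: dict[str, Any] = {}
    for section, val in raw.items():
        if section == "plant":
            if not isinstance(val, str):
                raise ConfigError("plant must be a string ('toy' or 'biped')")
            flat["plant"] = val
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown configuration section {section!r}")
        if not isinstance(val, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, v in val.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            want = _SCHEMA[section][key]
            if v is not None and not isinstance(v, (int, float) if want is float else want):
                raise ConfigError(f"{section}.{key} must be {want.__name__}")
            if key in _POSITIVE and v is not None and v <= 0:
                raise ConfigError(f"{section}.{key} must be positive, got {v}")
            flat[key] = v

    plant = flat.get("plant", "toy")
    if plant not in ("toy", "biped"):
        raise ConfigError(f"plant must be 'toy' or 'biped', got {plant!r}")
    episode = EpisodeConfig(
        t_max=float(flat.get("t_max", 50.0)),
        fall_height=float(flat.get("fall_height", 0.9)),
        transient=float(flat.get("transient", 10.0)),
        record_dt=float(flat.get("record_dt", 0.005)),
        contact_threshold=float(flat.get("contact_threshold", 20.0)),
    )
    cma = CmaConfig(
        sigma0=float(flat.get("sigma0", 0.01)),
        n_seeds=int(flat.get("n_seeds", 20)),
        improve_tol=float(flat.get("improve_tol", 1e-5)),
        improve_window=int(flat.get("improve_window", 500)),
        max_generations=int(flat.get("max_generations", 3000)),
        popsize=flat.get("popsize"),
    )
    return RunConfig(
        plant=plant,
        episode=episode,
        cma=cma,
        n_key=int(flat.get("n_key", 30)),
        degree=int(flat.get("degree", 3)),
        grid_min=float(flat.get("grid_min", 0.5)),
        grid_max=float(flat.get("grid_max", 3.5)),
        grid_step=float(flat.get("grid_step", 0.025)),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ----------------------------------------------------------------------
# run manifest
# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of the inputs that produced an output directory."""

    stages: list[str]
    seeds: dict[str, int]
    config_paths: list[str]
    out_dir: str
    tool_version: str = _version
    input_hashes: dict[str, str] = field(default_factory=dict)

    def write(self) -> Path:
        for p in self.config_paths:
            path = Path(p)
            if path.exists():
                self.input_hashes[p] = _sha256(path)
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        target = out / "manifest.json"
        target.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return target

    @classmethod
    def read(cls, out_dir: str | Path) -> "RunManifest":
        data = json.loads((Path(out_dir) / "manifest.json").read_text())
        return cls(**data)
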