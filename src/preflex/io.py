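"""Configuration files, trajectory CSV dialect, JSON summaries, manifests.

The configuration is a YAML file with flat sections ``muscle``, ``leg``,
``sim`` and (optionally) ``stimulation``; all values SI. An empty or absent
section falls back to the documented defaults. Unknown keys are rejected
with the offending key path. Trajectory tables are RFC-4180 CSV with a
header row carrying SI units; metadata (events, scalars, config hash) goes
to a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .engine import Trajectory
from .params import (LegParams, ModelParams, MuscleParams, SimConfig,
                     StimProtocol)

_SECTIONS = {"muscle": MuscleParams, "leg": LegParams, "sim": SimConfig}


class ConfigError(ValueError):
    pass


def _build_section(name: str, cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': "
            + ", ".join(f"{name}.{k}" for k in sorted(unknown)))
    if name == "sim" and "perturbations" in data:
        data = dict(data, perturbations=tuple(data["perturbations"]))
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path: str | Path | None = None) -> ModelParams:
    """Validated parameter set from a YAML file (defaults if empty/None)."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got "
                              f"{type(data).__name__}")
    unknown = set(data) - set(_SECTIONS) - {"stimulation"}
    if unknown:
        raise ConfigError("unknown section(s): " + ", ".join(sorted(unknown)))
    parts = {name: _build_section(name, cls, data.get(name) or {})
             for name, cls in _SECTIONS.items()}
    return ModelParams(muscle=parts["muscle"], leg=parts["leg"],
                       sim=parts["sim"])


def load_protocol(path: str | Path | None, kind: str | None = None,
                  ) -> StimProtocol:
    """Stimulation protocol from the config's ``stimulation`` section."""
    data = {}
    if path is not None:
        data = (yaml.safe_load(Path(path).read_text()) or {}).get(
            "stimulation") or {}
    if kind is not None:
        data = dict(data, kind=kind)
    return _build_section("stimulation", StimProtocol, data)


def dump_config(params: ModelParams, protocol: StimProtocol | None = None,
                path: str | Path | None = None) -> str:
    """Serialize parameters (and optionally a protocol) to YAML."""
    doc = {
        "muscle": dataclasses.asdict(params.muscle),
        "leg": dataclasses.asdict(params.leg),
        "sim": dataclasses.asdict(params.sim),
    }
    doc["sim"]["perturbations"] = list(doc["sim"]["perturbations"])
    if protocol is not None:
        doc["stimulation"] = dataclasses.asdict(protocol)
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(params: ModelParams,
                protocol: StimProtocol | None = None) -> str:
    """Hash of the canonical (key-sorted) parameter serialization."""
    return hashlib.sha256(
        dump_config(params, protocol).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# trajectory CSV dialect
# ----------------------------------------------------------------------

def write_trajectory(traj: Trajectory, csv_path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    """Trajectory table to CSV (units in headers) + JSON metadata."""
    traj.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(traj.meta(), indent=1))


def read_trajectory(csv_path: str | Path,
                    meta_path: str | Path) -> Trajectory:
    """Rebuild a Trajectory from the CSV dialect and its metadata."""
    import pandas as pd

    df = pd.read_csv(csv_path)
    meta = json.loads(Path(meta_path).read_text())
    cols = {"t": "t_s", "y": "y_m", "v_y": "v_y_m_per_s", "phi": "phi_rad",
            "l_mtu": "l_mtu_m", "v_mtu": "v_mtu_m_per_s", "l_ce": "l_ce_m",
            "v_ce": "v_ce_m_per_s", "a": "a", "u": "u", "f_ce": "f_ce_n",
            "f_mtu": "f_mtu_n", "f_leg": "f_leg_n"}
    arrays = {k: df[v].to_numpy() for k, v in cols.items()}
    arrays["phase"] = df["phase"].to_numpy(dtype=object)
    return Trajectory(
        protocol=meta["protocol"], dh=meta["dh_m"], h0=meta["h0_m"],
        h1=meta["h1_m"], t_td=meta["t_td_s"], t_to=meta["t_to_s"],
        t_apex_end=meta["t_apex_end_s"], **arrays)


# ----------------------------------------------------------------------
# run manifest
# ----------------------------------------------------------------------

#: conventions every output relies on, echoed into each manifest
DECISIONS_REGISTER = {
    "knee_angle": "inner angle phi; y = 2*l_s*sin(phi/2); phi=pi straight",
    "mtu_sign": "knee flexion (smaller phi) lengthens the extensor MTU",
    "v_ce_sign": "negative = shortening (concentric), positive = lengthening",
    "stimulation_clamp": "u clamped to [0, 1]",
    "work_sign": "positive fibre work = energy absorbed by the fibres",
    "preflex_window": "30 ms after the touch-down event",
    "pre_touchdown_sample": "last output sample strictly before touch-down",
    "midstance_marker": "temporal midpoint of stance",
    "w0_reporting": "work of the pre-impact force F0 reported separately "
                    "as w_0, not folded into the V/L/A components",
}


def run_manifest(params: ModelParams, protocol: StimProtocol,
                 trials: list[Trajectory], out_dir: str | Path,
                 files: list[str]) -> dict:
    """Machine-readable record of one suite run; every file must exist."""
    out_dir = Path(out_dir)
    missing = [f for f in files if not (out_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"manifest lists missing files: {missing}")
    return {
        "tool_version": _version,
        "config_hash": config_hash(params, protocol),
        "protocol": protocol.kind,
        "t_td_expected_s": protocol.t_td_expected,
        "dh_m": [tr.dh for tr in trials],
        "events": {f"{tr.dh:+.3f}": {"t_td_s": tr.t_td, "t_to_s": tr.t_to,
                                     "t_apex_end_s": tr.t_apex_end}
                   for tr in trials},
        "files": files,
        "decisions": DECISIONS_REGISTER,
    }


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
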