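"""TOML run configuration, extended-XYZ snapshots, CSV/JSON outputs.

Configs are TOML with sections [system], [interaction], [thermo], [box],
[drive], [mc], [bd], [output] and a top-level seed; unknown keys are
rejected and every run echoes its effective (default-filled) config for
provenance.  Snapshots are extended XYZ with per-atom columns
species:S:1:pos:R:3:quat:R:4 and the box on the comment-line Lattice field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

try:
    import tomllib
except ModuleNotFoundError:  # pragma: no cover - py310
    import tomli as tomllib

from .bd import BDParams, ContinuousPatchModel
from .mc import DriveSpec, MoveParams, SquareWave, StopMode
from .model import (
    LABEL_SPECIES,
    SPECIES_LABELS,
    BondRule,
    InteractionModel,
    ParameterError,
    PatchyConfiguration,
    SimulationBox,
    Species,
    ThermoState,
)


class ConfigError(ParameterError):
    """Schema violation in a run configuration."""


def _positive(x):
    return x > 0


def _non_negative(x):
    return x >= 0


def _fraction(x):
    return 0.0 <= x <= 1.0


# key -> (type, default, validator or None, description of the constraint)
_SCHEMA: Dict[str, Dict[str, tuple]] = {
    "system": {
        "preset": (str, "bare_8", lambda s: s in ("bare_8", "crowded_8_48", "large_1000"),
                   "one of bare_8 | crowded_8_48 | large_1000"),
        "bond_rule": (str, "one_state", lambda s: s in ("one_state", "two_state"),
                      "one of one_state | two_state"),
        "start": (str, "random", lambda s: s in ("random", "target"),
                  "one of random | target"),
    },
    "interaction": {
        "eps_patch": (float, 4.0, _non_negative, ">= 0"),
        "sigma": (float, 1.0, _positive, "> 0"),
        "lambda_range": (float, 1.1, lambda x: x > 1, "> 1"),
        "cos_theta_max": (float, 0.95, lambda x: 0 < x < 1, "in (0, 1)"),
        "opening_angle_deg": (float, 135.0, lambda x: 0 < x < 180, "in (0, 180)"),
    },
    "thermo": {
        "temperature": (float, 65.0, _positive, "> 0"),
    },
    "box": {
        "edge": (float, 0.0, _non_negative, ">= 0 (0 means preset default)"),
    },
    "drive": {
        "eps_drive": (float, 0.0, _non_negative, ">= 0"),
        "baseline": (float, 3.7, _non_negative, ">= 0"),
        "amplitude": (float, 0.0, _non_negative, ">= 0"),
        "period": (float, 20.0, _positive, "> 0"),
    },
    "mc": {
        "max_translation": (float, 0.3, _non_negative, ">= 0"),
        "max_rotation": (float, 0.4, _non_negative, ">= 0"),
        "translation_probability": (float, 0.5, _fraction, "in [0, 1]"),
        "budget_steps": (int, 10_000_000, _positive, "> 0"),
        "record_every": (int, 10_000, _positive, "> 0"),
        "stop_mode": (str, "fixed_budget",
                      lambda s: s in ("fixed_budget", "first_assembly", "first_disassembly"),
                      "one of fixed_budget | first_assembly | first_disassembly"),
    },
    "bd": {
        "timestep": (float, 0.005, _positive, "> 0"),
        "friction": (float, 1.0, _positive, "> 0"),
        "mass": (float, 1.0, _positive, "> 0"),
        "inertia": (float, 0.4, _positive, "> 0"),
        "budget_time": (float, 1000.0, _positive, "> 0"),
        "radial_width": (float, 0.15, _positive, "> 0"),
        "angular_width": (float, 0.5, _positive, "> 0"),
        "eps_core": (float, 5.0, _positive, "> 0"),
        "record_every_ps": (float, 1.0, _positive, "> 0"),
        "check_every_ps": (float, 0.25, _positive, "> 0"),
    },
    "output": {
        "directory": (str, "out", None, ""),
        "trajectory_every": (int, 0, _non_negative, ">= 0 (0 disables frames)"),
    },
}

_PRESET_EDGES = {"bare_8": 4.5, "crowded_8_48": 6.0, "large_1000": 22.5}


@dataclass
class RunConfig:
    """Validated, default-filled run configuration."""

    data: Dict[str, dict]
    seed: int = 0

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self.data == other.data and self.seed == other.seed

    # -- section accessors ---------------------------------------------------
    def bond_rule(self) -> BondRule:
        return BondRule(self.data["system"]["bond_rule"])

    def interaction_model(self) -> InteractionModel:
        from .model import PatchGeometry

        s = self.data["interaction"]
        return InteractionModel(
            eps_patch=s["eps_patch"], sigma=s["sigma"], lambda_range=s["lambda_range"],
            cos_theta_max=s["cos_theta_max"], bond_rule=self.bond_rule(),
            geometry=PatchGeometry(opening_angle_deg=s["opening_angle_deg"]),
        )

    def thermo(self) -> ThermoState:
        return ThermoState(self.data["thermo"]["temperature"])

    def box(self) -> SimulationBox:
        edge = self.data["box"]["edge"]
        if edge <= 0:
            edge = _PRESET_EDGES[self.data["system"]["preset"]]
        return SimulationBox.cubic(edge)

    def move_params(self) -> MoveParams:
        s = self.data["mc"]
        return MoveParams(
            max_translation=s["max_translation"], max_rotation=s["max_rotation"],
            translation_probability=s["translation_probability"],
        )

    def drive(self, with_waveform: bool = False) -> DriveSpec:
        s = self.data["drive"]
        wf = SquareWave(baseline=s["baseline"], amplitude=s["amplitude"],
                        period=s["period"]) if with_waveform else None
        return DriveSpec(eps_drive=s["eps_drive"], waveform=wf)

    def stop_mode(self) -> StopMode:
        return StopMode[self.data["mc"]["stop_mode"].upper()]

    def bd_params(self) -> BDParams:
        s = self.data["bd"]
        return BDParams(
            timestep=s["timestep"], friction=s["friction"], mass=s["mass"],
            inertia=s["inertia"], temperature=self.data["thermo"]["temperature"],
            budget_time=s["budget_time"],
        )

    def continuous_model(self) -> ContinuousPatchModel:
        from .model import PatchGeometry

        s = self.data["bd"]
        return ContinuousPatchModel(
            eps_base=self.data["drive"]["baseline"],
            sigma=self.data["interaction"]["sigma"],
            radial_width=s["radial_width"], angular_width=s["angular_width"],
            eps_core=s["eps_core"], bond_rule=self.bond_rule(),
            geometry=PatchGeometry(
                opening_angle_deg=self.data["interaction"]["opening_angle_deg"]
            ),
        )


def _validate(raw: dict) -> Tuple[Dict[str, dict], int]:
    seed = 0
    data: Dict[str, dict] = {}
    for key, value in raw.items():
        if key == "seed":
            if not isinstance(value, int):
                raise ConfigError("seed: must be an integer")
            seed = value
            continue
        if key not in _SCHEMA:
            raise ConfigError(f"unknown section [{key}]")
        if not isinstance(value, dict):
            raise ConfigError(f"[{key}] must be a table")
        for k in value:
            if k not in _SCHEMA[key]:
                raise ConfigError(f"unknown key {key}.{k}")
    for section, keys in _SCHEMA.items():
        sec_in = raw.get(section, {})
        sec_out = {}
        for k, (typ, default, validator, constraint) in keys.items():
            v = sec_in.get(k, default)
            if typ is float and isinstance(v, int) and not isinstance(v, bool):
                v = float(v)
            if not isinstance(v, typ) or isinstance(v, bool) and typ is not bool:
                raise ConfigError(f"{section}.{k}: expected {typ.__name__}")
            if validator is not None and not validator(v):
                raise ConfigError(f"{section}.{k}: must be {constraint}")
            sec_out[k] = v
        data[section] = sec_out
    return data, seed


def read_config(path) -> RunConfig:
    """Load and validate a TOML run config, filling defaults."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    data, seed = _validate(raw)
    return RunConfig(data=data, seed=seed)


def config_from_dict(raw: dict) -> RunConfig:
    data, seed = _validate(raw)
    return RunConfig(data=data, seed=seed)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v)} to TOML")


def write_config(config: RunConfig, path) -> None:
    """Write the effective config back out (round-trips through read_config)."""
    lines = [f"seed = {config.seed}", ""]
    for section, keys in config.data.items():
        lines.append(f"[{section}]")
        for k, v in keys.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_PROPERTIES = "species:S:1:pos:R:3:quat:R:4"


def write_snapshot(
    config: PatchyConfiguration,
    box: SimulationBox,
    path,
    time_label: Optional[float] = None,
    append: bool = False,
) -> None:
    """Write one extended-XYZ frame (appendable for trajectories)."""
    n = config.n_particles
    ex, ey, ez = (float(v) for v in box.edge)
    lattice = f'"{ex!r} 0.0 0.0 0.0 {ey!r} 0.0 0.0 0.0 {ez!r}"'
    comment = f"Lattice={lattice} Properties={_PROPERTIES} pbc=\"T T T\""
    if time_label is not None:
        comment += f" Time={float(time_label)!r}"
    rows = [str(n), comment]
    for i in range(n):
        sp = SPECIES_LABELS[Species(int(config.species[i]))]
        x, y, z = (float(v) for v in config.positions[i])
        qw, qx, qy, qz = (float(v) for v in config.quaternions[i])
        rows.append(f"{sp} {x!r} {y!r} {z!r} {qw!r} {qx!r} {qy!r} {qz!r}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(rows) + "\n")


def _parse_frame(lines: List[str]):
    n = int(lines[0])
    comment = lines[1]
    fields = {}
    for token in comment.replace('="', '\x00').split():
        if "=" in token and "\x00" not in token:
            k, v = token.split("=", 1)
            fields[k] = v
    # quoted values (Lattice, pbc, ...) need a small stateful pass
    rest = comment
    quoted = {}
    while "=\"" in rest:
        key_end = rest.index("=\"")
        key = rest[:key_end].split()[-1]
        rest2 = rest[key_end + 2:]
        val_end = rest2.index('"')
        quoted[key] = rest2[:val_end]
        rest = rest2[val_end + 1:]
    lattice = quoted.get("Lattice")
    if lattice is None:
        raise ParameterError("frame has no Lattice field")
    lat = np.array([float(x) for x in lattice.split()]).reshape(3, 3)
    box = SimulationBox(edge=np.diag(lat))
    time_label = None
    for token in comment.split():
        if token.startswith("Time="):
            time_label = float(token.split("=", 1)[1])
    positions = np.empty((n, 3))
    quats = np.empty((n, 4))
    species = np.empty(n, dtype=np.int64)
    for i in range(n):
        parts = lines[2 + i].split()
        species[i] = int(LABEL_SPECIES[parts[0]])
        positions[i] = [float(v) for v in parts[1:4]]
        quats[i] = [float(v) for v in parts[4:8]]
    return PatchyConfiguration(positions, quats, species), box, time_label


def read_snapshot(path) -> Tuple[PatchyConfiguration, SimulationBox, Optional[float]]:
    """Read the first frame of an extended-XYZ file."""
    for frame in read_trajectory(path):
        return frame
    raise ParameterError(f"no frames in {path}")


def read_trajectory(path) -> Iterator[Tuple[PatchyConfiguration, SimulationBox, Optional[float]]]:
    """Iterate over all frames of an extended-XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k])
        yield _parse_frame(lines[k:k + 2 + n])
        k += 2 + n


# ---------------------------------------------------------------------------
# series / summaries
# ---------------------------------------------------------------------------

def observables_frame(result) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step_or_time": result.steps,
            "total_energy_kJ_mol": result.total_energy,
            "R": result.order_parameter,
            "S_kB": result.entropy,
            "n_bonds": result.n_bonds,
        }
    )


def write_observables_csv(result, path) -> None:
    observables_frame(result).to_csv(path, index=False)


def write_summary_json(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
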