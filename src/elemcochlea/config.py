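"""Run configuration: hierarchical JSON/YAML files, presets and validation.

Internally everything is SI; configuration values may be given either as
plain SI numbers or as strings with a unit suffix from the field's customary
units ("35 mm", "20 kHz", "0.84 mm^2"), converted on load.  Unknown keys are
rejected with the offending field path.  An empty file yields the full
human-cochlea preset (uniform scalae, 1D fluid coupling, locally-reacting
micromechanics).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import params as _params
from .micromech import CouplingParams, MiddleEarParams
from .params import CochleaParams
from .fluid import NearFieldParams
from .solver import CochlearModel

__all__ = [
    "RunConfig",
    "load_config",
    "build_model",
    "parse_quantity",
    "PRESETS",
    "config_hash",
]

_UNIT_FACTORS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6},
    "area": {"m^2": 1.0, "m2": 1.0, "cm^2": 1e-4, "cm2": 1e-4, "mm^2": 1e-6, "mm2": 1e-6},
    "frequency": {"hz": 1.0, "khz": 1e3, "Hz": 1.0, "kHz": 1e3},
    "density": {"kg/m^3": 1.0, "kg/m3": 1.0, "g/cm^3": 1e3, "g/cm3": 1e3},
    "surface_density": {"kg/m^2": 1.0, "kg/m2": 1.0},
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6},
    "dimensionless": {"": 1.0},
}


def parse_quantity(value, kind: str) -> float:
    """Convert a number (SI) or a "value unit" string to an SI float."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ValueError(f"expected a number or 'value unit' string, got {value!r}")
    parts = value.split()
    try:
        magnitude = float(parts[0])
    except (ValueError, IndexError):
        raise ValueError(f"cannot parse quantity {value!r}") from None
    unit = parts[1] if len(parts) > 1 else ""
    table = _UNIT_FACTORS[kind]
    key = unit if unit in table else unit.lower()
    if key not in table:
        raise ValueError(
            f"unknown {kind} unit {unit!r} in {value!r}; accepted: {sorted(set(table))}")
    return magnitude * table[key]


def _quantity_validator(kind: str):
    def _validate(cls, v):  # noqa: ANN001
        return None if v is None else parse_quantity(v, kind)
    return _validate


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CochleaSection(_Section):
    length: object = _params.HUMAN_TABLE["length"]
    n_elements: int = Field(default=512, ge=2)
    f_base: object = _params.HUMAN_TABLE["f_base"]
    length_const: object = _params.HUMAN_TABLE["length_const"]
    q_factor: float = Field(default=_params.HUMAN_TABLE["q_factor"], gt=0)
    fluid_density: object = _params.HUMAN_TABLE["fluid_density"]
    bm_mass: object = None  # None -> preset default matched to fluid_mode
    fluid_mode: Literal["uniform-1d", "nonuniform-1d", "3d"] = "uniform-1d"

    _v_len = field_validator("length", "length_const", mode="before")(_quantity_validator("length"))
    _v_f = field_validator("f_base", mode="before")(_quantity_validator("frequency"))
    _v_rho = field_validator("fluid_density", mode="before")(_quantity_validator("density"))
    _v_m0 = field_validator("bm_mass", mode="before")(_quantity_validator("surface_density"))


class GeometrySection(_Section):
    mode: Optional[Literal["uniform", "tapered"]] = None  # None -> matched to fluid_mode
    overrides_csv: Optional[str] = None


class MicromechanicsSection(_Section):
    mode: Literal["local", "longitudinal", "feedforward"] = "local"
    stiffness_fraction: Optional[float] = Field(default=None, ge=0)
    damping_fraction: Optional[float] = Field(default=None, ge=0)
    near_field_peak_factor: float = Field(default=2.0, ge=0)
    near_field_decay_factor: float = Field(default=0.12, gt=0)


class MiddleEarSection(_Section):
    enabled: bool = False
    mass: object = None
    stiffness: Optional[float] = Field(default=None, gt=0)
    damping: Optional[float] = Field(default=None, gt=0)

    _v_m = field_validator("mass", mode="before")(_quantity_validator("surface_density"))


class SimulationSection(_Section):
    f_min: object = 100.0
    f_max: object = 20e3
    points_per_decade: int = Field(default=100, ge=1)
    positions: Optional[list[float]] = None  # m
    duration: object = 20e-3
    sample_rate_factor: float = Field(default=8.0, ge=4.0)
    snapshot_times_ms: list[float] = Field(
        default_factory=lambda: [0.195, 0.495, 0.995, 1.495])

    _v_f = field_validator("f_min", "f_max", mode="before")(_quantity_validator("frequency"))
    _v_t = field_validator("duration", mode="before")(_quantity_validator("time"))


class OutputSection(_Section):
    path: Optional[str] = None
    format: Literal["csv", "hdf5"] = "csv"


class RunConfig(_Section):
    """Fully validated run configuration with the human preset as default."""

    cochlea: CochleaSection = Field(default_factory=CochleaSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    micromechanics: MicromechanicsSection = Field(default_factory=MicromechanicsSection)
    middle_ear: MiddleEarSection = Field(default_factory=MiddleEarSection)
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    output: OutputSection = Field(default_factory=OutputSection)
    seed: int = 0  # randomised test utilities only; the model is deterministic


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalised configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _geometry_overrides_from_csv(path: str, params: CochleaParams) -> dict:
    """Read per-element geometry overrides from a columnar CSV.

    The file must have a header with an ``x`` column (m) plus any of
    ``area`` (m²), ``bm_width`` (m), ``partition_width`` (m); values are
    linearly interpolated onto the element centres.
    """
    df = pd.read_csv(path)
    if "x" not in df.columns:
        raise ValueError(f"geometry CSV {path!r} must have an 'x' column")
    known = {"area", "bm_width", "partition_width"}
    extra = set(df.columns) - known - {"x"}
    if extra:
        raise ValueError(f"unknown geometry CSV columns: {sorted(extra)}")
    x_src = df["x"].to_numpy(float)
    if np.any(np.diff(x_src) <= 0):
        raise ValueError("geometry CSV x column must be strictly increasing")
    overrides = {}
    for col in df.columns:
        if col == "x":
            continue
        overrides[col] = np.interp(params.x, x_src, df[col].to_numpy(float))
    return overrides


_COUPLING_DEFAULTS = {"longitudinal": 0.1, "feedforward": 0.5}


def build_model(config: RunConfig) -> CochlearModel:
    """Assemble a :class:`CochlearModel` from a validated configuration."""
    c = config.cochlea
    bm_mass = c.bm_mass
    if bm_mass is None:
        bm_mass = _params.default_bm_mass(c.fluid_mode)
    else:
        preset = _params.default_bm_mass(c.fluid_mode)
        if not np.isclose(bm_mass, preset, rtol=2.0):
            warnings.warn(
                f"bm_mass={bm_mass} kg/m^2 is far from the {c.fluid_mode} preset value "
                f"{preset} kg/m^2; the 1D value folds in fluid loading, the 3D one does not",
                stacklevel=2)
    params = CochleaParams(
        length=c.length, n_elements=c.n_elements, f_base=c.f_base,
        length_const=c.length_const, q_factor=c.q_factor,
        fluid_density=c.fluid_density, bm_mass=bm_mass, fluid_mode=c.fluid_mode)

    geo_mode = config.geometry.mode
    if geo_mode is None:
        geo_mode = "uniform" if c.fluid_mode == "uniform-1d" else "tapered"
    overrides = {}
    if config.geometry.overrides_csv:
        overrides = _geometry_overrides_from_csv(config.geometry.overrides_csv, params)

    mm = config.micromechanics
    if mm.mode == "local":
        coupling = CouplingParams()
    else:
        frac = _COUPLING_DEFAULTS[mm.mode]
        coupling = CouplingParams(
            mode=mm.mode,
            stiffness_fraction=frac if mm.stiffness_fraction is None else mm.stiffness_fraction,
            damping_fraction=frac if mm.damping_fraction is None else mm.damping_fraction)

    me = None
    if config.middle_ear.enabled:
        me = MiddleEarParams(enabled=True, mass=config.middle_ear.mass,
                             stiffness=config.middle_ear.stiffness,
                             damping=config.middle_ear.damping)
    nf = NearFieldParams(peak_factor=mm.near_field_peak_factor,
                         decay_factor=mm.near_field_decay_factor)
    return CochlearModel.from_params(params, geometry_mode=geo_mode, coupling=coupling,
                                     middle_ear=me, near_field=nf, **overrides)


def _preset(fluid_mode: str, mm_mode: str = "local") -> RunConfig:
    return RunConfig.model_validate({
        "cochlea": {"fluid_mode": fluid_mode},
        "micromechanics": {"mode": mm_mode},
    })


#: Named presets of the human-cochlea example.
PRESETS: dict[str, RunConfig] = {
    "human-uniform": _preset("uniform-1d"),
    "human-tapered-1d": _preset("nonuniform-1d"),
    "human-3d": _preset("3d"),
}
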