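"""Physical parameters, longitudinal geometry and the tonotopic map.

The model divides an uncoiled cochlea of length ``L`` into ``N`` elements of
length ``Δ = L/N``, centred at ``x_n = nΔ`` for ``n = 1 … N`` (element 1 is
reserved for the stapes/oval-window boundary and element ``N`` for the
helicotrema).  All quantities are strictly SI internally; the human preset is
expressed in the units customary in the field (mm, kHz, mm²) only at the
configuration layer.

The passive micromechanics of each element are a single-degree-of-freedom
resonator per unit BM area whose natural frequency follows the exponential
place–frequency (tonotopic) map ``f(x) = f_B · exp(−x/l)``, with constant mass
``m0`` and constant quality factor ``Q0`` along the cochlea.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "HUMAN_TABLE",
    "CochleaParams",
    "GeometryProfile",
    "BmElementParams",
    "place_frequency",
    "characteristic_place",
    "effective_height",
    "build_geometry",
    "build_bm_elements",
]

FluidMode = Literal["uniform-1d", "nonuniform-1d", "3d"]

#: Human-cochlea preset values (SI units).  Widths/areas carry separate basal
#: and apical entries for the linearly tapered model; the uniform model uses
#: the printed average scala area and the mean of the two end widths.
HUMAN_TABLE: dict[str, float] = {
    "length": 35e-3,                 # L, m
    "partition_width_base": 1.14e-3,  # W_B, m
    "partition_width_apex": 0.67e-3,  # W_A, m
    "bm_width_base": 0.15e-3,         # B_B, m
    "bm_width_apex": 0.50e-3,         # B_A, m
    "f_base": 20e3,                   # f_B, Hz
    "length_const": 7e-3,             # l, m
    "q_factor": 2.5,                  # Q0
    "fluid_density": 1000.0,          # rho, kg m^-3
    "bm_mass_1d": 0.28,               # m0 with 1D fluid coupling, kg m^-2
    "bm_mass_3d": 0.05,               # m0 with 3D fluid coupling, kg m^-2
    "area_base": 1.29e-6,             # A_1, m^2
    "area_apex": 0.45e-6,             # A_2, m^2
    "area_avg": 0.84e-6,              # A_0, m^2
    "n_elements": 512,
}


def default_bm_mass(fluid_mode: str) -> float:
    """Preset-coupled BM mass per area: the 1D value folds the entrained
    fluid layer into the micromechanics, the 3D value is the bare organ of
    Corti mass (the near-field term carries the fluid loading instead)."""
    return HUMAN_TABLE["bm_mass_3d"] if fluid_mode == "3d" else HUMAN_TABLE["bm_mass_1d"]


@dataclass(frozen=True)
class CochleaParams:
    """Scalar physical and numerical parameters of the elemental model."""

    length: float = HUMAN_TABLE["length"]
    n_elements: int = int(HUMAN_TABLE["n_elements"])
    f_base: float = HUMAN_TABLE["f_base"]
    length_const: float = HUMAN_TABLE["length_const"]
    q_factor: float = HUMAN_TABLE["q_factor"]
    fluid_density: float = HUMAN_TABLE["fluid_density"]
    bm_mass: float = HUMAN_TABLE["bm_mass_1d"]
    fluid_mode: FluidMode = "uniform-1d"

    def __post_init__(self) -> None:
        if int(self.n_elements) != self.n_elements or self.n_elements < 2:
            raise ValueError(f"n_elements must be an integer >= 2, got {self.n_elements}")
        for name in ("length", "f_base", "length_const", "q_factor",
                     "fluid_density", "bm_mass"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.fluid_mode not in ("uniform-1d", "nonuniform-1d", "3d"):
            raise ValueError(f"unknown fluid_mode {self.fluid_mode!r}")

    @property
    def delta(self) -> float:
        """Element length Δ = L/N (m)."""
        return self.length / self.n_elements

    @property
    def x(self) -> np.ndarray:
        """Element-centre coordinates x_n = nΔ, n = 1 … N (m)."""
        return np.arange(1, self.n_elements + 1) * self.delta

    def with_n_elements(self, n: int) -> "CochleaParams":
        return replace(self, n_elements=n)


def place_frequency(x, params: CochleaParams):
    """Natural frequency at position ``x`` from the exponential tonotopic map.

    f(x) = f_B · exp(−x/l); strictly decreasing from ``f_B`` at the base.
    ``x`` may be a scalar or array; values must lie in [0, L].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > params.length):
        raise ValueError("position x outside the cochlea [0, L]")
    f = params.f_base * np.exp(-x / params.length_const)
    return float(f) if f.ndim == 0 else f


def characteristic_place(frequency: float, params: CochleaParams) -> float:
    """Inverse of the tonotopic map: x = l·ln(f_B/f) (m)."""
    if not 0 < frequency <= params.f_base:
        raise ValueError("frequency outside the mapped range (0, f_B]")
    return params.length_const * np.log(params.f_base / frequency)


def effective_height(area, bm_width):
    """Effective 1D duct height h = π²A / 8B translating scala area into
    series fluid inertance per unit BM width."""
    return np.pi**2 * np.asarray(area, dtype=float) / (8.0 * np.asarray(bm_width, dtype=float))


@dataclass(frozen=True)
class GeometryProfile:
    """Per-element scala geometry along the cochlea (all SI, length N).

    ``area`` is the cross-sectional area of each (symmetric) scala;
    ``area_effective`` the harmonic mean of the upper and lower scala areas
    (equal to ``area`` for the symmetric presets); ``height`` the effective 1D
    duct height π²A/8B.
    """

    area: np.ndarray
    bm_width: np.ndarray
    partition_width: np.ndarray
    area_effective: np.ndarray = field(default=None)  # type: ignore[assignment]
    height: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("area", "bm_width", "partition_width"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = arrays["area"].shape[0]
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.shape[0] != n:
                raise ValueError(f"{name} must be 1-D of common length, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive and finite")
        ae = self.area_effective
        ae = arrays["area"].copy() if ae is None else np.asarray(ae, dtype=float)
        if ae.shape != (n,) or np.any(ae <= 0):
            raise ValueError("area_effective must be strictly positive of length N")
        object.__setattr__(self, "area_effective", ae)
        h = self.height
        h = effective_height(arrays["area"], arrays["bm_width"]) if h is None \
            else np.asarray(h, dtype=float)
        if h.shape != (n,) or np.any(h <= 0):
            raise ValueError("height must be strictly positive of length N")
        object.__setattr__(self, "height", h)

    @property
    def n_elements(self) -> int:
        return int(self.area.shape[0])

    @property
    def is_uniform(self) -> bool:
        return all(np.ptp(a) == 0.0 for a in (self.area, self.bm_width, self.partition_width))

    @property
    def effective_height_mean(self) -> float:
        """Scalar height used by the uniform finite-difference fluid matrix."""
        return float(np.mean(self.height))


def _taper(base: float, apex: float, x: np.ndarray, length: float) -> np.ndarray:
    return base + (apex - base) * x / length


def build_geometry(
    params: CochleaParams,
    mode: Literal["uniform", "tapered"] = "uniform",
    *,
    area=None,
    bm_width=None,
    partition_width=None,
    area_lower=None,
) -> GeometryProfile:
    """Geometry profile for the human preset, optionally user-overridden.

    ``uniform``: constant arrays at the average scala area A0 and the mean of
    the basal/apical widths.  ``tapered``: linear interpolation in x between
    the basal and apical table values, evaluated at the element centres.
    Per-element override arrays (length N, strictly positive) replace the
    preset columns; ``area_lower`` gives an asymmetric second scala, in which
    case the effective area is the harmonic mean 2·A·A_lower/(A+A_lower).
    """
    n = params.n_elements
    x = params.x
    if mode == "uniform":
        a = np.full(n, HUMAN_TABLE["area_avg"])
        b = np.full(n, 0.5 * (HUMAN_TABLE["bm_width_base"] + HUMAN_TABLE["bm_width_apex"]))
        w = np.full(n, 0.5 * (HUMAN_TABLE["partition_width_base"] + HUMAN_TABLE["partition_width_apex"]))
    elif mode == "tapered":
        a = _taper(HUMAN_TABLE["area_base"], HUMAN_TABLE["area_apex"], x, params.length)
        b = _taper(HUMAN_TABLE["bm_width_base"], HUMAN_TABLE["bm_width_apex"], x, params.length)
        w = _taper(HUMAN_TABLE["partition_width_base"], HUMAN_TABLE["partition_width_apex"], x, params.length)
    else:
        raise ValueError(f"unknown geometry mode {mode!r}")

    def _override(preset: np.ndarray, user, name: str) -> np.ndarray:
        if user is None:
            return preset
        user = np.asarray(user, dtype=float)
        if user.shape != (n,):
            raise ValueError(f"{name} override must have length N={n}, got shape {user.shape}")
        if not np.all(np.isfinite(user)) or np.any(user <= 0):
            raise ValueError(f"{name} override entries must be strictly positive")
        return user

    a = _override(a, area, "area")
    b = _override(b, bm_width, "bm_width")
    w = _override(w, partition_width, "partition_width")
    if area_lower is not None:
        a2 = _override(np.empty(n), area_lower, "area_lower")
        ae = 2.0 * a * a2 / (a + a2)
    else:
        ae = a.copy()
    return GeometryProfile(area=a, bm_width=b, partition_width=w, area_effective=ae)


@dataclass(frozen=True)
class BmElementParams:
    """Per-element single-DOF BM parameters, all per unit area.

    ``stiffness`` s_n = (2π f(x_n))²·m0 follows the tonotopic map (so it
    decreases exponentially with n); ``damping`` r_n = sqrt(s_n·m_n)/Q0 keeps
    the element Q factor constant along the cochlea.
    """

    mass: np.ndarray        # kg m^-2
    stiffness: np.ndarray   # N m^-3
    damping: np.ndarray     # N s m^-3
    natural_frequency: np.ndarray  # Hz

    def __post_init__(self) -> None:
        for name in ("mass", "stiffness", "damping", "natural_frequency"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be strictly positive and finite")
        if np.any(np.diff(self.stiffness) >= 0):
            raise ValueError("stiffness must be strictly decreasing along x (tonotopic map)")

    @property
    def n_elements(self) -> int:
        return int(self.mass.shape[0])


def build_bm_elements(params: CochleaParams) -> BmElementParams:
    """Constant-mass, constant-Q element parameters on the tonotopic map."""
    f = place_frequency(params.x, params)
    m = np.full(params.n_elements, params.bm_mass)
    s = (2.0 * np.pi * f) ** 2 * params.bm_mass
    r = np.sqrt(s * m) / params.q_factor
    return BmElementParams(mass=m, stiffness=s, damping=r, natural_frequency=f)
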