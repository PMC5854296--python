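"""Coupled frequency-domain solution of the elemental cochlear model.

At each frequency the fluid coupling (p = Z_FC·v) and BM micromechanics
(v = v_s − Y_BM·p) combine into

    v = [I + Y_BM·Z_FC]⁻¹ · v_s,          p = Z_FC·v,

with the excitation vector v_s holding the (unit) stapes velocity in element
1 and zero in element N (helicotrema).  For the special case of uniform 1D
fluid coupling with a diagonal Y_BM the same equations reduce to the
classical transmission-line ladder network (series inertances L = 2ρΔ²/h,
first element L₁ = 2ρΔ, shunt admittances Y_BM(n), short-circuit
termination), which is solved here directly as a banded tridiagonal system —
both as a fast path for frequency sweeps and as a mutual oracle for the
dense elemental route.

All reported responses are normalised to unit stapes velocity; magnitudes
are 20·log₁₀|v/v_st| in dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from . import fluid, micromech
from .fluid import FiniteDifferenceMatrix, FluidCouplingMatrix, NearFieldParams
from .micromech import BmAdmittanceMatrix, CouplingParams, MiddleEarParams
from .params import BmElementParams, CochleaParams, GeometryProfile, build_bm_elements, build_geometry

__all__ = [
    "CoupledResponse",
    "CochlearModel",
    "solve_velocity",
    "solve_pressure",
    "ladder_inertances",
    "transmission_line_solve",
    "frequency_sweep",
    "default_frequency_grid",
]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e13


@dataclass(frozen=True)
class CoupledResponse:
    """BM velocity and pressure-difference distributions at one frequency,
    normalised to unit stapes velocity."""

    omega: float
    velocity: np.ndarray
    pressure: np.ndarray

    @property
    def frequency(self) -> float:
        return self.omega / (2.0 * np.pi)


def _excitation(n: int, stapes_velocity: complex = 1.0) -> np.ndarray:
    vs = np.zeros(n, dtype=complex)
    vs[0] = stapes_velocity
    return vs


def solve_velocity(
    ybm: BmAdmittanceMatrix,
    zfc: FluidCouplingMatrix,
    vs: np.ndarray,
) -> np.ndarray:
    """v = [I + Y_BM·Z_FC]⁻¹·v_s (dense direct solve)."""
    n = ybm.n_elements
    if zfc.n_elements != n or vs.shape != (n,):
        raise ValueError("Y_BM, Z_FC and v_s dimensions do not conform")
    a = np.eye(n, dtype=complex) + ybm.matrix @ zfc.matrix
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"coupled system ill-conditioned at omega={zfc.omega:.4g} (cond={cond:.3e})")
    return np.linalg.solve(a, vs.astype(complex))


def solve_pressure(
    ybm: BmAdmittanceMatrix,
    zfc: FluidCouplingMatrix,
    vs: np.ndarray,
) -> np.ndarray:
    """p = Z_FC·v with v from :func:`solve_velocity`.

    Algebraically identical to p = [Z_FC⁻¹ + Y_BM]⁻¹·v_s when Z_FC is
    invertible; the identity is exercised in the test suite.
    """
    return zfc.matrix @ solve_velocity(ybm, zfc, vs)


def ladder_inertances(params: CochleaParams, height: float) -> tuple[float, float]:
    """Series inertances of the transmission-line analogue: the basal
    boundary element L₁ = 2ρΔ and the interior elements L = 2ρΔ²/h."""
    if height <= 0:
        raise ValueError("effective height must be positive")
    return 2.0 * params.fluid_density * params.delta, \
        2.0 * params.fluid_density * params.delta**2 / height


def transmission_line_solve(
    params: CochleaParams,
    elements: BmElementParams,
    omega: float,
    height: float,
    me: MiddleEarParams | None = None,
    stapes_velocity: complex = 1.0,
) -> CoupledResponse:
    """Direct ladder-network (transmission-line) solution.

    Valid only for uniform 1D fluid coupling and locally-reacting
    micromechanics.  Nodal equations on the pressures: the stapes node is fed
    by the current source v_st with shunt Y_ME and series inertance
    L₁ = 2ρΔ; interior nodes carry series inertances L = 2ρΔ²/h and shunt
    admittances Y_BM(n); the apical end is short-circuited (p_N = 0).
    Solved as a banded tridiagonal system, independently of the dense
    elemental route.
    """
    n = params.n_elements
    if elements.n_elements != n:
        raise ValueError("elements and params disagree on N")
    inertance_1, inertance = ladder_inertances(params, height)
    y = micromech.local_admittance(omega, elements.mass, elements.stiffness,
                                   elements.damping)

    ab = np.zeros((3, n), dtype=complex)  # banded (upper, diag, lower)
    rhs = np.zeros(n, dtype=complex)
    # stapes node
    ab[1, 0] = 1.0 / (1j * omega * inertance_1) + micromech.middle_ear_admittance(omega, me)
    ab[0, 1] = -1.0 / (1j * omega * inertance_1)
    rhs[0] = stapes_velocity
    # interior nodes
    idx = np.arange(1, n - 1)
    ab[1, idx] = 2.0 / (1j * omega * inertance) + y[idx]
    ab[0, idx + 1] = -1.0 / (1j * omega * inertance)
    ab[2, idx - 1] = -1.0 / (1j * omega * inertance)
    # helicotrema: short circuit
    ab[1, n - 1] = 1.0
    ab[2, n - 2] = 0.0
    p = scipy.linalg.solve_banded((1, 1), ab, rhs)

    v = np.empty(n, dtype=complex)
    v[0] = stapes_velocity - micromech.middle_ear_admittance(omega, me) * p[0]
    v[idx] = -y[idx] * p[idx]
    v[n - 1] = 0.0
    return CoupledResponse(omega=float(omega), velocity=v, pressure=p)


def default_frequency_grid(
    f_min: float = 100.0,
    f_max: float = 20e3,
    points_per_decade: int = 100,
) -> np.ndarray:
    """Logarithmic frequency grid (Hz), default 100 points/decade, 0.1–20 kHz."""
    if f_min <= 0 or f_max <= f_min:
        raise ValueError("need 0 < f_min < f_max")
    n = max(2, int(np.ceil(np.log10(f_max / f_min) * points_per_decade)) + 1)
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


@dataclass
class CochlearModel:
    """Assembled elemental model: parameters, geometry, micromechanics and
    fluid-coupling mode, with per-frequency solvers and sweep extraction."""

    params: CochleaParams
    geometry: GeometryProfile
    elements: BmElementParams
    coupling: CouplingParams = field(default_factory=CouplingParams)
    middle_ear: MiddleEarParams | None = None
    near_field: NearFieldParams = field(default_factory=NearFieldParams)
    _fd: FiniteDifferenceMatrix | None = field(default=None, repr=False)
    _base_unit: np.ndarray | None = field(default=None, repr=False)  # Z_1D at omega=1

    @classmethod
    def from_params(
        cls,
        params: CochleaParams,
        geometry_mode: str | None = None,
        coupling: CouplingParams | None = None,
        middle_ear: MiddleEarParams | None = None,
        near_field: NearFieldParams | None = None,
        **geometry_overrides,
    ) -> "CochlearModel":
        if geometry_mode is None:
            geometry_mode = "uniform" if params.fluid_mode == "uniform-1d" else "tapered"
        geometry = build_geometry(params, geometry_mode, **geometry_overrides)
        return cls(
            params=params,
            geometry=geometry,
            elements=build_bm_elements(params),
            coupling=coupling or CouplingParams(),
            middle_ear=middle_ear,
            near_field=near_field or NearFieldParams(),
        )

    @property
    def fd_matrix(self) -> FiniteDifferenceMatrix:
        """Finite-difference fluid matrix (uniform 1D modes only)."""
        if self._fd is None:
            self._fd = fluid.assemble_fd_matrix(
                self.params, self.geometry.effective_height_mean)
        return self._fd

    def fluid_matrix(self, omega: float) -> FluidCouplingMatrix:
        mode = self.params.fluid_mode
        if mode == "uniform-1d":
            return fluid.zfc_1d_uniform(self.fd_matrix, omega)
        base_mode = "uniform-1d" if self.geometry.is_uniform else "nonuniform-1d"
        if self._base_unit is None:
            # every 1D construction is linear in omega: build once at omega=1
            if self.geometry.is_uniform:
                self._base_unit = fluid.zfc_1d_uniform(self.fd_matrix, 1.0).matrix
            else:
                self._base_unit = fluid.zfc_1d_nonuniform(self.geometry, self.params, 1.0).matrix
        base = FluidCouplingMatrix(matrix=self._base_unit * omega, omega=omega, mode=base_mode)
        if mode == "nonuniform-1d":
            return base
        return fluid.zfc_3d(base, self.geometry, omega, self.near_field,
                            rho=self.params.fluid_density, delta=self.params.delta)

    def admittance(self, omega: float) -> BmAdmittanceMatrix:
        if self.coupling.mode == "local":
            return micromech.ybm_local(omega, self.elements, self.middle_ear)
        if self.coupling.mode == "longitudinal":
            z = micromech.zbm_longitudinal(omega, self.elements, self.coupling)
            return micromech.ybm_from_impedance(z, omega, self.middle_ear,
                                                structure="inverse-tridiagonal")
        z = micromech.zbm_feedforward(omega, self.elements, self.coupling)
        return micromech.ybm_from_impedance(z, omega, self.middle_ear,
                                            structure="inverse-bidiagonal")

    def solve(self, omega: float, dense: bool = False) -> CoupledResponse:
        """Coupled response at one angular frequency.

        Uniform-1D + diagonal Y_BM uses the banded pressure-form solve
        (F/iω + Y_BM)p = v_s, identical mathematics to the dense route at
        O(N) cost; all other modes use the dense velocity-form solve
        [I + Y_BM·Z_FC]v = v_s.
        """
        n = self.params.n_elements
        vs = _excitation(n)
        if (not dense and self.params.fluid_mode == "uniform-1d"
                and self.coupling.mode == "local"):
            return self._solve_banded(omega, vs)
        ybm = self.admittance(omega)
        zfc = self.fluid_matrix(omega)
        v = solve_velocity(ybm, zfc, vs)
        p = zfc.matrix @ v
        return CoupledResponse(omega=float(omega), velocity=v, pressure=p)

    def _solve_banded(self, omega: float, vs: np.ndarray) -> CoupledResponse:
        n = self.params.n_elements
        f = self.fd_matrix.matrix
        y = micromech.local_admittance(omega, self.elements.mass,
                                       self.elements.stiffness, self.elements.damping)
        ab = np.zeros((3, n), dtype=complex)
        diag = f.diagonal() / (1j * omega)
        ab[1, :] = diag
        ab[1, 1:-1] += y[1:-1]
        ab[1, 0] += micromech.middle_ear_admittance(omega, self.middle_ear)
        ab[0, 1:] = f.diagonal(1) / (1j * omega)
        ab[2, :-1] = f.diagonal(-1) / (1j * omega)
        p = scipy.linalg.solve_banded((1, 1), ab, vs)
        v = vs.copy()
        v[1:-1] -= y[1:-1] * p[1:-1]
        v[0] -= micromech.middle_ear_admittance(omega, self.middle_ear) * p[0]
        v[-1] = 0.0
        return CoupledResponse(omega=float(omega), velocity=v, pressure=p)

    # -- extraction ---------------------------------------------------------

    def observable_positions(self, margin: int = 1) -> tuple[float, float]:
        """Position range covered by mechanical elements (m)."""
        x = self.params.x
        return float(x[margin]), float(x[-1 - margin])

    def sweep(
        self,
        frequencies: Sequence[float],
        positions: Sequence[float] | None = None,
    ) -> pd.DataFrame:
        """Frequency sweep: tidy table of magnitude (dB re stapes velocity)
        and unwrapped phase (cycles) at the requested positions.

        Magnitude and phase are interpolated along x between mechanical
        element centres (elements 2 … N−1; the stapes and helicotrema rows
        are boundary elements, not BM observation points).
        """
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.size == 0:
            raise ValueError("empty frequency grid")
        x = self.params.x[1:-1]
        if positions is None:
            positions = x
        positions = np.asarray(positions, dtype=float)
        if positions.min() < x[0] or positions.max() > x[-1]:
            raise ValueError("observation positions outside the mechanical element range")
        rows = []
        for f_hz in frequencies:
            resp = self.solve(2.0 * np.pi * f_hz)
            v = resp.velocity[1:-1]
            mag = np.abs(v)
            with np.errstate(divide="ignore"):
                db = 20.0 * np.log10(mag)
            phase = np.unwrap(np.angle(v)) / (2.0 * np.pi)
            db_i = np.interp(positions, x, db)
            ph_i = np.interp(positions, x, phase)
            for pos, d, ph in zip(positions, db_i, ph_i):
                rows.append((f_hz, pos, d, ph))
        return pd.DataFrame(rows, columns=["frequency_hz", "position_m",
                                           "magnitude_db", "phase_cycles"])

    def profile(self, frequency_hz: float) -> pd.DataFrame:
        """Spatial response at a single frequency, one row per BM element."""
        resp = self.solve(2.0 * np.pi * frequency_hz)
        x = self.params.x[1:-1]
        v = resp.velocity[1:-1]
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.abs(v))
        return pd.DataFrame({
            "position_m": x,
            "magnitude_db": db,
            "phase_cycles": np.unwrap(np.angle(v)) / (2.0 * np.pi),
            "pressure_pa": np.abs(resp.pressure[1:-1]),
        })


def frequency_sweep(
    model: CochlearModel,
    frequencies: Sequence[float] | None = None,
    positions: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper around :meth:`CochlearModel.sweep`."""
    if frequencies is None:
        frequencies = default_frequency_grid()
    return model.sweep(frequencies, positions)
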