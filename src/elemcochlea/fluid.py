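"""Fluid-coupling matrices relating BM element velocities to modal pressures.

Three constructions of the N×N impedance matrix ``Z_FC`` (``p = Z_FC · v``)
are provided:

* **uniform 1D** — the finite-difference matrix ``F`` of the box model
  (``iω v = F p``) inverted, ``Z_FC = iω F⁻¹``.  Row 1 of ``F`` encodes the
  basal momentum boundary at the oval window, interior rows the discrete 1D
  wave operator, and the bottom-right element holds the small regularising
  value ``Δ²/h²`` that makes ``F`` invertible while the helicotrema
  pressure-release condition is imposed through the excitation vector.
* **non-uniform 1D** — tapered scalae: each column holds the far-field
  pressure due to one vibrating element, constant basal to the excitation and
  integrating the reciprocal effective area apically, reaching zero at the
  helicotrema.
* **3D** — a 1D construction plus a near-field correction: a decaying
  exponential around the excitation element with peak ``2iωρΔ`` and decay
  length ``0.12·W`` (fitted constants), capturing the local 3D pressure
  without resolving the cross-section.

All constructions are inertial, hence entrywise linear in ω.
Element indices in the public API are 1-based (n = 1 … N), matching the
conventions used throughout the cochlear-modelling literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CochleaParams, GeometryProfile

__all__ = [
    "FiniteDifferenceMatrix",
    "FluidCouplingMatrix",
    "NearFieldParams",
    "assemble_fd_matrix",
    "zfc_1d_uniform",
    "zfc_1d_nonuniform",
    "near_field_column",
    "zfc_3d",
]


@dataclass(frozen=True)
class FiniteDifferenceMatrix:
    """Real, frequency-independent matrix F with ``iω v = F p``."""

    matrix: np.ndarray
    rho: float
    height: float
    delta: float
    apex_reg: float

    @property
    def n_elements(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass(frozen=True)
class FluidCouplingMatrix:
    """Complex N×N matrix Z_FC at a single frequency: p = Z_FC · v."""

    matrix: np.ndarray
    omega: float
    mode: str  # "uniform-1d" | "nonuniform-1d" | "3d"

    @property
    def n_elements(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class NearFieldParams:
    """Fitted constants of the exponential near-field approximation."""

    peak_factor: float = 2.0   # peak pressure = peak_factor · iωρΔ per unit velocity
    decay_factor: float = 0.12  # decay length d = decay_factor · W

    def __post_init__(self) -> None:
        if self.peak_factor < 0 or self.decay_factor <= 0:
            raise ValueError("near-field peak factor must be >= 0 and decay factor > 0")


def assemble_fd_matrix(
    params: CochleaParams,
    height: float,
    apex_reg: float | None = None,
) -> FiniteDifferenceMatrix:
    """Assemble the 1D finite-difference fluid matrix F for a uniform duct.

    Interior rows carry the (1, −2, 1) second-difference stencil scaled by
    −h/(2ρΔ²); row 1 is the basal momentum boundary
    (p₂ − p₁)/Δ = −2iωρ v₁, i.e. F[1,1] = −F[1,2] = 1/(2ρΔ); row N holds only
    the regularising entry (default Δ²/h², exposed for sensitivity studies).
    """
    n = params.n_elements
    if n < 3:
        raise ValueError("the finite-difference fluid matrix needs N >= 3")
    if height <= 0:
        raise ValueError(f"effective height must be positive, got {height}")
    rho, delta = params.fluid_density, params.delta
    if apex_reg is None:
        apex_reg = delta**2 / height**2
    scale = -height / (2.0 * rho * delta**2)
    f = np.zeros((n, n))
    idx = np.arange(1, n - 1)
    f[idx, idx - 1] = scale
    f[idx, idx] = -2.0 * scale
    f[idx, idx + 1] = scale
    f[0, 0] = 1.0 / (2.0 * rho * delta)
    f[0, 1] = -1.0 / (2.0 * rho * delta)
    f[-1, :] = 0.0
    f[-1, -1] = scale * apex_reg
    return FiniteDifferenceMatrix(matrix=f, rho=rho, height=float(height),
                                  delta=delta, apex_reg=float(apex_reg))


def zfc_1d_uniform(fd: FiniteDifferenceMatrix, omega: float) -> FluidCouplingMatrix:
    """Uniform 1D fluid coupling, Z_FC = iω F⁻¹.

    Column n₀ is the pressure distribution due to unit velocity of element
    n₀ alone: constant basal to the excitation, decaying linearly to zero at
    the helicotrema.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return FluidCouplingMatrix(matrix=1j * omega * fd.inverse, omega=float(omega),
                               mode="uniform-1d")


def zfc_1d_nonuniform(
    geometry: GeometryProfile,
    params: CochleaParams,
    omega: float,
) -> FluidCouplingMatrix:
    """Non-uniform (tapered-scalae) 1D fluid coupling, built column by column.

    Column n₀ (a BM element, 2 ≤ n₀ ≤ N−1) holds the discrete far-field
    pressure per unit element velocity,

        p(n) = 2iωρΔ · [W(n₀)B(n₀) / (W(n)B(n))] · Σ_{n'=max(n,n₀)}^{N−1} Δ/h_e(n'),

    with h_e = π²A_e/8B the effective height from the harmonic-mean scala
    area: constant basal to the excitation and falling to exactly zero at the
    helicotrema.  In the uniform-geometry limit this reproduces the uniform
    construction iωF⁻¹ exactly, element for element.  Column 1 is the tapered
    stapes (boundary) drive, p(n) = 2iωρΔ·Σ_{n'=n}^{N−1} A_e(1)/A_e(n');
    column N (helicotrema element) is identically zero, so this matrix is
    used only through the velocity-route solver, never inverted.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    n = geometry.n_elements
    if n != params.n_elements:
        raise ValueError("geometry and params disagree on N")
    if np.any(geometry.area_effective <= 0):
        raise ValueError("effective area must be strictly positive")
    delta, rho = params.delta, params.fluid_density
    h_e = np.pi**2 * geometry.area_effective / (8.0 * geometry.bm_width)

    # tail[i] = sum_{i'=i}^{N-2} delta / h_e[i']   (0-based; tail[N-1] = 0)
    inv_h = delta / h_e
    tail = np.zeros(n)
    tail[:-1] = np.cumsum(inv_h[:-1][::-1])[::-1]

    i = np.arange(n)
    upper = np.maximum.outer(i, i)          # max(row, col)
    wb = geometry.partition_width * geometry.bm_width
    z = (2j * omega * rho * delta) * (wb[None, :] / wb[:, None]) * tail[upper]

    # column 1: stapes boundary drive (duct pressure, no modal W,B ratio)
    ratio = geometry.area_effective[0] / geometry.area_effective
    stapes_tail = np.zeros(n)
    stapes_tail[:-1] = np.cumsum((delta / delta) * ratio[:-1][::-1])[::-1]
    z[:, 0] = 2j * omega * rho * delta * stapes_tail
    # column N: helicotrema element, never driven (v_N = 0 in every solve)
    z[:, -1] = 0.0
    return FluidCouplingMatrix(matrix=z, omega=float(omega), mode="nonuniform-1d")


def near_field_column(
    n0: int,
    omega: float,
    rho: float,
    delta: float,
    n_elements: int,
    partition_width: float,
    nf: NearFieldParams | None = None,
) -> np.ndarray:
    """Near-field pressure column for excitation at element n₀ (1-based).

    Entry n is (peak factor)·iωρΔ·exp(−|n−n₀|Δ/(decay factor·W)): symmetric
    about the excitation element, peak 2iωρΔ with the default constants.
    """
    nf = nf or NearFieldParams()
    if not 1 <= n0 <= n_elements:
        raise ValueError(f"n0 must be in 1..{n_elements}, got {n0}")
    if partition_width <= 0:
        raise ValueError("partition width must be positive")
    n = np.arange(1, n_elements + 1)
    decay = np.exp(-np.abs(n - n0) * delta / (nf.decay_factor * partition_width))
    return nf.peak_factor * 1j * omega * rho * delta * decay


def zfc_3d(
    base: FluidCouplingMatrix,
    geometry: GeometryProfile,
    omega: float,
    nf: NearFieldParams | None = None,
    rho: float = 1000.0,
    delta: float | None = None,
) -> FluidCouplingMatrix:
    """3D fluid coupling: a 1D construction plus the near-field correction.

    Column n₀'s near field uses the partition width at the excitation
    element, W(n₀).  The correction is applied to BM-element columns
    2 … N−1 only (column 1 is the oval-window boundary, column N the
    helicotrema) and its bottom row is zeroed so that the pressure-release
    condition at the helicotrema is preserved exactly.
    """
    nf = nf or NearFieldParams()
    if base.mode == "3d":
        raise ValueError("base matrix is already a 3D construction")
    if not np.isclose(base.omega, omega):
        raise ValueError(f"base matrix built at omega={base.omega}, requested {omega}")
    n = base.n_elements
    if geometry.n_elements != n:
        raise ValueError("geometry and base matrix disagree on N")
    if delta is None:
        raise ValueError("element length delta is required")
    idx = np.arange(1, n + 1)
    sep = np.abs(idx[:, None] - idx[None, :]) * delta          # |n - n0|·Δ
    d = nf.decay_factor * geometry.partition_width[None, :]     # per-column decay, W(n0)
    nf_matrix = nf.peak_factor * 1j * omega * rho * delta * np.exp(-sep / d)
    nf_matrix[:, 0] = 0.0
    nf_matrix[:, -1] = 0.0
    nf_matrix[-1, :] = 0.0
    return FluidCouplingMatrix(matrix=base.matrix + nf_matrix, omega=float(omega),
                               mode="3d")
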