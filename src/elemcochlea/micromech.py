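"""Basilar-membrane micromechanics: admittance and impedance matrices.

The BM element at position x_n is a passive single-degree-of-freedom
resonator per unit area, with admittance

    Y_BM(n) = iω / (iω r_n − ω² m_n + s_n),

so its velocity responds only to the local pressure difference
(locally-reacting case, diagonal Y_BM).  Two non-local generalisations are
provided at the impedance level: symmetric longitudinal coupling (adjacent
elements joined by a stiffness k_L and damper c_L, giving a tri-diagonal
Z_BM) and unidirectional feedforward coupling along the organ of Corti
(Deiters'-cell/phalangeal-process geometry, giving a lower-bidiagonal Z_BM).
Inverting the mechanical sub-block of Z_BM yields the Y_BM required by the
coupled solver.

Sign convention: a positive pressure difference drives the BM downward while
velocities are taken upward, so v = −Y_BM·p and p = −Z_BM·v element-wise;
row N of every admittance matrix is zero (helicotrema) and entry (1,1)
carries the middle-ear admittance when middle-ear loading is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import BmElementParams

__all__ = [
    "MiddleEarParams",
    "CouplingParams",
    "BmAdmittanceMatrix",
    "local_admittance",
    "middle_ear_admittance",
    "ybm_local",
    "zbm_longitudinal",
    "zbm_feedforward",
    "ybm_from_impedance",
]


@dataclass(frozen=True)
class MiddleEarParams:
    """Single-DOF admittance looking into the middle ear from the cochlea
    (per unit stapes-footplate area).  Disabled by default, which recovers
    the unloaded stapes drive v₁ = v_st."""

    enabled: bool = False
    mass: float = 0.0
    stiffness: float = 0.0
    damping: float = 0.0

    def __post_init__(self) -> None:
        if self.enabled and min(self.mass, self.stiffness, self.damping) <= 0:
            raise ValueError("enabled middle ear requires positive mass, stiffness, damping")


@dataclass(frozen=True)
class CouplingParams:
    """Non-local BM coupling: stiffness/damping expressed as fractions of the
    local k_n, c_n.  The longitudinal and feedforward mechanisms are mutually
    exclusive alternatives to the locally-reacting model."""

    mode: Literal["local", "longitudinal", "feedforward"] = "local"
    stiffness_fraction: float = 0.0
    damping_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("local", "longitudinal", "feedforward"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")
        if self.stiffness_fraction < 0 or self.damping_fraction < 0:
            raise ValueError("coupling fractions must be >= 0")

    @classmethod
    def longitudinal_default(cls) -> "CouplingParams":
        """Illustrative 10% symmetric longitudinal coupling."""
        return cls(mode="longitudinal", stiffness_fraction=0.1, damping_fraction=0.1)

    @classmethod
    def feedforward_default(cls) -> "CouplingParams":
        """Illustrative 50% feedforward coupling."""
        return cls(mode="feedforward", stiffness_fraction=0.5, damping_fraction=0.5)


@dataclass(frozen=True)
class BmAdmittanceMatrix:
    """N×N complex BM admittance at one frequency; v = −Y_BM·p."""

    matrix: np.ndarray
    omega: float
    structure: str  # "diagonal" | "inverse-tridiagonal" | "inverse-bidiagonal"

    @property
    def n_elements(self) -> int:
        return int(self.matrix.shape[0])


def local_admittance(omega, mass, stiffness, damping):
    """Single-DOF BM admittance Y = iω/(iωr − ω²m + s); vectorised.

    Purely real (1/r) at resonance ω = sqrt(s/m); stiffness-dominated
    (|Y| → 0) as ω → 0.  The denominator cannot vanish for r > 0 and real ω.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("omega must be positive")
    y = 1j * omega / (1j * omega * damping - omega**2 * mass + stiffness)
    return complex(y) if y.ndim == 0 else y


def middle_ear_admittance(omega: float, me: MiddleEarParams | None) -> complex:
    """Y_ME(ω) of the single-DOF middle-ear model, or 0 when disabled."""
    if me is None or not me.enabled:
        return 0.0 + 0.0j
    return complex(local_admittance(omega, me.mass, me.stiffness, me.damping))


def ybm_local(
    omega: float,
    elements: BmElementParams,
    me: MiddleEarParams | None = None,
) -> BmAdmittanceMatrix:
    """Locally-reacting (diagonal) BM admittance matrix.

    Mechanical elements occupy n = 2 … N−1; entry (1,1) is the middle-ear
    admittance (0 when disabled, recovering v₁ = v_s(1)); row N is zero,
    preserving the helicotrema condition.
    """
    n = elements.n_elements
    y = np.zeros((n, n), dtype=complex)
    idx = np.arange(1, n - 1)
    y[idx, idx] = local_admittance(omega, elements.mass[idx],
                                   elements.stiffness[idx], elements.damping[idx])
    y[0, 0] = middle_ear_admittance(omega, me)
    return BmAdmittanceMatrix(matrix=y, omega=float(omega), structure="diagonal")


def _pair_coupling(omega: float, elements: BmElementParams,
                   coupling: CouplingParams) -> np.ndarray:
    """Coupling impedance c_L + k_L/(iω) of the coupler between elements
    n and n+1 (length N−1).  Fractions are applied to the geometric mean of
    the two elements' k_n, c_n so the assembled matrix is exactly symmetric
    even on the exponentially varying stiffness profile."""
    k = np.sqrt(elements.stiffness[:-1] * elements.stiffness[1:]) * coupling.stiffness_fraction
    c = np.sqrt(elements.damping[:-1] * elements.damping[1:]) * coupling.damping_fraction
    return c + k / (1j * omega)


def zbm_longitudinal(
    omega: float,
    elements: BmElementParams,
    coupling: CouplingParams,
) -> np.ndarray:
    """Tri-diagonal BM impedance matrix with symmetric longitudinal coupling.

    Diagonal: iωm_n + c_n + Σ c_L + (k_n + Σ k_L)/(iω), summing the one or
    two couplers attached to the element (one-sided at the first and last
    mechanical elements — no force from beyond the BM ends); off-diagonals:
    −(c_L + k_L/iω).  A rigid-body (constant) velocity pattern sees no
    coupling forces.  Rows/columns 1 and N (stapes, helicotrema) are zero.
    """
    if coupling.mode != "longitudinal":
        raise ValueError(f"coupling mode must be 'longitudinal', got {coupling.mode!r}")
    n = elements.n_elements
    z = np.zeros((n, n), dtype=complex)
    idx = np.arange(1, n - 1)
    z_local = (1j * omega * elements.mass[idx] + elements.damping[idx]
               + elements.stiffness[idx] / (1j * omega))
    z[idx, idx] = z_local
    zl = _pair_coupling(omega, elements, coupling)  # coupler (i, i+1), 0-based
    # couplers internal to the mechanical range 2..N-1 (0-based 1..n-2)
    for i in range(1, n - 2):
        z[i, i] += zl[i]
        z[i + 1, i + 1] += zl[i]
        z[i, i + 1] -= zl[i]
        z[i + 1, i] -= zl[i]
    return z


def zbm_feedforward(
    omega: float,
    elements: BmElementParams,
    coupling: CouplingParams,
) -> np.ndarray:
    """Lower-bidiagonal BM impedance for unidirectional feedforward coupling.

    Diagonal: the local impedance; subdiagonal (n, n−1): −(c_FF + k_FF/iω)
    built from the feedforward fractions of the local stiffness and damping
    (no mass term).  The admittance obtained by inversion spreads only
    apically of the forcing element.
    """
    if coupling.mode != "feedforward":
        raise ValueError(f"coupling mode must be 'feedforward', got {coupling.mode!r}")
    n = elements.n_elements
    z = np.zeros((n, n), dtype=complex)
    idx = np.arange(1, n - 1)
    z[idx, idx] = (1j * omega * elements.mass[idx] + elements.damping[idx]
                   + elements.stiffness[idx] / (1j * omega))
    zff = (elements.damping * coupling.damping_fraction
           + elements.stiffness * coupling.stiffness_fraction / (1j * omega))
    for i in range(2, n - 1):  # pairs (i, i-1) inside the mechanical range
        z[i, i - 1] = -zff[i]
    return z


def ybm_from_impedance(
    z_bm: np.ndarray,
    omega: float,
    me: MiddleEarParams | None = None,
    structure: str = "inverse-tridiagonal",
    cond_limit: float = 1e12,
) -> BmAdmittanceMatrix:
    """Invert the mechanical sub-block (rows/cols 2 … N−1) of Z_BM and embed
    it in the N×N frame with the middle-ear (1,1) entry and zero row N."""
    n = z_bm.shape[0]
    sub = z_bm[1:-1, 1:-1]
    cond = np.linalg.cond(sub)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"BM impedance sub-block is ill-conditioned (cond={cond:.3e})")
    y = np.zeros((n, n), dtype=complex)
    y[1:-1, 1:-1] = np.linalg.inv(sub)
    y[0, 0] = middle_ear_admittance(omega, me)
    return BmAdmittanceMatrix(matrix=y, omega=float(omega), structure=structure)
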