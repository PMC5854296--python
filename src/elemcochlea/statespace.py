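"""Time-domain state-space formulation of the coupled elemental model.

Each mechanical BM element (n = 2 … N−1) contributes two real states,
velocity and displacement, in companion form; the fluid coupling enters
through the real, frequency-independent finite-difference matrix F
(F·p = v̇ + v̇_s), giving the coupled real system

    ẋ = A x + B u,     A = [I − B_E F⁻¹ C_E]⁻¹ A_E,
                        B = [I − B_E F⁻¹ C_E]⁻¹ B_E,    u = F⁻¹ v̇_s,

where A_E, B_E, C_E are block matrices of the uncoupled element models and
v̇_s carries the stapes acceleration in element 1.  For passive parameters
all eigenvalues of A lie strictly in the left half-plane, so the model is
stable and the formulation doubles as a stability analysis of the linear
model; per-element output feedback through C_E is the hook where local
nonlinearities could be injected.

A stapes *velocity* impulse is realised either as the equivalent initial
condition x(0⁺) = A·B·F⁻¹e₁ (exact for t > 0) or as a short rectangular
velocity pulse fed through the exactly discretised input — the two agree to
integration tolerance and that agreement is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .fluid import FiniteDifferenceMatrix
from .micromech import MiddleEarParams
from .params import BmElementParams, CochleaParams

__all__ = [
    "StateSpaceSystem",
    "TimeSimulation",
    "StabilityReport",
    "element_state_space",
    "assemble_global",
    "stability_report",
    "impulse_initial_state",
    "simulate_impulse",
    "snapshots",
    "total_energy",
]


def element_state_space(mass: float, stiffness: float, damping: float):
    """Companion-form single-DOF element: states (velocity, displacement).

    Returns (A_n, B_n, C_n) with A_n = [[−c/m, −k/m], [1, 0]], input scaling
    1/m on the velocity state, and output selecting the velocity state.  The
    eigenvalues of A_n are the roots of mλ² + cλ + k = 0.

    Negative damping is admitted (it is the standard way to model active
    outer-hair-cell force injection and to probe stability); mass and
    stiffness must be positive.
    """
    if mass <= 0 or stiffness <= 0 or not np.isfinite(damping):
        raise ValueError("element mass and stiffness must be positive, damping finite")
    a = np.array([[-damping / mass, -stiffness / mass], [1.0, 0.0]])
    b = np.array([[1.0 / mass], [0.0]])
    c = np.array([[1.0, 0.0]])
    return a, b, c


@dataclass(frozen=True)
class StateSpaceSystem:
    """Coupled real state-space model of the passive cochlea.

    ``a`` is 2M×2M (M dynamic elements), ``b`` maps the N-vector u = F⁻¹v̇_s
    into the states, ``c_full`` maps states to the full N-vector of element
    velocities (zero rows at the stapes and helicotrema elements), and
    ``f_inv`` is the stored inverse of the fluid matrix.
    """

    a: np.ndarray
    b: np.ndarray
    c_full: np.ndarray
    f_inv: np.ndarray
    params: CochleaParams
    dynamic_elements: np.ndarray  # 0-based indices of elements carrying states
    state_mass: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    state_stiffness: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    fluid_mass: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_states(self) -> int:
        return int(self.a.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.c_full.shape[0])

    def transfer(self, omega: float) -> np.ndarray:
        """Frequency response from unit stapes velocity to element
        velocities: C_E(iωI − A)⁻¹(iω)B·F⁻¹e₁ plus the direct feedthrough."""
        e1 = np.zeros(self.n_elements)
        e1[0] = 1.0
        bu = self.b @ (self.f_inv @ e1)
        core = np.linalg.solve(1j * omega * np.eye(self.n_states) - self.a,
                               self.a @ bu)
        return self.c_full @ (core + bu)


def assemble_global(
    params: CochleaParams,
    elements: BmElementParams,
    fd: FiniteDifferenceMatrix,
    me: MiddleEarParams | None = None,
    damping_override: np.ndarray | None = None,
) -> StateSpaceSystem:
    """Couple the element state-space blocks through the fluid matrix F.

    Mechanical elements n = 2 … N−1 carry states; element 1 additionally
    carries a two-state middle-ear block when enabled, and element N
    (helicotrema) never does.  The pressure input blocks are negated when
    placed in B_E because a positive pressure difference drives the BM
    downward while element velocities are taken upward (v = −Y·p).

    ``damping_override`` replaces the per-element damping array, admitting
    negative entries to model active force injection or to construct
    stability counterexamples.
    """
    n = params.n_elements
    if elements.n_elements != n or fd.n_elements != n:
        raise ValueError("params, elements and F disagree on N")
    damping = elements.damping if damping_override is None else np.asarray(damping_override, float)
    if damping.shape != (n,):
        raise ValueError("damping_override must have length N")
    dyn = list(range(1, n - 1))
    blocks: list[tuple[int, float, float, float]] = [
        (i, elements.mass[i], elements.stiffness[i], damping[i]) for i in dyn
    ]
    if me is not None and me.enabled:
        blocks.insert(0, (0, me.mass, me.stiffness, me.damping))
        dyn = [0] + dyn
    m_dyn = len(blocks)
    n_states = 2 * m_dyn
    a_e = np.zeros((n_states, n_states))
    b_e = np.zeros((n_states, n))
    c_e = np.zeros((n, n_states))
    for k, (i, m, s, r) in enumerate(blocks):
        an, bn, cn = element_state_space(m, s, r)
        sl = slice(2 * k, 2 * k + 2)
        a_e[sl, sl] = an
        b_e[sl, i] = -bn[:, 0]  # pressure sign convention (v = −Y·p)
        c_e[i, sl] = cn[0, :]
    f_inv = np.linalg.inv(fd.matrix)
    coupling = np.eye(n_states) - b_e @ f_inv @ c_e
    try:
        a = scipy.linalg.solve(coupling, a_e)
        b = scipy.linalg.solve(coupling, b_e)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - assembly bug guard
        raise np.linalg.LinAlgError(f"inconsistent coupling assembly: {exc}") from exc
    fluid_mass = 0.5 * (f_inv + f_inv.T)  # symmetrised fluid inertance (mass per area)
    return StateSpaceSystem(a=a, b=b, c_full=c_e, f_inv=f_inv, params=params,
                            dynamic_elements=np.asarray(dyn),
                            state_mass=np.array([blk[1] for blk in blocks]),
                            state_stiffness=np.array([blk[2] for blk in blocks]),
                            fluid_mass=fluid_mass)


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    spectral_abscissa: float
    unstable_count: int

    @property
    def stable(self) -> bool:
        return self.spectral_abscissa < 0.0


def stability_report(sys: StateSpaceSystem) -> StabilityReport:
    """Eigenvalue summary of the coupled A matrix: spectral abscissa and the
    number of right-half-plane modes."""
    eig = np.linalg.eigvals(sys.a)
    return StabilityReport(
        eigenvalues=eig,
        spectral_abscissa=float(np.max(eig.real)),
        unstable_count=int(np.sum(eig.real >= 0.0)),
    )


def impulse_initial_state(sys: StateSpaceSystem, amplitude: float = 1.0) -> np.ndarray:
    """Equivalent initial condition of a stapes velocity impulse of area
    ``amplitude`` (m·s⁻¹·s): x(0⁺) = amplitude·A·B·F⁻¹e₁."""
    e1 = np.zeros(sys.n_elements)
    e1[0] = 1.0
    return amplitude * (sys.a @ (sys.b @ (sys.f_inv @ e1)))


@dataclass(frozen=True)
class TimeSimulation:
    """Uniformly sampled element-velocity histories."""

    time: np.ndarray
    velocity: np.ndarray  # (n_samples, N)
    sample_rate: float
    stimulus: str

    @property
    def n_samples(self) -> int:
        return int(self.time.shape[0])


def _check_stable(sys: StateSpaceSystem) -> None:
    report = stability_report(sys)
    if not report.stable:
        raise RuntimeError(
            "refusing to simulate an unstable system: spectral abscissa "
            f"{report.spectral_abscissa:.4g} 1/s, {report.unstable_count} "
            "right-half-plane eigenvalue(s)")


def simulate_impulse(
    sys: StateSpaceSystem,
    duration: float,
    sample_rate: float | None = None,
    method: str = "ic",
    amplitude: float = 1.0,
    check_stability: bool = True,
) -> TimeSimulation:
    """Simulate the response to a stapes velocity impulse.

    Exact discretisation over a fixed step (matrix exponential stepping);
    the default sample rate is 4·f_B, the enforced minimum.  ``method='ic'``
    uses the equivalent-initial-condition realisation (exact for t > 0);
    ``method='pulse'`` feeds a one-sample rectangular velocity pulse of unit
    area through the zero-order-hold discretised input, which approximates
    an impulse centred half a sample later.
    """
    if sample_rate is None:
        sample_rate = 4.0 * sys.params.f_base
    if sample_rate < 4.0 * sys.params.f_base:
        raise ValueError("sample rate must be at least 4×f_B")
    if check_stability:
        _check_stable(sys)
    dt = 1.0 / sample_rate
    n_samples = int(np.ceil(duration * sample_rate)) + 1
    time = np.arange(n_samples) * dt
    phi = scipy.linalg.expm(sys.a * dt)
    x = np.zeros(sys.n_states)
    velocity = np.zeros((n_samples, sys.n_elements))
    if method == "ic":
        x = impulse_initial_state(sys, amplitude)
    elif method == "pulse":
        # stapes velocity = amplitude/dt over one sample; its ZOH-discretised
        # acceleration input is a step up at t=0 and down at t=dt
        e1 = np.zeros(sys.n_elements)
        e1[0] = 1.0
        b_eff = sys.b @ (sys.f_inv @ e1)
        bd = np.linalg.solve(sys.a, (phi - np.eye(sys.n_states)) @ b_eff)
        w = amplitude / dt**2
        velocity[0] = sys.c_full @ x
        x = phi @ x + bd * w          # step 0 -> 1: v̇_st = +amp/dt²
        velocity[1] = sys.c_full @ x
        x = phi @ x + bd * (-w)       # step 1 -> 2: v̇_st = −amp/dt²
        for k in range(2, n_samples):
            velocity[k] = sys.c_full @ x
            x = phi @ x
        return TimeSimulation(time=time, velocity=velocity, sample_rate=sample_rate,
                              stimulus=f"stapes velocity pulse (ZOH), area {amplitude}")
    else:
        raise ValueError(f"unknown method {method!r}")
    for k in range(n_samples):
        velocity[k] = sys.c_full @ x
        x = phi @ x
    return TimeSimulation(time=time, velocity=velocity, sample_rate=sample_rate,
                          stimulus=f"stapes velocity impulse (IC), area {amplitude}")


def snapshots(
    sys: StateSpaceSystem,
    times: Sequence[float],
    amplitude: float = 1.0,
    check_stability: bool = True,
) -> np.ndarray:
    """Instantaneous BM velocity distributions at the requested instants (s)
    after a stapes velocity impulse, via the exact matrix exponential."""
    if check_stability:
        _check_stable(sys)
    x0 = impulse_initial_state(sys, amplitude)
    out = np.empty((len(times), sys.n_elements))
    for k, t in enumerate(times):
        if t < 0:
            raise ValueError("snapshot times must be non-negative")
        out[k] = sys.c_full @ (scipy.linalg.expm(sys.a * t) @ x0)
    return out


def total_energy(sys: StateSpaceSystem, x: np.ndarray,
                 include_fluid: bool = True) -> float:
    """Total mechanical energy per unit BM area in state ``x``: element
    kinetic (½mv²) and elastic (½kd²) energy, plus the fluid kinetic term
    ½vᵀM_f v through the symmetrised fluid inertance matrix M_f = −sym(F⁻¹)
    (mass-per-area units, positive for the BM-driven velocity patterns)."""
    vel = x[0::2]
    disp = x[1::2]
    energy = 0.5 * float(vel @ (sys.state_mass * vel) + disp @ (sys.state_stiffness * disp))
    if include_fluid:
        v_full = sys.c_full @ x
        energy += 0.5 * float(v_full @ (sys.fluid_mass @ v_full))
    return energy
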