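# Methods

## Model

The package simulates the passive mechanics of an uncoiled cochlea as a set
of N discrete elements along the longitudinal coordinate x.  A single
transverse mode of basilar-membrane (BM) motion is assumed per element, so
the state of the system at one frequency is a pair of complex N-vectors:
the modal pressure difference p between the two fluid chambers and the modal
BM velocity v.  Two constitutive relations close the problem,

    p = Z_FC · v           and          v = v_s − Y_BM · p,

where Z_FC is the fluid-coupling impedance matrix, Y_BM the BM admittance
matrix, and v_s the excitation vector holding the stapes velocity in element
1 (internal excitations may be placed in other entries; the helicotrema
entry N is always zero).  The coupled solution is
v = [I + Y_BM Z_FC]⁻¹ v_s.  The sign convention is that a positive pressure
difference drives the BM downward while v is counted upward, hence the
minus sign.

Assumptions: quasi-linear response at a single frequency (the frequency
solver), passive micromechanics (single degree of freedom per element — no
outer-hair-cell amplification; the state-space element feedback is the hook
where an active or nonlinear force could be injected), incompressible fluid
(only the slow wave is modelled, no compressional fast wave), and an
uncoiled geometry.

## Element grid and boundaries

Elements are centred at x_n = nΔ with Δ = L/N, n = 1…N.  Element 1 is the
stapes/oval-window boundary (it carries no BM dynamics; with middle-ear
loading disabled its velocity equals the drive), element N is the
helicotrema, and elements 2…N−1 are mechanical BM elements.  All public
element indices are 1-based, matching this convention; arrays are 0-based
internally.

The helicotrema is a pressure release: p_N = 0.  It is imposed through the
structure of the equations — the bottom row of Y_BM is zero and the bottom
row of the fluid finite-difference matrix F holds a single regularising
entry (Δ²/h², configurable), so a zero N-th entry of v_s forces p_N = 0
while keeping F invertible.

## Fluid coupling

**Uniform 1D.**  Z_FC = iωF⁻¹ with F real and frequency independent:
interior rows carry the second-difference stencil scaled by −h/(2ρΔ²)
(h = π²A/8B is the effective duct height translating scala area A and BM
width B into series inertance), row 1 the basal momentum boundary
(p₂−p₁)/Δ = −2iωρv₁.  A column of Z_FC — the pressure due to one vibrating
element — is constant basal to the excitation, decays linearly apically and
reaches zero at the helicotrema; the closed form of the basal value,
2iωρΔ²(N−n₀)/h, is verified in the tests.

**Non-uniform (tapered) 1D.**  Columns are built directly from the
far-field solution on tapered scalae:

    p(n) = 2iωρΔ · [W(n₀)B(n₀)/(W(n)B(n))] · Σ_{n'=max(n,n₀)}^{N−1} Δ/h_e(n'),

with h_e = π²A_e/8B and A_e the harmonic mean of the two scala areas.  The
factor convention (the prefactor 2iωρΔ together with sums of Δ/h_e running
to N−1) is fixed so that the uniform-geometry limit reproduces the uniform
construction iωF⁻¹ *exactly*, element for element — this is the invariant
that disambiguates the otherwise convention-dependent constants, and it is
asserted in the tests.  Column 1 is the tapered boundary drive
p(n) = 2iωρΔ·Σ A_e(1)/A_e(n') (a duct pressure, so no modal W·B ratio);
column N is identically zero because the helicotrema element is never
driven (v_N ≡ 0), so this matrix is used only through the velocity-route
solver and never inverted.

**3D near field.**  The 3D correction adds to each BM-element column an
exponential near-field, entry n = (peak)·iωρΔ·exp(−|n−n₀|Δ/(decay·W(n₀))),
with fitted constants peak = 2 and decay = 0.12 (both exposed as
parameters).  The decay length uses the partition width at the *excitation*
element, since the near field is local to it.  The bottom row of the
correction is zeroed (pressure release also kills the near field at the
helicotrema) and columns 1 and N receive no correction (oval-window and
helicotrema boundaries are not vibrating BM elements).  With the 3D
construction the BM mass default drops from 0.28 kg/m² to 0.05 kg/m²: the
1D value folds the entrained fluid layer into the micromechanics, the 3D
value is the bare organ-of-Corti mass.

## Micromechanics

Local admittance Y(ω) = iω/(iωr − ω²m + s) per unit area, with m = m₀
constant, s(x) = (2πf(x))²m₀ on the tonotopic map f(x) = f_B e^(−x/l), and
r = √(sm)/Q₀ for constant quality factor.  Human defaults: f_B = 20 kHz,
l = 7 mm, Q₀ = 2.5.

Longitudinal coupling joins adjacent elements with a stiffness k_L and
damper c_L expressed as fractions (default 10%, an illustrative choice) of
the local k_n, c_n, giving a tri-diagonal impedance matrix with
off-diagonals −(c_L + k_L/iω).  Because k_n varies exponentially along x,
the coupler between elements n and n+1 uses fractions of the *geometric
mean* √(k_n k_{n+1}) so the matrix is exactly symmetric; for uniform
stiffness this reduces to the plain fraction.  End elements couple to a
single neighbour (no force from beyond the BM ends).  A rigid-body velocity
pattern feels no coupling forces — asserted as a test.

Feedforward coupling (the unidirectional push of the outer-hair-cell /
Deiters'-cell geometry) puts −(c_FF + k_FF/iω) on the subdiagonal only
(default fractions 50%, chosen large to make the effect visible); no mass
enters the feedforward term.  The resulting admittance, obtained by
inverting the mechanical sub-block (rows/columns 2…N−1), spreads only
apically of a forced element, whereas the symmetric coupling spreads both
ways — the structural signature asserted in the tests.  The feedforward
length scale equals one element (≈68 μm at N = 512), which is coarser than
the ≈20 μm anatomical span of the phalangeal processes; the model couples
adjacent *model* elements and should be read accordingly.

Middle-ear loading is a single-DOF admittance at entry (1,1) of Y_BM.  It
is disabled by default (unloaded stapes drive, v₁ = v_st) because no
defensible default constants ship with the package; a config block accepts
user values for mass, stiffness and damping per unit area.

## Frequency solver

With uniform 1D fluid coupling and a diagonal Y_BM the coupled equations
are solved in pressure form, (F/iω + Y_BM)p = v_s, as a banded tridiagonal
system — identical mathematics to the dense route at O(N) cost per
frequency, which keeps full sweeps at N = 1024 in the sub-second range.
All other modes use the dense direct solve of [I + Y_BM Z_FC]v = v_s with a
condition-number guard (limit 10¹³).  The ladder-network (transmission-line)
solver assembles the same physics from the network side — series inertances
L = 2ρΔ²/h and L₁ = 2ρΔ, shunt admittances, short-circuited apex — through
an independent banded path, and agrees with the dense elemental route to
better than 10⁻⁸ relative error; the two serve as mutual oracles.

Reported responses are normalised to unit stapes velocity (absolute
calibration is out of scope); sweep tables are tidy CSV/HDF5 with columns
frequency_hz, position_m, magnitude_db, phase_cycles.  Magnitude and phase
are interpolated along x between mechanical element centres; the stapes and
helicotrema rows are boundary entries, not observation points.  The default
grid is logarithmic, 100 points/decade over 0.1–20 kHz.

## Time domain

Each mechanical element contributes two states (velocity, displacement) in
companion form, A_n = [[−c/m, −k/m], [1, 0]], input 1/m, output the
velocity state.  The fluid enters through F: writing F p = v̇ + v̇_s and
eliminating p yields the real coupled system

    ẋ = A x + B u,   A = [I − B_E F⁻¹ C_E]⁻¹ A_E,   u = F⁻¹ v̇_s,

where the element input blocks are negated when placed in B_E so that each
element responds as v = −Y·p, consistent with the frequency-domain sign
convention (verified by the time/frequency mutual oracle: the state-space
transfer function matches the frequency solver to <1% over 0.1–10 kHz, and
the Fourier transform of the simulated impulse response matches it within
a fraction of a dB across the 60 dB band of each element).  An enabled
middle ear adds one two-state block for element 1.

A stapes *velocity* impulse is realised either as the equivalent initial
condition x(0⁺) = A·B·F⁻¹e₁ — exact for t > 0, with the instantaneous
fluid-borne feedthrough C_E·B·F⁻¹e₁·δ(t) accounted for when spectra are
formed — or as a one-sample rectangular velocity pulse fed through the
zero-order-hold discretised input.  The two agree to O(dt²) once the pulse
has completed (from the second sample), and that agreement is a test.
Integration is exact discretisation: x_{k+1} = e^{AΔt}x_k with the matrix
exponential computed once; snapshots at arbitrary instants use e^{At}
directly.  The output sample rate is at least 4·f_B (enforced); tests use
8–32·f_B where quadrature accuracy matters.

Stability is read from the eigenvalues of A: the passive human model at
N = 128 has spectral abscissa ≈ −3.8 s⁻¹ (stable); flipping the sign of a
single element's damping — the standard probe for active instability —
moves a conjugate pair into the right half-plane and is flagged.
Simulation refuses unstable systems unless explicitly overridden.

The energy functional used for the decay test sums the element kinetic and
elastic terms ½mv² + ½kd² and the fluid kinetic term ½vᵀM_f v with
M_f = sym(F⁻¹), the symmetrised fluid inertance (positive definite on the
mechanical elements); it decays monotonically at 1 ms sampling in the
unforced passive system.

## Numerical convergence of the discretisation

Doubling the human preset from N = 512 to N = 1024 and comparing response
magnitudes at coincident element centres (every coarse centre nΔ is a fine
centre, so no interpolation enters) gives a maximum change below 0.06 dB
for all frequencies up to ≈12 kHz — the regime of the classic example
curves.  Approaching the 20 kHz base frequency, however, the change grows
to ≈0.8 dB: the difference is a near-constant dB offset along x that halves
when N doubles, i.e. first-order convergence originating in the one-sided
basal momentum boundary row (the condition is applied half a stencil inside
the duct), compounded by second-difference dispersion where the wavelength
approaches its ≈0.5 mm minimum.  This is a property of the discretisation
itself, not of the solver: a diagnostic run with a second-order boundary
row still leaves ≈0.6 dB at the band edge.  The acceptance script reports
this measured maximum over the full 0.1–20 kHz grid, excluding only points
more than 100 dB below the peak response (beyond the characteristic place
the passive response underflows double precision, so some dynamic-range
floor is a numerical necessity; 100 dB is far beyond any plotted range and
the reported value is insensitive to it between 60 and 140 dB).

## Problem sizes and test design

The frequency solver's unit tests run at N = 64–128 where the banded and
dense routes are both exercised; convergence and fluid-structure checks run
at the preset N = 512 (sub-second with the banded path).  Time-domain tests
use N = 64–128 (128–252 states), keeping eigen-decompositions and matrix
exponentials in the tens of milliseconds; these sizes resolve every
behaviour being asserted (travelling-wave snapshots, spectra, stability)
while keeping the full suite in a few seconds.  Property-based tests
(hypothesis, derandomised) cover the tonotopic-map bounds and the
ω-linearity of the inertial fluid constructions; randomised
transmission-line comparisons draw ten passive parameter sets from wide
physical ranges with a fixed seed.

All verification inputs are generated internally from the parameter preset;
nothing is fitted to data.  Consequently the tests demonstrate internal
consistency (mutual oracles, structural invariants, closed forms) and
faithfulness to the stated model — not agreement with physiological
measurements: the model is passive, so its peaks are broader, lower and
more basal than a living cochlea's, and no nonlinear compression is
present.

## Known limitations

* Passive only; the state-space feedback hook exists but no active
  micromechanical model is shipped.
* The basal boundary discretisation limits magnitude convergence to first
  order within the top half-octave below f_B (see above).
* The tapered fluid construction yields a singular Z_FC (zero helicotrema
  column) by design; pressure-route solves through [Z_FC⁻¹ + Y_BM]⁻¹ are
  only available in uniform mode.
* The transmission-line solver requires uniform 1D + locally-reacting
  settings and refuses anything else.
* Feedforward coupling acts at the model grid scale, not the anatomical
  ≈20 μm scale.
* No cochlear coiling, no fast (compressional) wave, no multi-DOF
  organ-of-Corti micromechanics.
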