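# Methods

## Bivariational time-dependent coupled-cluster dynamics

All five methods share one mathematical structure.  The right and left
states are parametrized independently,

    |Ψ(t)⟩ = e^κ̂(t) e^T̂(t) |Φ₀⟩ ,      ⟨Ψ̃(t)| = ⟨Φ₀| (λ₀ + Λ̂(t)) e^−T̂(t) e^−κ̂(t) ,

with |Φ₀⟩ a fixed reference determinant (occupied spin orbitals first,
then virtuals; nothing assumes canonical orbitals).  Stationarity of the
action with Lagrangian 𝓛 = ⟨Ψ̃|(i∂ₜ − Ĥ(t))|Ψ⟩ gives Hamilton-type
equations driven by the Hamilton function 𝓗(τ, λ; t) = ⟨Ψ̃|Ĥ(t)|Ψ⟩:

    i τ̇^μ = +∂𝓗/∂λ_μ ,      i λ̇_μ = −∂𝓗/∂τ^μ .

λ₀ is fixed to 1 once and for all (intermediate normalization ⟨Ψ̃|Ψ⟩ = 1
is preserved because λ₀ is a constant of motion); the phase τ₀ is
integrated as τ̇₀ = −i E(t) but never enters expectation values, which
use the effective one-body density γ = ∂𝓗/∂h̃: ⟨Ω̂⟩ = Σ_pq γ-weighted
dressed matrix elements.  The energy observable is Re 𝓗, which is a
constant of the field-free motion for every method (the amplitude flows
cancel pairwise and the orbital term vanishes by the cyclicity of the
trace).

### Method-specific Hamilton functions

**TDCCSD.**  Singles are absorbed by dressing the integrals with the
nilpotent similarity transform of T̂₁: h̃ = (1−x) h (1+x) and the
analogous four-index transform of the antisymmetrized two-electron
integrals, where x carries t₁ in its virtual–occupied block.  In the
dressed frame the Hamilton function is the exact flat polynomial

    𝓗 = Ẽ_ref + ¼ Σ ṽ_ijab t^ab_ij + Σ λ₁·r₁(t₂; h̃, ṽ) + ¼ Σ λ₂·r₂(t₂; h̃, ṽ),

with r₁, r₂ the CCD-form projections of e^−T₂ H̃ e^T₂ (the nested
commutator expansion terminates exactly at the terms kept; this was
verified symbol-free against dense determinant-space builds).

**TDCC2 / TDCC2-b.**  Same singles equations; the doubles commutator is
truncated to a one-body operator: the untransformed f + V(t) for TDCC2
(the zeroth-order Hamiltonian of the underlying perturbation partition,
so the time-dependent field is included), or the Fock matrix built from
the fully T1-transformed integrals for TDCC2-b.  The two variants have
identical amplitude and λ₂ flows at t₁ = 0 but different λ₁ flows there,
because their Hamilton functions carry different t₁-dependence.

**TDOMP2 / TDNOMP2.**  No singles; T̂ = τ₀ + T̂₂ and Λ̂ = λ₀ + Λ̂₂, and the
orbitals rotate in time.  The state stores accumulated orbital
coefficients Q (and Q_L for the non-unitary variant) rather than an
accumulated generator, so integrals are transformed to the co-moving
frame at every evaluation and all derivatives are taken at κ = 0, where
they are simplest.  The Hamilton function is the second-order truncation

    𝓗 = Ẽ_ref + ¼ Σ ṽ_ijab t^ab_ij + ¼ Σ λ₂ ( ṽ_abij + P(ab) Σ f̃ t₂ − P(ij) Σ f̃ t₂ ),

with f̃ the Fock matrix of the transformed (field-including) integrals.
For TDOMP2 the unitary rotation keeps the integrals Hermitian, which
makes λ₂ = t₂* an invariant of the flow and the densities Hermitian, so
only the t₂ equation is integrated; TDNOMP2 propagates t₂, λ₂ and both
orbital factors independently (and reduces to TDOMP2 on OMP2-consistent
data — this reduction is tested along kicked trajectories).

**Orbital equations.**  Euler–Lagrange stationarity with respect to the
rotation parameters yields, at κ = 0, the linear system

    i [γ, κ̇]_ov-block = ∂𝓗/∂κ_ov ,      i [γ, κ̇]_vo-block = ∂𝓗/∂κ_vo ,

where γ is the effective one-body density and the right-hand sides are
one-index-transform gradients of 𝓗.  Written out, the system matrix is
1j·(γ_oo ⊗ 1 − 1 ⊗ γ_vv), singular exactly when an occupied-block
eigenvalue of γ meets a virtual-block eigenvalue; the solver checks the
condition number (limit 1e12) and raises an error naming the smallest
singular value.  In the mean-field limit (v = 0) the equations reduce to
i κ̇_ia = h_ia, the exact one-determinant dynamics up to redundant
occupied–occupied/virtual–virtual rotations — a limit used as a test of
the normalization of the system.

### One source of equations

Every energy functional and residual is written once as a table of
tensor contractions (`rtcc.terms`): a term is a coefficient times named
factors with subscript strings whose letters encode occupied/virtual
blocks.  The λ equations of motion, the effective one- and two-body
densities, and the orbital/T1 gradients are *generated* from these
tables by the exact vector–Jacobian rule for einsum (derivative with
respect to one factor = contraction of the remaining factors), so there
is no second hand-derived set of equations to keep consistent.  The
tables themselves are validated against an independent dense
determinant-space implementation (`rtcc.fci`): projections
⟨Φ_μ|e^−T̂ Ĥ e^T̂|Φ₀⟩ built with matrix exponentials in the full CI space,
numerical gradients of the dense Hamilton function, and full-CI
propagation (CCSD is exact for two electrons, so the TDCCSD dipole
trajectory must match dense Schrödinger dynamics — it does, to ~1e−10
over 10 a.u. and well under 1e−6 over 50 a.u.).

## Ground states

- CC2/CCSD: quasi-Newton steps with Fock-diagonal denominators,
  accelerated by DIIS (subspace 8, error vectors = scaled residuals),
  then the linear λ equations by the same scheme; default residual-norm
  threshold 1e−10.  MP2 doubles (iterated when the Fock matrix is not
  diagonal) initialize t₂; λ is initialized at t*.
- OMP2: alternating t₂ updates and diagonal-Hessian orbital steps
  κ ← κ − g/max(2(ε_a − ε_i), 1e−3), the level shift guarding small
  gaps; the converged rotation is absorbed into the orbital basis.
  Stationarity is verified by numerical directional derivatives of the
  Lagrangian and by the invariance of the energy under occupied–occupied
  mixing of the reference.

## Propagation

s-stage Gauss–Legendre collocation (s ∈ {1,2,3}; order 2s), with nodes,
weights and the A matrix computed from the shifted Legendre roots by
exact polynomial integration.  The implicit stage equations are solved
by fixed-point iteration over the packed complex state vector
(concatenated τ₀, amplitudes, conjugate amplitudes, orbital
coefficients, in that fixed order) to a residual threshold of 1e−10,
seeded by an explicit-Euler predictor and warm-started from the previous
step's stages.  The external field is evaluated at the collocation stage
times, which is required for the full order with time-dependent
Hamiltonians.  Defaults follow the production protocol: s = 3,
Δt = 0.01 a.u.  The empirical order of the s = 3 scheme, measured by
Richardson extrapolation on a stiff field-free fixture (level spacing
~4 Hartree so the discretization errors sit far above the roundoff
floor), is 6.0 over Δt ∈ {0.02, 0.01, 0.005}.

## Fields

- Delta kick: the impulsive field is discretized as a box over exactly
  one integrator step with height E_max/Δt, so the impulse area is
  E_max regardless of the step; spectra are normalized by the area, so
  the height convention cancels.  Default strength 1e−3 a.u., weak
  enough that the induced dipole is linear to better than 1e−3 (tested)
  while remaining numerically significant.
- Ramped cosine: E_max n̂ (t/T_ramp) cos ωt during a one-cycle linear
  ramp, E_max n̂ cos ωt afterwards.

## Spectra and response functions

The absorption spectrum comes from the damped Fourier transform of the
induced dipole: α_jj(ω) = (1/E_max) Σ_k Δt μ^ind_j(t_k) e^{−γ t_k}
e^{iω t_k}, evaluated with the FFT on the 2π/T grid (no zero padding —
the resolution is reported as it is), and S(ω) = (4πω/3c) Im α(ω).  The
default damping γ = 0.00921 a.u. (0.251 eV) gives Lorentzian lines of
half-width γ; the eV conversion uses 27.211386 eV/Hartree.  Peaks are
local maxima above a height fraction of the global maximum; lines closer
than the width merge, as they must at finite resolution.  (With a
100 000-step production signal the stated line FWHM-to-resolution ratio
is only roughly reproduced by 2γ vs 2π/T; the half-width-equals-γ
convention is adopted and the small discrepancy left as such.)

For α(ω) and β(ω) the dipole is expanded in the field strength as
μ = μ⁰ + μ⁽¹⁾E + ½μ⁽²⁾E² + …, with, in a transparent region,
μ⁽¹⁾(t) = α(ω) cos ωt and μ⁽²⁾(t) = ½[β_OR + β_SHG cos 2ωt] — the unique
form consistent with ½β(E cos ωt)² and with both components reducing to
the static β at ω → 0.  μ⁽¹⁾ and μ⁽²⁾ are isolated with four-point
central differences over the strength family ±E, ±2E,

    μ⁽¹⁾ = [8(μ_{+E} − μ_{−E}) − (μ_{+2E} − μ_{−2E})]/(12E) ,
    μ⁽²⁾ = [16(μ_{+E} + μ_{−E}) − (μ_{+2E} + μ_{−2E}) − 30 μ⁰]/(12E²) ,

which cancel the cubic contamination of μ⁽¹⁾ exactly (verified against a
five-strength polynomial-differentiation oracle); μ⁰ is the constant
permanent dipole.  The linear least-squares fits use the cos ωt basis
for μ⁽¹⁾ and the {½, ½cos 2ωt} basis for μ⁽²⁾ on the window after the
one-cycle ramp (the ramp cycle is always excluded), over the standard
one-ramp + three-cycle protocol; fit residuals are reported.  Default
strengths are E = 5e−4 with the ±2E companions at 1e−3.  The static
limit is cross-checked without any time propagation: α extracted at
ω = 0.01 agrees with −d²E/dε² of the field-dependent OMP2 ground state
to ~5e−5 relative on the bundled fixture.

## Synthetic data and what the tests do (and do not) show

The fixture generator produces random Hermitian spin-orbital model
systems with the full tensor-symmetry set: a diagonally dominant
one-body matrix with occupied levels below and virtual levels above a
gap (default 1 Hartree; off-diagonal noise 0.05), and two-electron
integrals with particle-exchange and Hermitian symmetry scaled by a
coupling factor (default 0.1; 0.3 in most tests so correlation is
non-trivial but perturbation theory remains well conditioned).  All
integrals are real, matching the closed-shell molecular setting in which
the OMP2 conjugation relation λ₂ = t₂* holds.  Closed-shell spin
structure is covered by the spatial-to-spin-orbital expansion and by the
bundled H₂/STO-3G system (standard literature MO integrals at
R = 1.4 bohr, stored as JSON text).

These systems exercise every equation at full generality of the tensor
algebra, but they are small and have sparse spectra: passing tests
demonstrate correctness of the equations, conservation laws, integrator
order and extraction pipelines — not basis-set-quality molecular
spectra, core excitations, or the density-of-states effects of real
molecules.  Reproducing published basis-set results (e.g. a neon atom
in a doubly augmented double-zeta basis) additionally requires a
Gaussian-integral engine; the `pyscf` adapter is provided for that
purpose but the package does not evaluate molecular integrals itself.

## Problem sizes used by the bundled checks

Chosen as the package's standard desk-scale study conditions:

- TDCCSD vs full CI: two electrons in four spin orbitals, delta kick
  1e−3, 50 a.u. at Δt = 0.02 (s = 3).
- Conservation runs: kick followed by field-free propagation to 5 a.u.
  at Δt = 0.01 for CCSD/CC2/CC2-b/OMP2 (and the NOMP2 constraint
  preservation along the same protocol).
- Integrator order: field-free stiff fixture, endpoints at
  Δt ∈ {0.02, 0.01, 0.005} against a Δt = 0.00125 reference.
- Static limit: TDOMP2 at ω = 0.01, strengths ±5e−4/±1e−3, one ramp
  plus three cycles (≈2513 a.u.) at Δt = 0.25 with the two-stage
  (fourth-order) integrator — amply accurate at these frequencies, as
  checked against Δt = 0.01/s = 3 runs at higher ω.
- H₂ spectrum: 5000 steps of Δt = 0.1 (T = 500 a.u., resolution
  2π/T ≈ 0.34 eV).

## Known limitations

- No triples and no full orbital-optimized doubles (OCCD/NOCCD); no
  velocity-gauge coupling; no autocorrelation functions (τ₀ is carried
  but unused).
- TDCC2 response properties inherit the known limitations of the CC2
  doubles truncation; the CC2 vs CC2-b difference is exposed but small.
- The dense reference implementation is exponential in system size and
  intended for at most ~12 spin orbitals.
- The term-table evaluator favors transparency over throughput; it is
  comfortable at fixture scale and would need contraction batching for
  production basis sets.
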