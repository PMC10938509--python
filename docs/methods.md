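# Methods

This note records the model, the numerical choices, and the design decisions
behind `iedrf`, at the level of detail a maintainer or reviewer needs to
judge what the tests do and do not establish.

## Model and assumptions

The environment is classical: fixed point charges plus isotropic atomic
point polarizabilities on a subset of MM atoms.  Induced dipoles interact
through the damped dipole field tensor and respond linearly and
instantaneously to all fields (no frequency dependence, no exchange
repulsion between QM and MM — MM atoms are electrostatics + polarizability
only, so nothing stops QM density from overlapping an MM site except the
damping).  The QM side is restricted closed-shell Hartree–Fock in Cartesian
Gaussian bases with s and p shells; a bundled STO-3G (H, He, C, N, O) is the
default basis.  The embedding operator is the full quadratic polarization
Hamiltonian −½ f̂ᵀA f̂ with the *operator-valued* electronic field — one
Hamiltonian for all states — evaluated with exact damped integrals, so
energies are smooth functions of all coordinates and analytical gradients
exist for nuclei, MM charges and polarizable sites alike.

Assumed conventions: Hartree atomic units internally; Ångström in all
external files; `F^(e)` defined with the (r − R_site) numerator so that its
trace with the electron number density gives the physical field of the
electron cloud; p-shell AO order (x, y, z); doubled closed-shell density,
Tr(DS) = N_elec.  The sign bookkeeping of the zero/one/two-electron pieces
is pinned operationally by the energy-assembly identity (the converged SCF
energy must equal an independently assembled Tr-based sum, to 1e−10) plus
physical checks (a He atom and a distant polarizable site attract, with a
monotone distance decay).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| Thole width `a` | 2.1304 | — | exponential-density damping of T(ij); the van Duijnen–Swart refit for this functional form |
| damping radius `r0` | 1.0·α^(1/3) | bohr | length scale of the polarization-integral cutoff C(r), per site |
| RI mode | exact-same-site | — | replace same-site RI blocks by exact CPP integrals; `pure-ri` keeps the RI form |
| overlap pseudoinverse threshold | 1e−8 (relative) | — | singular values of S dropped in the RI metric |
| SCF convergence | ΔE ≤ 1e−10, max commutator ≤ 1e−8 | hartree / a.u. | DIIS with plain-mixing start |
| CPP radial grid | 140 Gauss–Legendre nodes | — | converged to ≈1e−12 (doubling changes results < 1e−11) |

Site–site damping (Thole, exponential density): λ₃ = 1 − e^(−a u³),
λ₅ = 1 − (1 + a u³)e^(−a u³), u = r/(α_i α_j)^(1/6);
T = (3λ₅ r̂r̂ᵀ − λ₃ 1)/r³, finite for r → 0.

Charge/electron-to-site damping: C(r) = (1 − e^(−(r/r0)²))², applied
identically to electronic, nuclear and MM-charge fields so the net field of
a neutral atom cancels correctly at short range.  This form vanishes like r⁴
at the origin — enough zeros to regularize every kernel used (the CPP kernel
C²/r⁴ then behaves like r⁴) — and, being a three-term Gaussian sum, merges
exactly with the AO-pair Gaussians.  The electronic field integrals do not
strictly need damping, but it is included for consistency with the
nucleus/charge fields.  The damping form is a strategy object; alternative
forms can be swapped in (the analytic field path requires a Gaussian
expansion, the CPP path and the oracle only need pointwise values).

## Integral evaluation

*Field integrals* F^(e): each damping Gaussian merges with the AO-pair
Gaussian; monomials are re-expanded about the merged center, converted to
Hermite Gaussians, and contracted with the Boys-function R-tensor (the field
is the first Cartesian derivative of the Coulomb kernel).  Exact to machine
precision.

*CPP integrals*: the C²/r⁴ kernel cannot be split term-by-term into
Gaussians (individual terms diverge), so these use a single-center expansion
about the site: the angular integral of monomial×Gaussian factors against
exp(v·n) is done exactly with scaled modified spherical Bessel moments
(series below z = 30, stable upward recurrence above), leaving a smooth 1-D
radial integral on the support of the Gaussian envelope (Gauss–Legendre,
140 nodes).  This is the only non-closed-form integral path; its grid error
(~1e−12) is far below every tolerance used.

*Base integrals* (S, T, V, ERIs): McMurchie–Davidson Hermite recursions,
dense storage, no screening — adequate and transparent at ≤ ~12 AOs, with
hard resource guards.

*Oracle*: an independent adaptive spherical-product quadrature (composite
radial panels focused on the Gaussian product shells, Gauss–Legendre ×
uniform-φ angular grids, refinement until two levels agree).  It shares no
code with either analytic path and verifies every integral class, including
a 200-case randomized suite with exponents in [0.1, 50].

*Derivatives*: all geometric derivatives are taken at the primitive level by
Cartesian power shifting (d/dA of a primitive is a two-term combination of
raised/lowered monomials) and contracted immediately with weight matrices —
derivative-integral arrays are never stored.  Site-position derivatives of
F^(e) and CPP integrals follow from translation invariance (minus the sum of
the AO-center derivatives), which also guarantees exactly vanishing net
forces.

## Gradient architecture

The polarization energy is written as an explicit function of the arrays
(A, F^(e), F^(n), S, I_cpp) and the converged density D.  Analytic
array-adjoints (∂E/∂A, ∂E/∂F, …) are chained with the geometric derivatives
of each array; ∂A/∂x = A (∂T/∂x) A since atomic polarizabilities and damping
lengths are geometry-independent constants.  The overlap matrix enters twice
— through the Pulay term (energy-weighted density W = 2Σ_occ ε_k c_k c_kᵀ)
and explicitly through the RI metric (∂S⁻¹ = −S⁻¹ ∂S S⁻¹) — both are
included.  Validation is by central finite differences (step 1e−4 bohr, SCF
converged to 1e−12), which agree to ≤1e−6 hartree/bohr on the full fixture
matrix; agreement is typically ~2e−9, i.e. at the FD truncation floor.
Richardson extrapolation of the FD reference is unnecessary at these sizes
but trivial to add on top of the provided energy functions.

Two-density contraction functions (`jk_gradient_corrections(D1, D2)`) keep
separate density labels; with D1 = D2 = D they reproduce the RHF terms, and
they are the seam for response-theory gradients (CIS/TD-DFT-style), which
are out of scope here.

## Classical energy bookkeeping

The total energy contains: electronic terms, nuclear–nuclear repulsion,
nucleus/MM-charge Coulomb energy, and E0_pol.  E0_pol contains the MM
self-polarization (verified against the MM module's classical polarization
energy on MM-only inputs — the double-counting guard).  The MM–MM
charge–charge Coulomb energy is *not* included: it belongs to the fixed MM
force field, is independent of every QM degree of freedom, and its internal
forces sum to zero, so no invariance test can see it.  Gradients are of the
energy actually defined, so finite differences match exactly.

Sites with α = 0 are excluded from the supermatrix (the inverted
formulation presumes invertible atomic polarizabilities); a zero-α,
zero-charge environment is verified to be an exact no-op.  An unstable
dipole system (α⁻¹ − T not positive definite) raises a diagnostic naming
the closest scaled site pair rather than returning an unphysical response.

## Synthetic data

`generate_solvent_shell` emulates a packed solvent shell: rigid linear
three-site molecules (bond 2.8 bohr; α = 1.5/3.0/1.5 bohr³; charges
−0.15/+0.30/−0.15 e — net neutral, apolar, quadrupolar; own-molecule
charge-to-site fields excluded), placed with seeded rejection sampling under
minimum-distance constraints.  The parameters are chosen so the molecule's
own Applequist system is comfortably stable (molecular polarizability
eigenvalues 5.3/5.3/8.4 bohr³) with realistic anisotropy.  What it does
*not* emulate: thermal configurations from an equilibrated liquid,
Lennard-Jones packing structure, orientational correlations, or conformers.
Tests passing on these shells therefore establish the *mechanics* of the
embedding (identities, limits, gradients, invariances) — not quantitative
solvation thermodynamics of any real solvent.

The *designed far-shell fixture* for the coarse-graining check deserves its
own justification.  Grouping a molecule's atomic dipoles into one isotropic
site incurs two errors that do **not** vanish with distance alone: (i) the
eigenvalue mean discards the molecular anisotropy, an orientation-dependent
error that only averages out over many molecules (∝ 1/√N), and (ii) placing
the group dipole "on the atom closest to the centroid" is first-order
accurate only if an atom actually sits at the centroid (true for a linear
A–B–A molecule; badly violated for, e.g., a tetrahedral one).  The fixture
therefore uses 40 weakly coupled linear molecules (bond 3.5 bohr,
α = 0.2/1.0/0.2 bohr³, uncharged) at 60–85 bohr around a *charged* QM core
(HeH⁺, so a clean monopole field dominates).  Measured state-polarization
changes under 5 Å coarse-graining are 0.04–0.17% across seeds, against the
1% acceptance band — the band is a fixture design choice, not a general
property of coarse-graining at 5 Å.

## Problem sizes

The test suite runs H2, HeH⁺ and H2O (STO-3G, 2–7 AOs) against environments
of 0–3 hand-placed sites/charges, 18-site generated shells, and the 120-site
far-shell fixture; finite-difference gradient validation covers every
coordinate for the 2-AO systems and a seeded coordinate subset for H2O; the
randomized integral-oracle suite is 200 cases.  These sizes were chosen so
the entire suite exercises every code path in minutes on one core; nothing
in the implementation is specific to them except the dense-storage resource
guards.

## Known limitations

* s/p shells only; dense ERIs; no integral screening.
* Restricted closed-shell HF only; excited-state solvers, Δ-SCF and
  nonadiabatic couplings are out of scope (the generalized J/K and
  two-density gradient contracts are the designed seams).
* No Pauli repulsion on MM atoms (no ECPs), no periodic boundary
  conditions, no Ewald dipole sums, no anisotropic atomic polarizabilities,
  no fluctuating charges or Drude oscillators.
* Dense LU inversion of the 3N×3N dipole system; no iterative solver.
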