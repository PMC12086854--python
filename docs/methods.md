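# Methods

`vcdkit` computes vibrational circular dichroism (VCD) and infrared (IR)
spectra of small closed-shell molecules in the double harmonic
approximation. The quantities of interest are, per normal mode *i*, the
dipole strength `D_i` and the rotational strength `R_i`,

    D_i = (1/2 omega_i) sum_a [ sum_{l,b} P^l_{ab} S_i^{lb} ]^2
    R_i =               sum_a [ sum P^l_{ab} S_i^{lb} ] [ sum M^l_{ab} S_i^{lb} ]

(Hartree atomic units; `S_i^{lb}` are the Cartesian normal-mode vectors,
mass-weighted-normalized). `P^l` is the atomic polar tensor (APT), the
derivative of the electric dipole with respect to the position (length form)
or velocity (velocity form) of nucleus *l*; `M^l` is the atomic axial tensor
(AAT), the derivative of the magnetic dipole with respect to the nuclear
velocity. Because the electronic ground state is real, `M^l` requires
physics beyond Born-Oppenheimer: it is accessed either through nuclear
velocity perturbation theory (NVPT, complete-adiabatic coupling
`-i sum_l Rdot_l . grad_l`) or, equivalently, through magnetic field
perturbation theory (MFPT, the mixed second derivative of the energy with
respect to nuclear velocity and magnetic field).

## Mean field and response framework

The reference is an all-electron restricted Hartree-Fock determinant over
contracted Cartesian Gaussians (6d), in the spinless density convention
`D = C_occ C_occ^T`, `tr(D S) = n_occ`, so idempotency reads `D S D = D`
literally. Integrals use McMurchie-Davidson recursions (numba-compiled);
moment-weighted and center-derivative integrals are generated *exactly* by
linear maps on an extended primitive table closed under raising the angular
momentum by two (the identities `(r-A) chi` = l-raised function and
`d/dA chi` = mix of l+-1 functions). Two-electron integrals are stored as a
dense rank-4 tensor (fixture-scale systems); "augmented" ERI tensors with
one raised or center-differentiated index supply the velocity/magnetic
phase terms and nuclear ERI derivatives.

Three perturbation channels are built over one linear-response machinery:

* **NDPT** (nuclear displacement, real symmetric, 3N coupled channels):
  `H1 = dh/dR + G1(D0)` from derivative integrals, `S1 = dS/dR`.
* **NVPT** (nuclear velocity, imaginary antihermitian, 3N channels):
  velocity atomic orbitals attach `exp(i Rdot.(r - O_sp))` to functions on
  the moving atom. The channel collects the phase derivative of the Fock
  matrix (one- and two-electron, including the density phases that at
  Hartree-Fock act through exchange), the nuclear-momentum coupling on the
  moving atom's basis functions, and the cross term with the NDPT response
  `D(1,R)` (the coefficient part of `grad_l`). The raw sum is not termwise
  antihermitian in a finite basis; since both solvers consume only its
  action on the occupied space and its occ-virt blocks, the channel matrix
  is the antihermitian completion `N D0 S0 - (N D0 S0)^T`, exactly the
  symmetrization the MO solver's density assembly performs.
* **MFPT** (magnetic field, imaginary antihermitian, exactly 3 channels):
  gauge-including atomic orbitals (GIAOs) with minimal-coupling phases make
  every matrix element depend only on center differences, so the magnetic
  gauge origin never enters.

Imaginary quantities are stored as the real factor multiplying i, so all
solver algebra is real. For antisymmetric stored densities the Coulomb
response vanishes identically and the two-electron response reduces to
exchange, which is exact at Hartree-Fock; `response.uncoupled_imaginary`
drops it to reproduce the uncoupled behavior of pure density functionals.

## The AO density-matrix solver

The first-order density is parametrized by an anti-Hermitian generator
acting on the reference density:

    D1 = -D0 S1 D0 + D0 S0 X - X S0 D0,

which satisfies the differentiated idempotency and trace conditions by
construction (the occupied-occupied block is fixed by `S1`; the
virtual-virtual block vanishes). Projecting the differentiated stationarity
condition `d/dx (F D S - S D F) = 0` onto the occupied-virtual block in the
Loewdin (S^-1/2) basis gives a linear equation for the occ-virt block
`U = o X v`,

    U F~ - F~ U + o G(U + s U^T) v = -( o [H1~ + G(D1_oo~)] v - o F~ D0~ S1~ v ),

with `s = +1` (real channels, X antisymmetric) or `s = -1` (imaginary
channels, stored-real X symmetric). The operator is symmetric positive
definite at a stable SCF solution and is solved by preconditioned conjugate
gradients (Jacobi preconditioner from occupied/virtual level differences of
the Loewdin Fock matrix; the reference multilevel preconditioner is not
reproduced - the contract is the converged solution, not the iteration
path). Convergence threshold 5e-12 on the residual norm; the CG initial
guess is zero, so the whole path is deterministic.

The independent **MO Sternheimer solver** solves, per occupied orbital,
`(F0 - eps_j S0) C1_j = -Q^T (H1 - eps_j S1 + G(D1)) C0_j` in the
S-orthogonal virtual projection by CG, fixes the occupied-occupied mixing
from the orthonormality derivative (`C1_oo = -1/2 C0 (C0^T S1 C0)`, the
prefactor confirmed by the differentiated-idempotency invariant), and
iterates coupled channels with damping 0.5. The two solvers share no
response code; their element-wise agreement (<= 1e-8, typically ~1e-10) is
the package's central internal validation, mirrored from the reference
method's own validation logic.

## Property assembly

* APT length (NDPT): `P = Z d_ab - 2[tr(D1 Dip) + tr(D0 dDip/dR)]`, the
  second term being the basis-derivative (Pulay) contribution.
* APT velocity (NVPT): derivative of the momentum expectation in the
  velocity-gauge basis; the phase derivative contributes the co-moving term
  `d_ab S0` on the moving atom (which makes the translational sum rule
  exact in any basis: a rigid boost of all nuclei leaves the coefficient
  response exactly zero, electrons co-move through the phases alone).
* AAT (NVPT): half the derivative of the magnetic-moment expectation with
  respect to nuclear velocity; the 1/2 matches the nuclear part
  `(Z_l/4c) eps_{agb} R^l_g` so that `R_i = (P.S).(M.S)` without further
  factors. Verified exactly on the analytically solvable single-atom case
  (`M_el = -(n_elec/4c) eps R`, cancelling the nuclear part for a neutral
  atom).
* AAT (MFPT): the overlap of first-order wavefunctions
  `M_el = Im <dPsi/dR | dPsi/dB>` expanded over the occupied determinant,
  including the basis-function derivatives on both sides (R-derivative:
  coefficients plus moving centers; B-derivative: coefficients plus GIAO
  phases). Two algebraically equivalent forms are implemented: directly
  from MO coefficient responses, and purely from density responses via
  occupied/virtual projector identities (the normalization-identity
  rewrite); they agree to ~1e-11 and are cross-checked in the tests. GIAO
  phase derivatives are referenced to each function's center relative to
  the common origin, so the magnetic gauge origin drops out of the entire
  MFPT pipeline - AATs are invariant under `O_mag` shifts by construction,
  as the GIAO formulation promises. The NVPT AAT, by contrast, references
  the physical magnetic-moment operator at `O_mag` and additionally
  acquires a finite-basis `O_sp` dependence through the velocity-gauge
  phases; both dependencies are reported, not errors. In the all-electron
  setting the MFPT AAT has no `O_sp` dependence (the term that carries it
  in pseudopotential implementations is absent).

## Gauge origins

The common-origin choice `O_sp = O_mag = (0,0,0)` is the default; both are
configurable. The two AAT theories are directly comparable at the common
origin.

## Vibrational analysis and spectra

The Hessian is seminumerical: central three-point differences of the
*analytic* nuclear gradient with increment 1e-2 bohr (the gradient comes
almost for free from the derivative integrals the displacement channels
already require; differencing energies instead would need O((3N)^2) rather
than O(6N) SCF solutions and lose accuracy). The max-abs symmetrization
residual is recorded; rigid translations/rotations are projected out in the
mass-weighted (Eckart) frame before diagonalization, and modes below
15 cm^-1 are classified rigid. A BFGS minimizer with the analytic gradient
(convergence max|g| <= 3e-5, rms <= 1.5e-5 a.u.) keeps the shipped fixture
geometries at true stationary points of this level of theory; the chiral
hydrogen peroxide minimum has an HOOH dihedral of +-125 degrees at HF in
the built-in minimal basis.

Spectra are sums of *unit-area* Lorentzians (an explicit normalization
choice; the printed form of the reference broadening function was not
available), full width at half maximum 12 cm^-1 by default, optional rigid
shift (0 by default; a +55 cm^-1 alignment shift can be requested). The
single-mode peak height is `2 s_i/(pi w)` and the spectrum integral equals
the summed strengths - note that meeting a 1e-6 relative integral identity
numerically requires a very wide, dense grid, because Lorentzian tails
carry `w/(2 pi L)` mass beyond `+-L` and trapezoid aliasing grows as
`exp(-pi w/h)`.

## Units and reported columns

Atomic units internally; CGS convention for magnetic quantities (explicit
1/c with c = 137.035999084). Wavenumbers in cm^-1 via 219474.63 cm^-1/Eh
with isotope-averaged masses (overridable). Strength tables carry a.u.
columns plus the community-convention columns `D` in 1e-40 esu^2 cm^2 and
`R` in 1e-44 esu^2 cm^2 (conversion (e a0)^2 = 6.460434e4 * 1e-40
esu^2 cm^2; the magnetic moment matrix carries its 1/c factor explicitly,
so R_au has the same dimension as D_au).

## Validation program (what the tests show, and what they do not)

Every analytic first-order integral is checked against an independent
finite-difference oracle: geometric displacement for the R channels, and
complex-phase FD for the V and B channels, using a separate pure-python
evaluator over complex-center Gaussians (a linear phase `exp(i k.r)` shifts
a Gaussian center into the complex plane, so phased overlaps are exact
closed forms). The solver pair provides a genuinely independent dual route
to every density response. Physical anchors: the length-form APT against
finite differences of the SCF dipole; exact translational sum rules in both
dipole forms; exact single-atom boost identities for APT and both AAT
theories; enantiomer antisymmetry of rotational strengths and their exact
vanishing for planar (achiral) fixtures; invariance of the MFPT pipeline
under magnetic-origin shifts. During development the NVPT channel was
additionally validated against a real-time TDHF oracle (propagating the
SCF state with one nucleus moving at constant velocity in its co-moving
basis and measuring the steady momentum response), which reproduces the
analytic velocity-form APT at the level of the basis-convention difference.

The built-in fixtures are small all-electron molecules in compact bases.
What passing tests do *not* show: basis-converged spectra. All-electron
velocity-gauge quantities converge slowly with basis saturation (the
reference setting uses pseudopotentials, i.e. no cores), so at the minimal
level the velocity- and length-form APTs, and the NVPT and MFPT AATs,
differ substantially; the built-in ladder (minimal -> split-valence ->
polarized) shows the monotone approach (velocity-length APT deviation
0.39 -> 0.17 -> 0.11 on water; MFPT-vs-NVPT rotational strength on the
largest peroxide mode agrees to ~9% at the polarized level), and saturated
even-tempered ladders drive the deviation to ~1e-3. Anharmonicity,
temperature and solvent effects are out of scope.

## Problem sizes

The shipped validation program runs on H2 (2 AOs), H2O (7/13/25 AOs along
the ladder), HOF, and the H2O2 enantiomer pair (12 AOs minimal, 40
polarized), with seminumerical Hessians at the minimal level. These sizes
were chosen so the complete suite exercises every channel of every theory
with both solvers in minutes on one CPU; the method itself has no such
limit beyond the dense ERI storage (~60 AOs).
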