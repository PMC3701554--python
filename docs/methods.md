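# Methods

## Model

A distribution of N point charges {q_i, **r**_i} (e, Å) is approximated by
n < N charges chosen so that the error of the approximate potential,
integrated over a spherical shell [r_in, R] about a stated expansion
center, is minimized *order by order*.  With orthonormal complex spherical
harmonics (Condon–Shortley phase) and spherical moments
q_lm = Σ_i q_i r_i^l Y*_lm(θ_i, φ_i), the shell integral of the squared
difference of two truncated expansions separates exactly:

    ε²(r_in, R) = Σ_{l=0}^{l_max} (4π/(2l+1))² I_l · Σ_m |Δq_lm|²,
    I_0 = R − r_in,     I_l = (r_in^{1−2l} − R^{1−2l})/(2l−1)   (l ≥ 1).

Because each order enters through its own nonnegative term with its own
radial weight, sequential (lexicographic) minimization of the per-order
terms is radius-independent, and an approximation whose first n orders
match exactly has potential error falling off at least as R^−(n+2).
These weights are frozen as constants in `potential.moment_discrepancy`
and regression-tested against a numerical quadrature of the shell
integral (`shell_error_quadrature`).

All potentials are in e/Å with the 1/(4πε₀) factor dropped.  Cartesian
quadrupole and octupole tensors use the traceless Buckingham convention
with a ½ prefactor — the convention in which tabulated gas-phase water
moments (Q_xx ≈ −2.5 D·Å) are quoted; 1 D = 0.2082 e·Å.  The convention
identifier is recorded on every moments object and checked when two are
compared.

The Cartesian↔spherical connection for l ≤ 3 contracts the traceless
tensors against the coefficient tensors of the solid harmonics; those
coefficient tensors are obtained once per (l, m) by an exact least-squares
fit of r^l·Y_lm on a fixed deterministic point set (solid harmonics are
homogeneous polynomials, so the fit residual is at rounding level ~1e−15)
rather than from transcribed prefactor tables.

## Expansion centers

Orders that are matched exactly are matched about *every* center, so the
center choice only matters for the first order that cannot be zeroed.
The solvers follow the method's optimal-center conventions: center of
charge for charged sets (dipole term vanishes there for the 1- and
2-charge constructions), center of dipole for neutral sets (the point
minimizing the Frobenius norm of the traceless quadrupole, derived here
in closed form as d = 2Θp/(3p²) − (p·Θ·p)p/(6p⁴) from any origin), and
center of geometry as the fallback for neutral, zero-dipole sets.

## Closed-form solvers

* `opca1` — M at the center of charge (requires |M| > 1e−8 e).
* `opca2_neutral` — ±q pair along p̂ centered at the center of dipole.
  The pair's traceless quadrupole about that center vanishes identically
  for every q, so the charge is fixed by the octupole term; writing the
  pair octupole as (|p|s²/8)(5ûûû − sym) gives the optimal squared
  separation s² = 4(Ω : p̂p̂p̂)/|p| with Ω the original octupole about the
  center of dipole.  A negative projection means the formal optimum is
  s → 0 (an imaginary charge magnitude): the solver then fixes
  s = `d_sep` and flags `small_separation`.
* `ppca2_neutral` — the practical 4-step variant: pair at the center of
  dipole, separation fixed at `d_sep`, q = |p|/d_sep, and, if either
  charge falls outside `bound_factor`·a of the center of geometry (a =
  extent), the pair center is shifted along the line to the center of
  geometry until both are inside (`bound_shift`).  This guards the
  mid-field against centers of dipole that fall far outside the
  distribution.
* `ppca2_charged` — q₁ + q₂ = M on the **v**₁ axis of the quadrupole
  about the center of charge, pair center of charge pinned there, and the
  v₁ quadrupole component set to λ₁.  The distance ratio |r₁|/|r₂| = κ
  closes the one-parameter freedom, with the larger distance assigned to
  the smaller-|q| charge.  Both sign patterns have closed forms: for
  sign λ₁ = sign M, same-sign charges on opposite sides
  (q₁ = M/(1+κ), r₁² = λ₁κ/M); for sign λ₁ ≠ sign M, opposite-sign
  charges on the same side (q₂ = Mκ/(κ−1), r₂² = −λ₁/(Mκ)).  A vanishing
  quadrupole degenerates to the 1-charge optimum split in two (flagged).

## Parameters

| name | default | unit | role |
|------|---------|------|------|
| `d_sep` | 0.1 | Å | fixed pair separation of the neutral practical variant; small against the ~3 Å extent of amino-acid groups, inside the flat small-separation regime of the error |
| `bound_factor` | 1.5 | a | mid-field position bound (multiples of the extent) |
| `kappa` | 1.5 | — | distance ratio closing the charged 2-charge construction |
| `neutral_tol` | 1e−8 | e | below this |M| a set is treated as neutral (force-field charges are rounded; exact-zero tests are brittle) |
| evaluation radius | 2a | Å | default mid-field shell/sphere for error reports |
| grid | 7200 | points | Fibonacci-spiral sphere grid (deterministic, equal weights, seam-free); reports carry the descriptor |

`kappa` multiplying the *distance ratio* r₁ = κ·r₂ is an interpretation
of the charged-case free parameter; it is exposed in `Ppca2Config` rather
than hard-coded so sensitivity can be explored.

## Numeric solver

`solve_opca` implements the sequential minimization for any n ≤ N in the
4n parameters (q, x, y, z per charge), as a chain of constrained stages:

1. *Zeroing phase* — trust-region nonlinear least squares on the stacked
   real moment components of orders 0..l, advancing l while an exact
   match is attainable (tolerance 1e−10 on the squared mismatch).
2. *Constrained phase* — the first order that cannot be zeroed is
   minimized with SLSQP; exactly-matched earlier orders are kept as
   per-component equality constraints (their squared forms have vanishing
   gradients on the zero surface, which blinds an SQP linearization),
   non-zeroable earlier orders as inequality pins at their achieved value
   plus a 1e−9 relative slack.
3. *Manifold walk* — when every earlier order is matched exactly and the
   match manifold is low-dimensional (≤ 2), the stage finishes with a
   null-space predictor/corrector line search: step along the numerical
   null space of the matched-components Jacobian, re-project by least
   squares.  This handles the long hyperbolic ravines that tight charge
   pairs create (charge magnitude ∝ 1/separation), where single SQP runs
   stall.

Nonconvexity is handled by multi-start (default 16 restarts, seed
20130704): seeds from the center-of-charge/center-of-dipole
constructions, a geometric ladder of pair separations, subsets of the
original charges (including the exact set when n = N), and random
placements in the extent sphere.  Runs are compared lexicographically
with residuals below 1e−9 treated as matched and the rest quantized to 6
significant digits, so float noise in a tied order cannot outrank a
genuine improvement at the next order.  Variables are rescaled per run
(charge block by its seed magnitude, positions by the extent).
`solve_opca_constrained` applies the same machinery to a target moment
set under equality constraints expressed as a shared parameter vector
(e.g. the C2v spec: mirror pair + on-axis charge, 5 parameters); its
random seeds draw charge magnitudes log-uniformly because tight-pair
optima live orders of magnitude away from unit scale.

An optional `bounded` mode confines positions to `bound_factor`·a via
inequality constraints (the manifold walk and zeroing phase are then
skipped in favor of the constrained SQP steps).

## The C2v water solver

In the oxygen-origin frame (molecule in the y–z plane, z bisecting the
hydrogens) the 3-charge system is a mirror pair q₁ at (0, ±y, z₁) and a
central charge −2q₁ at (0, 0, z₃).  Eliminating the monopole, dipole and
quadrupole mismatches leaves one free parameter, and the constraint chain
fixes z₁ + z₃ = −2(Θ_yy + 2Θ_xx)/(3p_z) before any search.  The solver
scans z₃ over [0, 1.2] Å (2401-point grid, then bounded refinement to
1e−8 Å), solving q₁ = p_z/2(z₁−z₃) and y² = −Θ_xx/q₁ − (z₁²−z₃²) in
closed form at each trial and minimizing the l = 3 term of the error
expansion.  The default objective is the spherical all-m norm (the same
quantity the shell error uses — equal, up to a constant, to the full
tensor contraction ΔΩ:ΔΩ); a plain sum of squares over the three distinct
components is available behind `objective="cartesian"` for sensitivity
analysis and lands measurably elsewhere on the constraint curve, which is
why the invariant norm is the default.  For the built-in gas-phase water
moments the solution places the pair at (0, ±0.155, 0.487) Å and the
central charge at (0, 0, 0.474) Å; at print rounding these reproduce the
published geometry, and the octupole of the solved set obeys the trace
identity O_zzz + O_xxz + O_yyz = 0 to print precision.

`atom_centered_water3` provides the standard comparison baseline —
charges pinned to the O/H/H atom centers (experimental gas-phase
geometry: O–H 0.9572 Å, H–O–H 104.52°), net-neutral and dipole-matched —
which necessarily misses the quadrupole.

## Synthetic data

`random_chargeset` emulates backbone-inclusive amino-acid charge groups:
5–30 partial charges uniform in a 3 Å sphere, raw charges uniform in
[−1, 1] e shifted linearly to an exact integer net charge in {−1, 0, +1};
`ensemble` draws cohorts with 20 % charged / 80 % neutral composition.
What this reproduces about real charge groups: the size, extent, charge
magnitudes and net-charge mix that determine how fast the multipole
series converges at 2a–10a.  What it does not: the spatial correlation of
real partial charges (bond-alternating signs, charged termini), anisotropy
of real residues, or conformational coupling — so passing tests support
the solver contracts and error analysis, not force-field-grade accuracy
claims for any specific residue.  Degenerate fixtures (a physical dipole
pair, an alternating-charge square with p = 0, a group whose center of
dipole falls outside 1.5×extent, and one with a negative octupole
projection) are located by deterministic rejection sampling over seeds at
build time, so no data files ship with the package.

## Numerical choices and edge cases

* Shell quadrature: Gauss–Legendre in ln r (the radial integrand is a sum
  of decaying exponentials in log-radius) × product Gauss–Legendre /
  uniform-azimuth angular rule, exact for the band-limited angular part;
  convergence is verified by doubling the angular rule (relative change
  > 1e−6 raises).
* Evaluation points within 1e−9 Å of a charge raise a singularity error
  naming the offending pair — never a silent skip.
* Eigen-decomposition ties: eigenvalues ordered by descending |λ|, ties
  broken by descending signed λ then lexicographic eigenvector; each
  eigenvector's largest-magnitude component is made positive.
* Neutral sets with |p| ≈ 0 (pure quadrupole and beyond): the 2-charge
  dipole constructions raise a degenerate-input error pointing to
  `solve_opca(n=2)`; the center of charge of a neutral set is likewise a
  hard error rather than a large number.
* `moment_discrepancy` takes the shell [r_inner, R] with r_inner
  defaulting to R/2, matching the default mid-field report (shell [a, 2a]
  at R = 2a).

## Problem sizes used in the tests

The suite exercises cohorts of 100 synthetic groups for the far-field and
metric-identity checks, 100 instances for analytic/numeric equivalence
(60 charged, 40 neutral with a real closed-form solution), spheres of
300–600 points for RMS error estimates and 7200 where the grid size
itself is under test.  These sizes keep the full suite in the
few-minutes range while leaving every statistical margin wide (the
equivalence worst case sits near 7e−5 against a 1e−4 bound; the cohort
far-field ratio is ≈0.85 against a bound of 1).

## Known limitations

* The charged practical 2-charge construction (κ fixed) is not
  guaranteed to beat the optimal point dipole on every individual set —
  only in cohort RMS; sets with nearly degenerate λ₂ ≈ λ₃ are its worst
  case.  The fully optimized `solve_opca(n=2)` does not share this
  weakness.
* Likewise the fixed-separation neutral variant is marginally (≲1e−4
  relative at 10a) worse than the point dipole exactly when the octupole
  projection is negative; the gap closes as d_sep → 0.
* Moments above l = 3 are out of scope throughout; continuous charge
  densities are consumed only via their printed moments.
* `solve_opca` is tuned for n ≤ 4; larger n works but without any
  performance or global-optimality attention.
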