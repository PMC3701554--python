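# opca — optimal point charge approximations

`opca` replaces an arbitrary distribution of point charges (charge in e,
coordinates in Å) with a small number of *optimally placed* point charges
that reproduce its multipole expansion to the highest order the charge
count allows.  It is aimed at molecular modellers who coarse-grain
electrostatics — amino-acid charge groups, small molecules, water — and
want an approximation that keeps the asymptotic guarantees of a truncated
multipole expansion while being a plain sum of Coulomb terms.

## The method

For charges {q_i, **r**_i} the potential error of an approximating set,
integrated over a spherical shell around the expansion center, separates
by spherical-harmonic order (orthonormal complex Y_lm):

    ε² = Σ_l (4π/(2l+1))² I_l(R) Σ_m |q_lm − q'_lm|²,
    q_lm = Σ_i q_i r_i^l Y*_lm(θ_i, φ_i),

so the best n-charge representation is found by minimizing the terms
*sequentially*, lowest order first.  A representation that zeroes the
terms through order n has error falling off at least as R^−(n+2).
Closed forms exist for small n:

* **1 charge** (charged sets): the net charge M at the center of charge
  Σq_i**r**_i/M — monopole and dipole errors vanish.
* **2 charges** (neutral sets): a ±q pair along **p̂** centered at the
  *center of dipole*; the pair's quadrupole there vanishes for every q, so
  q is fixed one order up, by the octupole term: s² = 4(Ω : p̂p̂p̂)/|p|.
  When that projection is negative the optimum degenerates to s → 0 and
  the practical variant (PPCA) fixes s = 0.1 Å.
* **2 charges** (charged sets): charges summing to M on the principal
  axis **v**₁ of the quadrupole about the center of charge, matching its
  largest principal value λ₁, with the distance ratio closed by the
  empirical κ = 1.5.
* **3 charges, C2v symmetry** (water): zero net charge plus exact dipole
  and traceless-quadrupole matching leave one free parameter, closed by a
  1-D numerical minimization of the octupole term.

A general numeric solver (`solve_opca`) performs the same sequential
minimization for any n, and doubles as the oracle for every closed form.
Cartesian moments use the traceless (Buckingham, ½-prefactor) convention;
1 D = 0.2082 e·Å; potentials are in e/Å with 1/(4πε₀) dropped.

## Worked example: a 3-charge model of gas-phase water

```python
from opca import solve_water3, gas_phase_water_moments

sol = solve_water3(gas_phase_water_moments())
print(f"pair:    {sol.q_pair:+.3f} e at (0, ±{sol.y_off:.3f}, {sol.z_pair:.3f}) A")
print(f"central: {sol.q_central:+.3f} e at (0, 0, {sol.z_central:.3f}) A")
print("octupole (D.A^2):", [round(v, 2) for v in sol.octupole_dA2])
```

prints

```
pair:    +14.459 e at (0, ±0.155, 0.487) A
central: -28.918 e at (0, 0, 0.474) A
octupole (D.A^2): [-1.17, -1.44, 2.61]
```

Three charges clustered ~0.5 Å above the oxygen reproduce the quantum
mechanical dipole (1.81 D) and quadrupole (Q_xx = −2.53 D·Å) of water
*exactly* and its octupole as closely as the remaining freedom allows —
the tight spacing is what forces the large charge magnitudes.  The same
machinery is available from the shell:

```
opca water3
opca synth --n-sets 5 --seed 1        # amino-acid-like test groups
opca ppca synth_000.xyzq --out approx.xyzq
opca evaluate synth_000.xyzq approx.xyzq --radii 2a,10a
```

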