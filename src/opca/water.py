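"""Symmetric 3-charge optimal approximation for a C2v target (water).

Frame: origin at the oxygen nucleus, molecule in the y–z plane, z axis
bisecting the hydrogens.  The three charges are a mirror pair q_pair at
(0, ±y, z_pair) and a central charge q_central = −2 q_pair at
(0, 0, z_central).  Zero net charge plus exact dipole and traceless
quadrupole matching fix four of the five unknowns; the leftover freedom is
closed by numerically minimizing the octupole (l = 3) term of the
shell-error expansion.

A useful consequence of the constraint chain: the sum z_pair + z_central
is determined before the 1-D search,

    z_pair + z_central = −2 (Θ_yy + 2 Θ_xx) / (3 p_z),

so the solver scans the single variable z_central, solving the remaining
constraints in closed form at each trial value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateInputError, InfeasibleError
from .multipoles import (
    DEBYE_TO_EA,
    CartesianMultipoles,
    ChargeSet,
    cart_to_spherical,
    cartesian_moments,
)

_PRINT_TOL = 0.02  # print-rounding slack for tabulated moment identities


@dataclass(frozen=True)
class C2vTarget:
    """Target moments in the oxygen-origin C2v frame (Debye-based units)."""

    p_z: float                     # D
    Theta_zz: float                # D·Å
    Theta_xx: float
    Theta_yy: float
    Omega_zzz: float               # D·Å²
    Omega_xxz: float
    Omega_yyz: float
    frame: str = "origin at O; molecule in y-z plane; z bisects the hydrogens"

    def __post_init__(self):
        if abs(self.Theta_zz + self.Theta_xx + self.Theta_yy) > _PRINT_TOL:
            raise ValueError("quadrupole components must sum to zero (traceless)")
        if abs(self.Omega_zzz + self.Omega_xxz + self.Omega_yyz) > _PRINT_TOL:
            raise ValueError("octupole components must satisfy the trace identity")

    def octupole_tensor_ea(self) -> np.ndarray:
        """Full traceless octupole tensor in e·Å³ (all symmetric placements)."""
        O = np.zeros((3, 3, 3))
        comps = {
            (2, 2, 2): self.Omega_zzz,
            (0, 0, 2): self.Omega_xxz,
            (1, 1, 2): self.Omega_yyz,
        }
        for (j, k, l), val in comps.items():
            for perm in {(j, k, l), (j, l, k), (k, j, l), (k, l, j), (l, j, k), (l, k, j)}:
                O[perm] = val * DEBYE_TO_EA
        return O

    def cartesian_ea(self, origin=(0.0, 0.0, 0.0)) -> CartesianMultipoles:
        """The target as a CartesianMultipoles object in e/Å units (M = 0)."""
        Theta = np.diag(
            np.array([self.Theta_xx, self.Theta_yy, self.Theta_zz]) * DEBYE_TO_EA
        )
        return CartesianMultipoles(
            origin=origin,
            M=0.0,
            p=np.array([0.0, 0.0, self.p_z * DEBYE_TO_EA]),
            Theta=Theta,
            Omega=self.octupole_tensor_ea(),
            order=3,
        )


def gas_phase_water_moments() -> C2vTarget:
    """Gas-phase water moments from a CCSD/aug-cc-pCVTZ charge density.

    Dipole in D, quadrupole in D·Å, octupole in D·Å², oxygen-origin frame.
    """
    return C2vTarget(
        p_z=1.81,
        Theta_zz=0.08,
        Theta_xx=-2.53,
        Theta_yy=2.45,
        Omega_zzz=-1.35,
        Omega_xxz=-1.25,
        Omega_yyz=2.61,
    )


@dataclass(frozen=True)
class C2vSolution:
    """3-charge C2v solution: pair q_pair at (0, ±y_off, z_pair), q_central at (0,0,z_central)."""

    q_pair: float        # e
    y_off: float         # Å
    z_pair: float        # Å
    q_central: float     # e
    z_central: float     # Å
    octupole_dA2: tuple = ()   # achieved (O_zzz, O_xxz, O_yyz) in D·Å²

    def __post_init__(self):
        if abs(2 * self.q_pair + self.q_central) > 1e-10:
            raise ValueError("total charge must vanish")

    def to_chargeset(self) -> ChargeSet:
        return ChargeSet(
            [self.q_pair, self.q_pair, self.q_central],
            [
                [0.0, -self.y_off, self.z_pair],
                [0.0, self.y_off, self.z_pair],
                [0.0, 0.0, self.z_central],
            ],
            label="water-c2v-3charge",
        )


def _constrained_geometry(z3, S, p, Theta_xx):
    """Solve the monopole/dipole/quadrupole constraints at trial z_central.

    Returns (q_pair, y, z_pair) or None if infeasible (imaginary y).
    """
    z1 = S - z3
    dz = z1 - z3
    if abs(dz) < 1e-12:
        return None
    q1 = p / (2.0 * dz)
    y2 = -Theta_xx / q1 - (z1 * z1 - z3 * z3)
    if y2 < 0.0 or not np.isfinite(y2):
        return None
    return q1, float(np.sqrt(y2)), z1


def _l3_discrepancy(cs: ChargeSet, target_Omega, objective: str) -> float:
    Om = cartesian_moments(cs, (0, 0, 0), order=3).Omega
    dO = Om - target_Omega
    if objective == "cartesian":
        # plain sum of squares over the distinct components
        return dO[2, 2, 2] ** 2 + dO[0, 0, 2] ** 2 + dO[1, 1, 2] ** 2
    # spherical-norm (all-m) objective of the shell-error expansion
    cm = CartesianMultipoles((0, 0, 0), 0.0, np.zeros(3), np.zeros((3, 3)), dO, order=3)
    return float(np.sum(np.abs(cart_to_spherical(cm).coeffs[3]) ** 2))


def solve_water3(
    target: C2vTarget,
    objective: str = "spherical",
    bracket: tuple = (0.0, 1.2),
    xatol: float = 1e-8,
) -> C2vSolution:
    """Solve the C2v 3-charge system for the given target moments.

    Matches monopole (0), dipole and traceless quadrupole exactly, then
    minimizes the l = 3 error term over the free parameter z_central with a
    grid scan plus bounded refinement inside ``bracket``.

    ``objective`` is "spherical" (the all-m octupole norm of the error
    expansion; default) or "cartesian" (plain sum of squares of the three
    distinct components) for sensitivity analysis.
    """
    if objective not in ("spherical", "cartesian"):
        raise ValueError("objective must be 'spherical' or 'cartesian'")
    p = target.p_z * DEBYE_TO_EA
    if abs(p) < 1e-12:
        raise DegenerateInputError("C2v construction needs a nonzero dipole")
    Txx = target.Theta_xx * DEBYE_TO_EA
    Tyy = target.Theta_yy * DEBYE_TO_EA
    S = -2.0 * (Tyy + 2.0 * Txx) / (3.0 * p)
    target_Omega = target.octupole_tensor_ea()

    def build(z3):
        g = _constrained_geometry(z3, S, p, Txx)
        if g is None:
            return None
        q1, y, z1 = g
        return ChargeSet([q1, q1, -2 * q1], [[0, -y, z1], [0, y, z1], [0, 0, z3]])

    def obj(z3):
        cs = build(z3)
        if cs is None:
            return np.inf
        return _l3_discrepancy(cs, target_Omega, objective)

    zs = np.linspace(bracket[0], bracket[1], 2401)
    vals = np.array([obj(z) for z in zs])
    if not np.any(np.isfinite(vals)):
        raise InfeasibleError(
            "no feasible z_central in the bracket (quadrupole pattern forces "
            "an imaginary pair offset)"
        )
    i = int(np.nanargmin(np.where(np.isfinite(vals), vals, np.nan)))
    lo = zs[max(i - 1, 0)]
    hi = zs[min(i + 1, len(zs) - 1)]
    r = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    z3 = float(r.x if r.fun <= vals[i] else zs[i])
    q1, y, z1 = _constrained_geometry(z3, S, p, Txx)
    cs = build(z3)
    Om = cartesian_moments(cs, (0, 0, 0), order=3).Omega
    octu = (
        float(Om[2, 2, 2] / DEBYE_TO_EA),
        float(Om[0, 0, 2] / DEBYE_TO_EA),
        float(Om[1, 1, 2] / DEBYE_TO_EA),
    )
    return C2vSolution(q1, y, z1, -2 * q1, z3, octupole_dA2=octu)


#: experimental gas-phase water geometry (Å): O–H 0.9572 Å, H–O–H 104.52°,
#: hydrogens on the +z side so that p_z > 0 with positive hydrogen charges
WATER_ATOM_POSITIONS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.0, -0.756950, 0.585882],
        [0.0, 0.756950, 0.585882],
    ]
)


def atom_centered_water3(p_z_debye: float, atom_positions=None) -> ChargeSet:
    """Baseline: charges fixed at the O, H, H atom centers, dipole-matched.

    Net charge zero and p_z equal to the target; the quadrupole is whatever
    the geometry dictates (in general it does not match).  Comparison
    baseline only.
    """
    pos = np.asarray(
        WATER_ATOM_POSITIONS if atom_positions is None else atom_positions, float
    ).reshape(3, 3)
    z_h = 0.5 * (pos[1, 2] + pos[2, 2]) - pos[0, 2]
    if abs(z_h) < 1e-9:
        raise DegenerateInputError("degenerate geometry: hydrogens not displaced along z")
    q_h = p_z_debye * DEBYE_TO_EA / (2.0 * z_h)
    return ChargeSet(
        [-2.0 * q_h, q_h, q_h], pos, label="water-atom-centered"
    )
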