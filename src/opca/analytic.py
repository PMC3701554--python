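"""Closed-form 1- and 2-charge optimal / practical point charge approximations.

The 1-charge OPCA is the net charge placed at the center of charge.  The
2-charge case splits by net charge:

* neutral — a ±q pair along the dipole direction, centered at the center
  of dipole.  The pair's traceless quadrupole about that center vanishes
  for every q, so the charge magnitude is fixed one order higher, by the
  octupole term: the optimal squared separation is s² = 4 (Ω : p̂p̂p̂)/|p|
  with Ω about the center of dipole.  When that projection is negative the
  optimum is s → 0 (the "imaginary charge" case) and the practical fallback
  fixes s = d_sep.
* charged — two charges summing to M, placed on the principal axis v₁ of
  the quadrupole about the center of charge, with their center of charge
  kept there and the v₁ quadrupole component matched to λ₁.  The leftover
  one-parameter freedom is closed by the empirical distance ratio κ.

The practical variants (PPCA) replace the octupole closed form with the
fixed small separation / distance ratio and add a mid-field position bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateInputError
from .multipoles import (
    DIPOLE_TOL,
    NEUTRAL_TOL,
    ChargeSet,
    cartesian_moments,
    center_of_charge,
    center_of_dipole,
    center_of_geometry,
    extent,
    quadrupole_principal_axes,
    spherical_moments,
)
from .numeric import OpcaResult, matched_order_of, residuals_about


@dataclass(frozen=True)
class Ppca2Config:
    """Empirical constants of the practical 2-charge constructions."""

    d_sep: float = 0.1          # Å, fixed pair separation for the neutral PPCA
    bound_factor: float = 1.5   # position bound in units of the extent a
    kappa: float = 1.5          # distance ratio r1/r2 for the charged case
    neutral_tol: float = NEUTRAL_TOL

    def __post_init__(self):
        if self.d_sep <= 0:
            raise ValueError("d_sep must be positive")
        if self.bound_factor < 1:
            raise ValueError("bound_factor must be >= 1")
        if self.kappa <= 0 or self.kappa == 1.0:
            raise ValueError("kappa must be positive and != 1")


def _result(cs, approx, origin, fallback="none", diagnostics="") -> OpcaResult:
    sm = spherical_moments(cs, origin, 3)
    res = residuals_about(sm, approx, origin, 3)
    return OpcaResult(
        approx=approx,
        matched_order=matched_order_of(res),
        residual_per_order=res,
        fallback=fallback,
        diagnostics=diagnostics,
        origin=origin,
    )


def opca1(cs: ChargeSet, neutral_tol: float = NEUTRAL_TOL) -> OpcaResult:
    """1-charge OPCA: the net charge M at the center of charge.

    Zeroes the monopole and dipole error terms; only defined for charged
    distributions.
    """
    M = cs.net_charge
    if abs(M) <= neutral_tol:
        raise DegenerateInputError(
            "1-charge approximation needs a net charge; use a 2-charge solver "
            "(opca2_neutral / ppca2_neutral) for neutral distributions"
        )
    coc = center_of_charge(cs, neutral_tol)
    approx = ChargeSet([M], [coc], label=f"opca1[{cs.label}]")
    return _result(cs, approx, coc)


def _octupole_projection(cs: ChargeSet, origin, u) -> float:
    Om = cartesian_moments(cs, origin, order=3).Omega
    return float(np.einsum("jkl,j,k,l->", Om, u, u, u))


def opca2_neutral(cs: ChargeSet, cfg: Ppca2Config | None = None) -> OpcaResult:
    """2-charge OPCA for a neutral distribution.

    Falls back to the fixed separation ``cfg.d_sep`` (fallback flag
    ``small_separation``) when the octupole closed form would require an
    imaginary charge.
    """
    cfg = cfg or Ppca2Config()
    _require_neutral_dipole(cs, cfg)
    cod = center_of_dipole(cs)
    p = cartesian_moments(cs, cod, order=1).p
    pn = float(np.linalg.norm(p))
    u = p / pn
    s2 = 4.0 * _octupole_projection(cs, cod, u) / pn
    if s2 > DIPOLE_TOL:
        s = float(np.sqrt(s2))
        fallback, diag = "none", f"octupole-optimal separation s={s:.6g} A"
    else:
        s = cfg.d_sep
        fallback = "small_separation"
        diag = "octupole projection <= 0 (imaginary optimal charge); fixed separation"
    q = pn / s
    approx = ChargeSet(
        [q, -q], [cod + 0.5 * s * u, cod - 0.5 * s * u], label=f"opca2[{cs.label}]"
    )
    return _result(cs, approx, cod, fallback, diag)


def ppca2_neutral(cs: ChargeSet, cfg: Ppca2Config | None = None) -> OpcaResult:
    """Practical 2-charge approximation for a neutral distribution.

    (i) pair centered at the center of dipole, (ii) separation fixed at
    ``cfg.d_sep``, (iii) q = |p|/d_sep along p̂, (iv) if either charge lies
    beyond ``bound_factor``·a from the center of geometry, the pair center
    is shifted toward the center of geometry until both are inside
    (fallback flag ``bound_shift``).
    """
    cfg = cfg or Ppca2Config()
    _require_neutral_dipole(cs, cfg)
    cod = center_of_dipole(cs)
    p = cartesian_moments(cs, cod, order=1).p
    pn = float(np.linalg.norm(p))
    u = p / pn
    s = cfg.d_sep
    q = pn / s
    cog = center_of_geometry(cs)
    a = extent(cs)
    bound = cfg.bound_factor * a
    center = cod
    fallback, diag = "none", ""

    def worst(c):
        return max(
            np.linalg.norm(c + 0.5 * s * u - cog), np.linalg.norm(c - 0.5 * s * u - cog)
        )

    if worst(cod) > bound:
        w = cog - cod
        dist = np.linalg.norm(w)
        w = w / dist

        def f(t):
            return worst(cod + t * w) - bound

        # moving the pair center onto the center of geometry always satisfies
        # the bound (s/2 + 0 <= 1.5a for any sane separation)
        t = brentq(f, 0.0, dist) if f(dist) <= 0 else dist
        center = cod + t * w
        fallback = "bound_shift"
        diag = f"pair center shifted {t:.4g} A toward the center of geometry"
    approx = ChargeSet(
        [q, -q], [center + 0.5 * s * u, center - 0.5 * s * u], label=f"ppca2[{cs.label}]"
    )
    return _result(cs, approx, cod, fallback, diag)


def ppca2_charged(cs: ChargeSet, cfg: Ppca2Config | None = None) -> OpcaResult:
    """Practical 2-charge approximation for a charged distribution.

    Both charges lie on the principal axis v₁ of the quadrupole about the
    center of charge; q₁+q₂ = M, the pair's center of charge coincides with
    the original's, and the v₁ quadrupole component equals λ₁.  The distance
    ratio |r₁|/|r₂| = κ closes the remaining freedom; the larger distance
    goes with the smaller-|q| charge.  Sign(λ₁) ≠ sign(M) is realized with
    opposite-sign charges on the same side of the center of charge.
    """
    cfg = cfg or Ppca2Config()
    M = cs.net_charge
    if abs(M) <= cfg.neutral_tol:
        raise DegenerateInputError("charged 2-charge construction needs a net charge")
    coc = center_of_charge(cs, cfg.neutral_tol)
    Theta = cartesian_moments(cs, coc, order=2).Theta
    pq = quadrupole_principal_axes(Theta)
    lam1, v1 = pq.lambda1, pq.v1
    k = cfg.kappa
    if pq.degenerate or abs(lam1) < 1e-12:
        approx = ChargeSet(
            [M / 2, M / 2], [coc, coc], label=f"ppca2[{cs.label}]"
        )
        return _result(
            cs, approx, coc, fallback="degenerate",
            diagnostics="vanishing quadrupole about the center of charge; "
            "1-charge optimum split in two",
        )
    if lam1 / M > 0:
        # same-sign charges on opposite sides of the center of charge
        q1, q2 = M / (1 + k), k * M / (1 + k)
        a1 = float(np.sqrt(lam1 * k / M))
        a2 = -a1 / k
        case = "same-sign"
    else:
        # opposite-sign charges on the same side
        q1, q2 = -M / (k - 1), k * M / (k - 1)
        a2 = float(np.sqrt(-lam1 / (M * k)))
        a1 = k * a2
        case = "opposite-sign"
    approx = ChargeSet(
        [q1, q2], [coc + a1 * v1, coc + a2 * v1], label=f"ppca2[{cs.label}]"
    )
    return _result(cs, approx, coc, diagnostics=f"kappa={k} case={case} lambda1={lam1:.6g}")


def ppca2(cs: ChargeSet, cfg: Ppca2Config | None = None) -> OpcaResult:
    """Practical 2-charge approximation, dispatching on the net charge.

    Sets with |M| < ``cfg.neutral_tol`` take the neutral branch (so an |M|
    of half the tolerance is, by documented rule, neutral).
    """
    cfg = cfg or Ppca2Config()
    if abs(cs.net_charge) < cfg.neutral_tol:
        out = ppca2_neutral(cs, cfg)
        branch = "neutral"
    else:
        out = ppca2_charged(cs, cfg)
        branch = "charged"
    return OpcaResult(
        approx=out.approx,
        matched_order=out.matched_order,
        residual_per_order=out.residual_per_order,
        fallback=out.fallback,
        diagnostics=f"branch={branch}; {out.diagnostics}",
        origin=out.origin,
    )


def _require_neutral_dipole(cs: ChargeSet, cfg: Ppca2Config) -> None:
    if abs(cs.net_charge) > cfg.neutral_tol:
        raise DegenerateInputError("neutral 2-charge construction requires |M| ~ 0")
    p = cartesian_moments(cs, center_of_geometry(cs), order=1).p
    if np.linalg.norm(p) <= DIPOLE_TOL:
        raise DegenerateInputError(
            "2-charge dipole construction undefined for |p| ~ 0 "
            "(e.g. a pure quadrupole); use solve_opca(n=2) directly"
        )
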