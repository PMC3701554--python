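"""General N→n optimal point charge approximation by sequential minimization.

The solver minimizes the terms of the shell-error expansion order by order
(lexicographically): first the monopole mismatch Σ_m |Δq_0m|², then, with
that pinned near its minimum, the dipole mismatch, and so on through
``l_max``.  Each stage is a constrained minimization (SLSQP) in the 4n
parameters (charge + position per approximating charge), with every earlier
order held at or below the stage tolerance.  Stages whose objective cannot
respond to the parameters (zero gradient at the incumbent — e.g. the
quadrupole of a dipole-matched pair at the center of dipole) are skipped.

Nonconvexity is handled by multi-start: deterministic seeds built from the
center of charge / center of dipole plus random placements inside the
extent sphere, with a fixed default seed.  The best run is selected by
lexicographic comparison of the per-order residuals.

This module also serves as the independent oracle for the closed-form
solvers in :mod:`opca.analytic` and :mod:`opca.water`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from functools import lru_cache

from .errors import ConvergenceError, DegenerateInputError
from .multipoles import (
    NEUTRAL_TOL,
    CartesianMultipoles,
    ChargeSet,
    _harmonic_tensor,
    cart_to_spherical,
    cartesian_moments,
    center_of_charge,
    center_of_geometry,
    center_of_dipole,
    extent,
    quadrupole_principal_axes,
    spherical_moments,
)

#: squared moment mismatch allowed in pinned earlier stages
STAGE_TOL = 1e-10

#: a stage residual below this counts as "matched" when comparing runs
#: (coarser than STAGE_TOL so bound-limited drift does not mask a match)
MATCH_BAND = 1e-9


@dataclass
class OpcaOptions:
    """Tuning knobs for the sequential solver."""

    l_max: int = 3
    restarts: int = 16
    seed: int = 20130704
    bounded: bool = False
    bound_factor: float = 1.5
    stage_tol: float = STAGE_TOL
    maxiter: int = 200


@dataclass(frozen=True)
class OpcaResult:
    """An approximating charge set plus diagnostics."""

    approx: ChargeSet
    matched_order: int
    residual_per_order: dict
    fallback: str = "none"          # none | small_separation | bound_shift | degenerate
    diagnostics: str = ""
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))


def residuals_about(cs_ref_moments, approx: ChargeSet, origin, l_max: int) -> dict:
    """Per-order squared spherical-moment mismatch Σ_m |Δq_lm|² about ``origin``."""
    sm_b = spherical_moments(approx, origin, l_max)
    return {
        l: float(np.sum(np.abs(cs_ref_moments.coeffs[l] - sm_b.coeffs[l]) ** 2))
        for l in range(l_max + 1)
    }


def matched_order_of(res: dict, tol: float = MATCH_BAND) -> int:
    matched = -1
    for l in sorted(res):
        if res[l] <= tol:
            matched = l
        else:
            break
    return matched


def _lex_key(res: dict, l_max: int, band: float = MATCH_BAND):
    """Comparison key: matched orders collapse to 0, the rest are quantized
    to 6 significant digits so float noise in a tied order cannot outrank a
    genuine improvement at the next order."""
    return tuple(
        0.0 if res[l] <= band else float(f"{res[l]:.6e}") for l in range(l_max + 1)
    )


@lru_cache(maxsize=None)
def _solid_basis(l: int):
    """Stacked conjugate solid-harmonic coefficient tensors, shape (2l+1, 3, ..)."""
    return np.stack([np.conj(_harmonic_tensor(l, m)) for m in range(-l, l + 1)])


def _order_moments(q, d, l) -> np.ndarray:
    """q_lm (m = −l..l) of charges ``q`` at origin-relative positions ``d``.

    Contracting the raw position-moment sums against the traceless solid
    harmonic coefficient tensors gives the spherical moments directly.
    """
    if l == 0:
        return np.array([complex(_harmonic_tensor(0, 0)) * q.sum()])
    if l == 1:
        return _solid_basis(1) @ (q @ d)
    if l == 2:
        return np.einsum("mjk,jk->m", _solid_basis(2), np.einsum("i,ij,ik->jk", q, d, d))
    return np.einsum(
        "mjkl,jkl->m", _solid_basis(3), np.einsum("i,ij,ik,il->jkl", q, d, d, d)
    )


class _MomentModel:
    """Maps a parameter vector [q_1..q_n, xyz_1..xyz_n] to moment residuals."""

    def __init__(self, target_sm, origin, n, l_max):
        self.origin = np.asarray(origin, float)
        self.n = n
        self.l_max = l_max
        self.target = [np.asarray(target_sm.coeffs[l]) for l in range(l_max + 1)]

    def chargeset(self, x) -> ChargeSet:
        n = self.n
        return ChargeSet(x[:n], x[n:].reshape(n, 3))

    def _qd(self, x):
        n = self.n
        return x[:n], x[n:].reshape(n, 3) - self.origin

    def scale_vector(self, x0, a) -> np.ndarray:
        scale = np.ones_like(x0)
        scale[: self.n] = max(1.0, np.abs(x0[: self.n]).max())
        scale[self.n :] = max(0.3, a)
        return scale

    def stage(self, x, l) -> float:
        q, d = self._qd(x)
        dq = _order_moments(q, d, l) - self.target[l]
        return float(np.real(dq @ np.conj(dq)))

    def stage_components(self, x, l) -> np.ndarray:
        """Real residual components of order l: (q_l0, Re q_lm, Im q_lm)_{m>0}.

        Unlike the squared stage objective, these have nonvanishing
        gradients on the zero surface, which is what a constrained
        optimizer needs to track an exactly-matched order.
        """
        q, d = self._qd(x)
        dq = _order_moments(q, d, l) - self.target[l]
        parts = [dq[l].real]
        for m in range(1, l + 1):
            parts.extend([dq[l + m].real, dq[l + m].imag])
        return np.array(parts)

    def residuals(self, x) -> dict:
        return {l: self.stage(x, l) for l in range(self.l_max + 1)}


def _grad_norm(f, x, h=1e-6):
    g = np.empty_like(x)
    f0 = f(x)
    for i in range(x.size):
        xp = x.copy()
        xp[i] += h
        g[i] = (f(xp) - f0) / h
    return float(np.linalg.norm(g))


def _stagewise_once(model: _MomentModel, x0, opts: OpcaOptions, center, a, constraints_extra=()):
    """One lexicographic pass.

    Phase A drives as many leading orders to zero as possible with
    trust-region nonlinear least squares on the stacked moment components
    (robust to the narrow ravines that tight charge pairs create).  Phase B
    then minimizes each remaining order with SLSQP, matched orders held as
    per-component equality constraints (nondegenerate Jacobian on the zero
    surface) and non-zeroable earlier orders pinned at their achieved value.
    """
    x0 = np.asarray(x0, float)
    nq = model.n
    scale = model.scale_vector(x0, a)

    def phys(y):
        return y * scale

    y = x0 / scale
    skipped = []
    bounds = []
    l_start = 0
    for l in range(opts.l_max + 1):
        stacked = lambda y, l=l: np.concatenate(
            [model.stage_components(phys(y), k) for k in range(l + 1)]
        )
        if model.stage(phys(y), l) > opts.stage_tol or l == 0:
            sol = least_squares(stacked, y, method="trf", xtol=3e-16, ftol=3e-16, gtol=1e-14,
                                max_nfev=80 * y.size)
            cand = sol.x
        else:
            cand = y
        if all(model.stage(phys(cand), k) <= opts.stage_tol for k in range(l + 1)):
            y = cand
            bounds.append(opts.stage_tol)
            l_start = l + 1
        else:
            break
    for l in range(l_start, opts.l_max + 1):
        f = lambda y, l=l: model.stage(phys(y), l)
        fy = f(y)
        if fy <= opts.stage_tol and _grad_norm(f, y) < 1e-7 * (1.0 + fy):
            skipped.append(l)
            bounds.append(opts.stage_tol)
            continue
        cons = []
        for k, b in enumerate(bounds):
            if b <= opts.stage_tol:
                cons.append(
                    {"type": "eq", "fun": (lambda y, k=k: model.stage_components(phys(y), k))}
                )
            else:
                cons.append(
                    {"type": "ineq", "fun": (lambda y, k=k, b=b: b - model.stage(phys(y), k))}
                )
        for c in constraints_extra:
            cons.append({"type": c["type"], "fun": (lambda y, c=c: c["fun"](phys(y)))})
        if opts.bounded:
            bound = opts.bound_factor * a

            def inside(y, nq=nq, bound=bound, center=center):
                r = phys(y)[nq:].reshape(nq, 3) - center
                return bound**2 - np.einsum("ij,ij->i", r, r)

            cons.append({"type": "ineq", "fun": inside})
        res = minimize(
            f,
            y,
            method="SLSQP",
            constraints=cons,
            options={"maxiter": opts.maxiter, "ftol": 1e-13 * (1.0 + fy)},
        )
        cand = res.x
        # accept only if it does not break earlier stages
        ok = all(
            model.stage(phys(cand), k) <= b * (1 + 1e-6) + 1e-12 for k, b in enumerate(bounds)
        )
        if ok and f(cand) <= fy:
            y = cand
        if (
            l >= 1
            and not opts.bounded
            and not constraints_extra
            and all(b <= opts.stage_tol for b in bounds)
        ):
            # every earlier order matched exactly: finish the stage with a
            # null-space predictor/corrector walk along the match manifold
            walked = _manifold_descent(model, phys(y), l, opts, a)
            if all(
                model.stage(walked, k) <= b * (1 + 1e-6) + 1e-12
                for k, b in enumerate(bounds)
            ) and model.stage(walked, l) <= f(y):
                y = walked / scale
        bounds.append(max(opts.stage_tol, f(y) * (1 + 1e-9) + 1e-14))
    return phys(y), skipped


def _manifold_descent(model: _MomentModel, x, l, opts: OpcaOptions, a):
    """Minimize stage ``l`` over the manifold where all orders k < l are
    matched exactly.

    Predictor–corrector scheme: step along the (numerical) null space of the
    matched-components Jacobian, then re-project onto the manifold with a
    trust-region least-squares corrector.  Handles the long, narrow ravines
    (e.g. pair separation vs charge magnitude trade-offs) where a single SQP
    run stalls.
    """
    scale = model.scale_vector(x, a)

    def matched(y):
        return np.concatenate(
            [model.stage_components(y * scale, k) for k in range(l)]
        )

    def correct(y):
        sol = least_squares(matched, y, method="trf", xtol=3e-16, ftol=3e-16,
                            gtol=1e-14, max_nfev=40 * y.size)
        return sol.x

    def fl(y):
        return model.stage(y * scale, l)

    y = x / scale
    best = fl(y)
    for _ in range(60):
        m = matched(y)
        h = 1e-6
        J = np.empty((m.size, y.size))
        for i in range(y.size):
            yp = y.copy()
            yp[i] += h
            J[:, i] = (matched(yp) - m) / h
        _, s, Vt = np.linalg.svd(J, full_matrices=True)
        rank = int(np.sum(s > max(1e-8 * (s[0] if s.size else 1.0), 1e-12)))
        null = Vt[rank:]
        # the walk pays off on low-dimensional match manifolds (the ravine
        # cases); higher-dimensional stages are left to the SQP step
        if null.shape[0] == 0 or null.shape[0] > 2:
            break
        improved = False
        for v in null:
            for t in (3.0, 1.0, 0.3, 0.1, 0.03, 0.01, 0.003):
                for sgn in (1.0, -1.0):
                    cand = correct(y + sgn * t * v)
                    if np.max(np.abs(matched(cand)) ** 2, initial=0.0) > opts.stage_tol:
                        continue
                    fc = fl(cand)
                    if fc < best * (1 - 1e-10) - 1e-16:
                        y, best = cand, fc
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return y * scale


def _stagewise(model: _MomentModel, x0, opts: OpcaOptions, center, a, constraints_extra=()):
    """Repeated lexicographic sweeps until the residual profile stops improving."""
    x = np.asarray(x0, float).copy()
    skipped = []
    last = None
    for _ in range(3):
        x, skipped = _stagewise_once(model, x, opts, center, a, constraints_extra)
        prof = _lex_key(model.residuals(x), opts.l_max)
        if last is not None and all(
            new >= old * (1 - 1e-8) - 1e-14 for new, old in zip(prof, last)
        ):
            break
        last = prof
    return x, skipped


def _seeds(cs, n, origin, a, opts, rng):
    seeds = []
    cog = center_of_geometry(cs)
    M = cs.net_charge
    cm = cartesian_moments(cs, cog, order=2)
    p = cm.p
    pn = np.linalg.norm(p)

    def pack(q, r):
        return np.concatenate([np.asarray(q, float), np.asarray(r, float).ravel()])

    if n == len(cs):
        seeds.append(pack(cs.q, cs.r))
    # largest-|q| subset of the original charges
    idx = np.argsort(-np.abs(cs.q))[:n]
    seeds.append(pack(cs.q[idx], cs.r[idx]))
    if abs(M) > NEUTRAL_TOL:
        coc = center_of_charge(cs)
        if n == 1:
            seeds.append(pack([M], [coc]))
        else:
            pq = quadrupole_principal_axes(cartesian_moments(cs, coc, 2).Theta)
            off = 0.3 * a * pq.v1
            qs = np.full(n, M / n)
            rs = np.array([coc + (i - (n - 1) / 2) * off for i in range(n)])
            seeds.append(pack(qs, rs))
    elif pn > 1e-12 and n >= 2:
        try:
            cod = center_of_dipole(cs)
        except DegenerateInputError:
            cod = cog
        u = p / pn
        # dipole-matched pairs over a ladder of separations: multi-start
        # across the one-dimensional family the 2-charge optimum lives in
        for s in (0.1, 0.25 * a, 0.5 * a, a, 1.5 * a, 2.0 * a):
            q = pn / s
            rs = np.zeros((n, 3))
            qs = np.zeros(n)
            qs[0], qs[1] = q, -q
            rs[0], rs[1] = cod + 0.5 * s * u, cod - 0.5 * s * u
            if n > 2:
                rs[2:] = cog + rng.uniform(-0.3, 0.3, (n - 2, 3)) * a
            seeds.append(pack(qs, rs))
    while len(seeds) < opts.restarts:
        qs = rng.uniform(-1.0, 1.0, n)
        if n > 1:
            qs += (M - qs.sum()) / n
        else:
            qs[:] = M if abs(M) > NEUTRAL_TOL else qs
        rs = cog + rng.uniform(-1.0, 1.0, (n, 3)) * a
        seeds.append(pack(qs, rs))
    return seeds[: max(opts.restarts, len(seeds))]


def _solve(target_sm, origin, n, seeds, opts, center, a, constraints_extra=(), label=""):
    model = _MomentModel(target_sm, origin, n, opts.l_max)
    best = None
    best_key = None
    best_skipped = []
    for x0 in seeds:
        x, skipped = _stagewise(model, x0, opts, center, a, constraints_extra)
        res = model.residuals(x)
        key = _lex_key(res, opts.l_max)
        if best_key is None or key < best_key:
            best, best_key, best_skipped = x, key, skipped
            if all(v == 0.0 for v in key):
                break
    if best is None:
        raise ConvergenceError("no restart produced a usable solution")
    res = model.residuals(best)
    approx = model.chargeset(best)
    approx = ChargeSet(approx.q, approx.r, label=label)
    diag = f"restarts={len(seeds)} skipped_stages={best_skipped}"
    return OpcaResult(
        approx=approx,
        matched_order=matched_order_of(res),
        residual_per_order=res,
        fallback="none",
        diagnostics=diag,
        origin=origin,
    )


def solve_opca(cs: ChargeSet, n: int, l_max: int = 3, options: OpcaOptions | None = None) -> OpcaResult:
    """Optimal n-charge approximation of ``cs`` by sequential minimization.

    The expansion center follows the method's convention: the center of
    charge for charged sets, the center of dipole for neutral sets with a
    dipole, and the center of geometry otherwise.  (Orders that are matched
    exactly are matched about every center; the choice only matters for the
    first order that cannot be zeroed, where the sequential procedure is
    defined about the optimal expansion center of the preceding order.)
    Deterministic for a fixed ``options.seed``.
    """
    if not (1 <= n <= len(cs)):
        raise ValueError(f"need 1 <= n <= {len(cs)}, got {n}")
    opts = replace(options or OpcaOptions(), l_max=min(l_max, 3))
    if abs(cs.net_charge) > NEUTRAL_TOL:
        origin = center_of_charge(cs)
    else:
        try:
            origin = center_of_dipole(cs)
        except DegenerateInputError:
            origin = center_of_geometry(cs)
    a = extent(cs)
    target = spherical_moments(cs, origin, opts.l_max)
    rng = np.random.default_rng(opts.seed)
    seeds = _seeds(cs, n, origin, a, opts, rng)
    return _solve(target, origin, n, seeds, opts, origin, a, label=f"opca{n}[{cs.label}]")


# ---------------------------------------------------------------------------
# symmetry-constrained solve against target moments


@dataclass(frozen=True)
class SymmetrySpec:
    """Equality constraints on charges/coordinates via a shared parameter vector.

    ``charge_map`` has one row per site: (scale, param_index) so that
    q_site = scale * theta[param_index].  ``coord_map`` has one row per
    site and axis: (scale, param_index) with param_index = -1 meaning the
    coordinate is fixed at ``scale``.
    """

    n_params: int
    charge_map: tuple           # ((scale, idx), ...) per site
    coord_map: tuple            # (((scale, idx), (scale, idx), (scale, idx)), ...) per site
    name: str = ""

    @property
    def n_sites(self) -> int:
        return len(self.charge_map)

    def build(self, theta) -> ChargeSet:
        theta = np.asarray(theta, float)
        q = np.array([s * theta[i] for s, i in self.charge_map])
        r = np.array(
            [
                [s if i < 0 else s * theta[i] for s, i in site]
                for site in self.coord_map
            ]
        )
        return ChargeSet(q, r, label=self.name)


def c2v_3charge_spec() -> SymmetrySpec:
    """Three charges with C2v symmetry: a mirror pair at (0, ±y, z1), one at (0, 0, z3).

    Parameters: theta = (q_pair, y, z1, q_central, z3); neutrality is left to
    the monopole stage rather than being hard-wired.
    """
    return SymmetrySpec(
        n_params=5,
        charge_map=((1.0, 0), (1.0, 0), (1.0, 3)),
        coord_map=(
            ((0.0, -1), (-1.0, 1), (1.0, 2)),
            ((0.0, -1), (1.0, 1), (1.0, 2)),
            ((0.0, -1), (0.0, -1), (1.0, 4)),
        ),
        name="c2v-3charge",
    )


class _SymmetryModel(_MomentModel):
    def __init__(self, target_sm, origin, spec, l_max):
        super().__init__(target_sm, origin, spec.n_sites, l_max)
        self.spec = spec

    def chargeset(self, x) -> ChargeSet:
        return self.spec.build(x)

    def _qd(self, x):
        cs = self.spec.build(x)
        return cs.q, cs.r - self.origin

    def scale_vector(self, x0, a) -> np.ndarray:
        return np.maximum(1.0, np.abs(x0))


def solve_opca_constrained(
    target: CartesianMultipoles,
    n: int,
    symmetry: SymmetrySpec | None,
    options: OpcaOptions | None = None,
    free_param_objective: str = "spherical",
    seeds=None,
) -> OpcaResult:
    """Sequential solve against target moments under equality constraints.

    With ``symmetry=None`` this is :func:`solve_opca` applied to a target
    moment set instead of a charge set (the charges are unconstrained).
    ``free_param_objective`` is kept for interface symmetry with the water
    solver; the lexicographic stages already use the spherical-norm (all-m)
    objective of the shell-error expansion.
    """
    opts = options or OpcaOptions()
    target_sm = cart_to_spherical(target)
    origin = target.origin
    rng = np.random.default_rng(opts.seed)
    if symmetry is None:
        scale = max(np.linalg.norm(target.p), 1.0)
        seeds = seeds or [
            np.concatenate([rng.uniform(-2, 2, n) * scale, rng.uniform(-1, 1, 3 * n)])
            for _ in range(opts.restarts)
        ]
        return _solve(target_sm, origin, n, seeds, opts, origin, 1.0, label="opca-target")
    if symmetry.n_sites != n:
        raise ValueError("symmetry spec does not produce n charges")
    model = _SymmetryModel(target_sm, origin, symmetry, opts.l_max)
    if seeds is None:
        # tight-pair optima need charge parameters orders of magnitude larger
        # than coordinate parameters: draw magnitudes log-uniformly
        seeds = []
        for _ in range(max(opts.restarts, 24)):
            mag = 10.0 ** rng.uniform(0.0, 1.6, symmetry.n_params)
            seeds.append(rng.uniform(-1.0, 1.0, symmetry.n_params) * mag)
    best, best_key, best_skipped = None, None, []
    for x0 in seeds:
        x, skipped = _stagewise(model, np.asarray(x0, float), opts, origin, 1.0)
        res = model.residuals(x)
        key = _lex_key(res, opts.l_max)
        if best_key is None or key < best_key:
            best, best_key, best_skipped = x, key, skipped
    if best is None:
        raise ConvergenceError("constrained solve failed for every restart")
    res = model.residuals(best)
    feasible_orders = [l for l in res if res[l] <= MATCH_BAND]
    if not feasible_orders:
        raise ConvergenceError("over-constrained symmetry spec: no order could be matched")
    return OpcaResult(
        approx=model.chargeset(best),
        matched_order=matched_order_of(res),
        residual_per_order=res,
        diagnostics=f"symmetry={symmetry.name} skipped_stages={best_skipped}",
        origin=origin,
    )
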