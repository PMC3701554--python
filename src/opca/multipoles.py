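"""Point-charge sets and their multipole moments.

Units are elementary charges (e) and ångströms (Å) throughout; the
1/(4πε₀) factor is dropped, so potentials come out in e/Å.

Conventions
-----------
Cartesian quadrupole and octupole tensors are the traceless (Buckingham)
forms with a ½ prefactor,

    Θ_jk  = ½ Σ_i q_i (3 x_j x_k − r² δ_jk),
    Ω_jkl = ½ Σ_i q_i (5 x_j x_k x_l − r² (x_j δ_kl + x_k δ_jl + x_l δ_jk)),

which is the convention in which gas-phase water quadrupoles are usually
tabulated (Q_xx ≈ −2.5 D·Å, ...).  Spherical moments use orthonormal
complex spherical harmonics with the Condon–Shortley phase,

    q_lm = Σ_i q_i r_i^l Y*_lm(θ_i, φ_i),

so that φ(r) = Σ_lm 4π/(2l+1) q_lm Y_lm(θ,φ) / r^{l+1}.  Every moments
object records the convention string so mismatches can be detected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .errors import ConventionError, DegenerateInputError

#: identifier recorded on every moments object produced by this module
CONVENTION = "traceless-buckingham-half/orthonormal-complex-cs"

#: 1 debye in e·Å
DEBYE_TO_EA = 0.2082

#: a set is treated as neutral when |M| is below this (e)
NEUTRAL_TOL = 1e-8

#: a dipole below this magnitude (e·Å) is treated as zero
DIPOLE_TOL = 1e-10

_EYE = np.eye(3)


# ---------------------------------------------------------------------------
# charge sets


@dataclass(frozen=True)
class ChargeSet:
    """A labeled set of point charges: values ``q`` (e) at positions ``r`` (Å)."""

    q: np.ndarray
    r: np.ndarray
    label: str = ""

    def __post_init__(self):
        q = np.atleast_1d(np.asarray(self.q, dtype=float))
        r = np.asarray(self.r, dtype=float).reshape(-1, 3)
        if q.size < 1:
            raise ValueError("a ChargeSet needs at least one charge")
        if q.shape[0] != r.shape[0]:
            raise ValueError(f"{q.shape[0]} charges but {r.shape[0]} positions")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(r))):
            raise ValueError("charges and coordinates must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return self.q.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.q.sum())

    def is_neutral(self, tol: float = NEUTRAL_TOL) -> bool:
        return abs(self.net_charge) < tol

    def translated(self, shift) -> "ChargeSet":
        return ChargeSet(self.q.copy(), self.r + np.asarray(shift, float), self.label)

    def rotated(self, rot, about=(0.0, 0.0, 0.0)) -> "ChargeSet":
        """Rigidly rotate by the 3×3 matrix ``rot`` about the point ``about``."""
        rot = np.asarray(rot, float)
        about = np.asarray(about, float)
        return ChargeSet(self.q.copy(), (self.r - about) @ rot.T + about, self.label)


def center_of_geometry(cs: ChargeSet) -> np.ndarray:
    return cs.r.mean(axis=0)


def center_of_charge(cs: ChargeSet, tol: float = NEUTRAL_TOL) -> np.ndarray:
    """Charge-weighted mean position Σ q_i r_i / M.

    Raises
    ------
    DegenerateInputError
        if the set is numerically neutral (|M| < ``tol``).
    """
    M = cs.net_charge
    if abs(M) < tol:
        raise DegenerateInputError(
            f"center of charge undefined for a neutral set (|M|={abs(M):.2e} e)"
        )
    return cs.q @ cs.r / M


def extent(cs: ChargeSet, center=None) -> float:
    """Distance from ``center`` (default: center of geometry) to the outermost charge."""
    if center is None:
        center = center_of_geometry(cs)
    return float(np.linalg.norm(cs.r - np.asarray(center, float), axis=1).max())


# ---------------------------------------------------------------------------
# Cartesian moments


@dataclass(frozen=True)
class CartesianMultipoles:
    """Traceless Cartesian multipole moments about a stated origin.

    ``M`` in e, ``p`` in e·Å, ``Theta`` in e·Å², ``Omega`` in e·Å³.
    """

    origin: np.ndarray
    M: float
    p: np.ndarray
    Theta: np.ndarray
    Omega: np.ndarray
    order: int = 3
    convention: str = CONVENTION

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(self, "p", np.asarray(self.p, float).reshape(3))
        object.__setattr__(self, "Theta", np.asarray(self.Theta, float).reshape(3, 3))
        object.__setattr__(self, "Omega", np.asarray(self.Omega, float).reshape(3, 3, 3))

    def check(self, tol: float = 1e-10) -> None:
        """Assert symmetry/tracelessness invariants (relative to tensor norms)."""
        th, om = self.Theta, self.Omega
        nth = max(np.linalg.norm(th), 1.0)
        nom = max(np.linalg.norm(om), 1.0)
        if abs(np.trace(th)) > tol * nth:
            raise ValueError("quadrupole tensor is not traceless")
        if np.abs(th - th.T).max() > tol * nth:
            raise ValueError("quadrupole tensor is not symmetric")
        for perm in itertools.permutations(range(3)):
            if np.abs(om - om.transpose(perm)).max() > tol * nom:
                raise ValueError("octupole tensor is not fully symmetric")
        if np.abs(np.einsum("jjk->k", om)).max() > tol * nom:
            raise ValueError("octupole tensor is not traceless")


def cartesian_moments(cs: ChargeSet, origin=(0.0, 0.0, 0.0), order: int = 3) -> CartesianMultipoles:
    """Moments of ``cs`` about ``origin`` through ``order`` ≤ 3 (higher tensors zeroed)."""
    if order not in (0, 1, 2, 3):
        raise ValueError(f"order must be in 0..3, got {order}")
    origin = np.asarray(origin, float).reshape(3)
    d = cs.r - origin
    q = cs.q
    r2 = np.einsum("ij,ij->i", d, d)
    M = float(q.sum())
    p = np.zeros(3)
    Theta = np.zeros((3, 3))
    Omega = np.zeros((3, 3, 3))
    if order >= 1:
        p = q @ d
    if order >= 2:
        Theta = 0.5 * (3.0 * np.einsum("i,ij,ik->jk", q, d, d) - (q @ r2) * _EYE)
    if order >= 3:
        t = (q * r2) @ d  # Σ q r² x_j
        tr = (
            np.einsum("j,kl->jkl", t, _EYE)
            + np.einsum("k,jl->jkl", t, _EYE)
            + np.einsum("l,jk->jkl", t, _EYE)
        )
        Omega = 0.5 * (5.0 * np.einsum("i,ij,ik,il->jkl", q, d, d, d) - tr)
    return CartesianMultipoles(origin, M, p, Theta, Omega, order=order)


def shift_origin(cs: ChargeSet, new_origin, order: int = 3) -> CartesianMultipoles:
    """Moments of the same ChargeSet about a new origin.

    Recomputed from the charges rather than by translation theorems, which
    keeps the result convention-independent.
    """
    return cartesian_moments(cs, new_origin, order=order)


# ---------------------------------------------------------------------------
# spherical moments


@dataclass(frozen=True)
class SphericalMultipoles:
    """Complex spherical moments ``q_lm`` for 0 ≤ l ≤ l_max about an origin.

    ``coeffs[l]`` is a complex array of length 2l+1 holding m = −l..l.
    """

    origin: np.ndarray
    coeffs: tuple
    convention: str = CONVENTION

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        object.__setattr__(
            self, "coeffs", tuple(np.asarray(c, complex).reshape(2 * l + 1) for l, c in enumerate(self.coeffs))
        )
        for c in self.coeffs:
            if not np.all(np.isfinite(c)):
                raise ValueError("spherical moments must be finite")

    @property
    def l_max(self) -> int:
        return len(self.coeffs) - 1

    def q(self, l: int, m: int) -> complex:
        return complex(self.coeffs[l][m + l])


def spherical_moments(cs: ChargeSet, origin=(0.0, 0.0, 0.0), l_max: int = 3) -> SphericalMultipoles:
    """q_lm = Σ q_i ρ_i^l Y*_lm computed directly from the charges."""
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    origin = np.asarray(origin, float).reshape(3)
    d = cs.r - origin
    rho = np.linalg.norm(d, axis=1)
    # polar/azimuth; charges at the origin only contribute to l = 0
    safe = np.where(rho > 0, rho, 1.0)
    theta = np.arccos(np.clip(d[:, 2] / safe, -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    coeffs = []
    for l in range(l_max + 1):
        radial = cs.q * np.where((rho == 0) & (l > 0), 0.0, safe**l)
        row = np.empty(2 * l + 1, complex)
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            row[m + l] = np.sum(radial * np.conj(ylm))
        coeffs.append(row)
    return SphericalMultipoles(origin, tuple(coeffs))


@lru_cache(maxsize=None)
def _harmonic_tensor(l: int, m: int):
    """Symmetric coefficient tensor B with r^l Y_lm(r̂) = B_{j1..jl} x_{j1}···x_{jl}.

    Solid harmonics are homogeneous polynomials, so B is obtained exactly by a
    least-squares fit on a fixed deterministic point set (residual ~1e−15);
    this avoids hand-transcribing l = 3 prefactor tables.
    """
    if l == 0:
        return complex(sph_harm_y(0, 0, 0.0, 0.0))
    rng = np.random.default_rng(987654321 + 17 * l + m)
    pts = rng.normal(size=(40 + 10 * l, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    theta = np.arccos(np.clip(pts[:, 2], -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    target = sph_harm_y(l, m, theta, phi)
    combos = list(itertools.combinations_with_replacement(range(3), l))
    design = np.empty((pts.shape[0], len(combos)))
    mult = []
    for c, combo in enumerate(combos):
        mult.append(len(set(itertools.permutations(combo))))
        design[:, c] = np.prod(pts[:, combo], axis=1)
    # columns already carry the monomial; coefficient applies to all permutations
    coef, *_ = np.linalg.lstsq(design * np.array(mult), target, rcond=None)
    B = np.zeros((3,) * l, complex)
    for combo, c in zip(combos, coef):
        for perm in set(itertools.permutations(combo)):
            B[perm] = c
    return B


def cart_to_spherical(cm: CartesianMultipoles) -> SphericalMultipoles:
    """Exact linear map from traceless Cartesian to spherical moments, l ≤ 3.

    Because the coefficient tensors of solid harmonics are traceless, the raw
    position sums contract against them exactly as (2/3)Θ and (2/5)Ω.
    """
    if cm.order > 3:
        raise ValueError("only orders up to 3 are supported")
    coeffs = []
    scale = {0: 1.0, 1: 1.0, 2: 2.0 / 3.0, 3: 2.0 / 5.0}
    source = {0: cm.M, 1: cm.p, 2: cm.Theta, 3: cm.Omega}
    sub = {1: "j,j->", 2: "jk,jk->", 3: "jkl,jkl->"}
    for l in range(cm.order + 1):
        row = np.empty(2 * l + 1, complex)
        for m in range(-l, l + 1):
            B = _harmonic_tensor(l, m)
            if l == 0:
                row[0] = np.conj(B) * cm.M
            else:
                row[m + l] = scale[l] * np.einsum(sub[l], np.conj(B), source[l])
        coeffs.append(row)
    return SphericalMultipoles(cm.origin, tuple(coeffs))


def check_same_frame(a: SphericalMultipoles, b: SphericalMultipoles, tol: float = 1e-9) -> None:
    if a.convention != b.convention:
        raise ConventionError(f"convention mismatch: {a.convention!r} vs {b.convention!r}")
    if not np.allclose(a.origin, b.origin, atol=tol):
        raise ConventionError(f"origin mismatch: {a.origin} vs {b.origin}")


# ---------------------------------------------------------------------------
# center of dipole and principal axes


def center_of_dipole(cs: ChargeSet, tol: float = NEUTRAL_TOL) -> np.ndarray:
    """Optimal expansion center for a dipole-matched pair on a neutral set.

    The point R₀ minimizing the Frobenius norm of the (traceless) quadrupole
    of the distribution about R₀ — equivalently the quadrupole-order term of
    the error expansion for a dipole-matched two-charge pair centered there.
    Closed form (gradient of ‖Θ(O+d)‖² set to zero):

        d = 2Θp/(3p²) − (p·Θ·p) p/(6p⁴)

    with Θ, p about any origin O (neutral ⇒ the result is origin-independent).
    """
    if not cs.is_neutral(tol):
        raise DegenerateInputError("center of dipole requires a neutral set")
    cog = center_of_geometry(cs)
    cm = cartesian_moments(cs, cog, order=2)
    p, Theta = cm.p, cm.Theta
    p2 = float(p @ p)
    if p2 <= DIPOLE_TOL**2:
        raise DegenerateInputError("center of dipole undefined: |p| ~ 0")
    Tp = Theta @ p
    d = (2.0 / (3.0 * p2)) * Tp - (float(p @ Tp) / (6.0 * p2 * p2)) * p
    return cog + d


@dataclass(frozen=True)
class PrincipalQuadrupole:
    """Quadrupole eigen-decomposition, ordered by descending |λ|."""

    eigenvalues: np.ndarray      # (3,), e·Å²
    eigenvectors: np.ndarray     # (3,3), columns v1, v2, v3
    degenerate: bool = False

    @property
    def lambda1(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def v1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def quadrupole_principal_axes(Theta, tol: float = 1e-12) -> PrincipalQuadrupole:
    """Eigen-decomposition of a symmetric quadrupole tensor.

    Deterministic output: eigenvalues sorted by descending |λ| (ties broken by
    descending signed λ, then lexicographically by eigenvector); each
    eigenvector is flipped so its largest-magnitude component is positive.
    """
    Theta = np.asarray(Theta, float).reshape(3, 3)
    if np.abs(Theta - Theta.T).max() > 1e-9 * max(1.0, np.linalg.norm(Theta)):
        raise ValueError("quadrupole tensor must be symmetric")
    w, V = np.linalg.eigh(Theta)
    cols = []
    for i in range(3):
        v = V[:, i]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        cols.append((w[i], v))
    scale = max(np.abs(w).max(), 1.0)
    cols.sort(key=lambda t: (-round(abs(t[0]) / (scale * tol)), -t[0], tuple(-t[1])))
    lam = np.array([c[0] for c in cols])
    vecs = np.column_stack([c[1] for c in cols])
    return PrincipalQuadrupole(lam, vecs, degenerate=bool(np.abs(lam).max() < tol))
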