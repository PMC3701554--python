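"""Synthetic charge distributions emulating amino-acid partial-charge groups.

The generator draws 5–30 partial charges uniformly inside a 3 Å sphere with
magnitudes up to 1 e, linearly adjusted to an exact integer net charge —
the size, extent and charge statistics of backbone-inclusive amino-acid
groups in force-field parameterizations.  An ensemble helper reproduces
the roughly 20 % charged / 80 % neutral composition of protein residues
at physiological pH.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .multipoles import (
    ChargeSet,
    cartesian_moments,
    center_of_dipole,
    center_of_geometry,
    extent,
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic charge group."""

    n_range: tuple = (5, 30)
    radius: float = 3.0           # Å
    net_charge: int = 0           # e
    partial_charge_cap: float = 1.0  # e
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.n_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_range")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.partial_charge_cap <= 0:
            raise ValueError("partial_charge_cap must be positive")
        if self.net_charge == 0 and lo < 2:
            raise ValueError("neutral specs need at least 2 charges")


def random_chargeset(spec: SynthSpec) -> ChargeSet:
    """Draw one charge group: uniform-in-sphere positions, exact net charge."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.n_range
    n = int(rng.integers(lo, hi + 1))
    if n == 1 and spec.net_charge == 0:
        raise DegenerateInputError("cannot build a neutral single-charge set")
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = spec.radius * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    pos = v * r[:, None]
    q = rng.uniform(-spec.partial_charge_cap, spec.partial_charge_cap, n)
    q += (spec.net_charge - q.sum()) / n
    return ChargeSet(q, pos, label=f"synthetic[seed={spec.seed},net={spec.net_charge}]")


def ensemble(n_sets: int, seed: int = 0, frac_charged: float = 0.2, **kwargs) -> list:
    """A cohort of groups, ``frac_charged`` of them with net ±1 e."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_sets):
        charged = rng.uniform() < frac_charged
        net = int(rng.choice([-1, 1])) if charged else 0
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(random_chargeset(SynthSpec(net_charge=net, seed=sub, **kwargs)))
    return out


def _search(predicate, start_seed: int, net_charge: int = 0, max_tries: int = 5000) -> ChargeSet:
    for k in range(max_tries):
        cs = random_chargeset(SynthSpec(net_charge=net_charge, seed=start_seed + k))
        try:
            if predicate(cs):
                return cs
        except DegenerateInputError:
            continue
    raise RuntimeError("fixture search exhausted its budget")


def _octupole_projection_at_cod(cs: ChargeSet) -> float:
    cod = center_of_dipole(cs)
    cm = cartesian_moments(cs, cod, order=3)
    p = cm.p
    u = p / np.linalg.norm(p)
    return float(np.einsum("jkl,j,k,l->", cm.Omega, u, u, u))


def degenerate_fixtures() -> dict:
    """Named edge-case distributions for the 2-charge solvers.

    * ``pure_dipole`` — a physical ±1 e pair; its own 2-charge optimum.
    * ``zero_dipole_quadrupole`` — alternating charges on a square: M = 0,
      p = 0, quadrupole nonzero; the dipole-pair constructions must refuse it.
    * ``cod_outside`` — neutral group whose center of dipole lies outside
      1.5× the extent, exercising the practical bound shift.
    * ``imaginary_charge`` — neutral group whose octupole projection along
      p̂ at the center of dipole is negative, so the closed-form 2-charge
      magnitude is imaginary and the small-separation fallback engages.

    The last two are located by deterministic rejection sampling over seeds.
    """
    fixtures = {
        "pure_dipole": ChargeSet(
            [1.0, -1.0], [[0.0, 0.0, 0.1], [0.0, 0.0, -0.1]], label="pure-dipole"
        ),
        "zero_dipole_quadrupole": ChargeSet(
            [1.0, -1.0, 1.0, -1.0],
            [[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]],
            label="square-quadrupole",
        ),
    }

    def cod_outside(cs):
        d = np.linalg.norm(center_of_dipole(cs) - center_of_geometry(cs))
        return d > 1.5 * extent(cs)

    fixtures["cod_outside"] = ChargeSet(
        *(lambda c: (c.q, c.r))(_search(cod_outside, start_seed=1000)),
        label="cod-outside",
    )
    fixtures["imaginary_charge"] = ChargeSet(
        *(lambda c: (c.q, c.r))(
            _search(lambda cs: _octupole_projection_at_cod(cs) < -0.05, start_seed=2000)
        ),
        label="imaginary-charge",
    )
    return fixtures
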