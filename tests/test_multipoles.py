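"""Moment computation: oracles, conventions, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opca import (
    ChargeSet,
    DegenerateInputError,
    cart_to_spherical,
    cartesian_moments,
    center_of_charge,
    center_of_dipole,
    center_of_geometry,
    extent,
    quadrupole_principal_axes,
    shift_origin,
    spherical_moments,
)
from conftest import make_charged, make_neutral


def brute_force_moments(cs, origin):
    """Defining sums coded as explicit per-charge loops (oracle path)."""
    origin = np.asarray(origin, float)
    M, p = 0.0, np.zeros(3)
    Theta, Omega = np.zeros((3, 3)), np.zeros((3, 3, 3))
    for q, pos in zip(cs.q, cs.r):
        d = pos - origin
        r2 = d @ d
        M += q
        p += q * d
        for j in range(3):
            for k in range(3):
                Theta[j, k] += 0.5 * q * (3 * d[j] * d[k] - r2 * (j == k))
                for l in range(3):
                    Omega[j, k, l] += 0.5 * q * (
                        5 * d[j] * d[k] * d[l]
                        - r2 * (d[j] * (k == l) + d[k] * (j == l) + d[l] * (j == k))
                    )
    return M, p, Theta, Omega


class TestCartesianMoments:
    def test_point_charge_at_center_has_only_monopole(self):
        cm = cartesian_moments(ChargeSet([1.0], [[0, 0, 0]]), (0, 0, 0))
        assert cm.M == 1.0
        assert np.allclose(cm.p, 0) and np.allclose(cm.Theta, 0) and np.allclose(cm.Omega, 0)

    def test_symmetric_pair_is_pure_dipole(self):
        cs = ChargeSet([1.0, -1.0], [[0, 0, 0.5], [0, 0, -0.5]])
        cm = cartesian_moments(cs, (0, 0, 0))
        assert cm.M == 0.0
        assert np.allclose(cm.p, [0, 0, 1.0])
        assert np.allclose(cm.Theta, 0, atol=1e-14)

    def test_matches_brute_force_sums(self, rng):
        cs = ChargeSet(rng.uniform(-1, 1, 12), rng.uniform(-2, 2, (12, 3)))
        origin = rng.uniform(-1, 1, 3)
        cm = cartesian_moments(cs, origin)
        M, p, Theta, Omega = brute_force_moments(cs, origin)
        assert np.isclose(cm.M, M)
        assert np.allclose(cm.p, p, atol=1e-12)
        assert np.allclose(cm.Theta, Theta, atol=1e-12)
        assert np.allclose(cm.Omega, Omega, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tensors_traceless_and_symmetric(self, seed):
        cs = make_neutral(seed) if seed % 2 else make_charged(seed)
        cm = cartesian_moments(cs, center_of_geometry(cs))
        cm.check(tol=1e-10)

    def test_traceless_symmetric_on_many_random_sets(self):
        for seed in range(1000):
            cs = make_charged(seed, net=seed % 3 - 1, n_range=(2, 8))
            cm = cartesian_moments(cs, (0.1, -0.2, 0.3))
            nth = max(np.linalg.norm(cm.Theta), 1.0)
            assert abs(np.trace(cm.Theta)) < 1e-10 * nth
            assert np.abs(np.einsum("jjk->k", cm.Omega)).max() < 1e-10 * max(
                np.linalg.norm(cm.Omega), 1.0
            )


class TestOriginShifts:
    def test_zero_shift_is_identity(self, rng):
        cs = make_charged(1)
        a = cartesian_moments(cs, (1, 2, 3))
        b = shift_origin(cs, (1, 2, 3))
        assert np.allclose(a.p, b.p) and np.allclose(a.Theta, b.Theta)

    def test_neutral_dipole_origin_independent(self, rng):
        cs = make_neutral(4)
        p0 = cartesian_moments(cs, (0, 0, 0)).p
        for _ in range(10):
            p1 = shift_origin(cs, rng.uniform(-5, 5, 3)).p
            assert np.linalg.norm(p1 - p0) < 1e-10 * max(np.linalg.norm(p0), 1)

    def test_charged_dipole_shifts_by_minus_M_dO(self, rng):
        cs = make_charged(5)
        O1, O2 = rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3)
        p1 = cartesian_moments(cs, O1).p
        p2 = cartesian_moments(cs, O2).p
        assert np.allclose(p2, p1 - cs.net_charge * (O2 - O1), atol=1e-10)

    def test_zero_monopole_zero_dipole_quadrupole_invariant(self, fixtures):
        cs = fixtures["zero_dipole_quadrupole"]
        t0 = cartesian_moments(cs, (0, 0, 0)).Theta
        t1 = cartesian_moments(cs, (3.7, -1.1, 0.4)).Theta
        assert np.allclose(t0, t1, atol=1e-12)


class TestSphericalMoments:
    def test_point_charge_pure_monopole(self):
        sm = spherical_moments(ChargeSet([2.0], [[0, 0, 0]]), (0, 0, 0), 3)
        assert np.isclose(sm.q(0, 0).real, 2.0 / np.sqrt(4 * np.pi))
        for l in range(1, 4):
            assert np.abs(sm.coeffs[l]).max() < 1e-14

    def test_conjugation_symmetry(self, rng):
        cs = ChargeSet(rng.uniform(-1, 1, 7), rng.uniform(-2, 2, (7, 3)))
        sm = spherical_moments(cs, (0, 0, 0), 3)
        for l in range(4):
            for m in range(l + 1):
                assert np.isclose(sm.q(l, -m), (-1) ** m * np.conj(sm.q(l, m)))

    def test_rotation_invariant_l_norms(self, rng):
        cs = ChargeSet(rng.uniform(-1, 1, 9), rng.uniform(-2, 2, (9, 3)))
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        a = spherical_moments(cs, (0, 0, 0), 3)
        b = spherical_moments(cs.rotated(Q), (0, 0, 0), 3)
        for l in range(4):
            assert np.isclose(
                np.sum(np.abs(a.coeffs[l]) ** 2), np.sum(np.abs(b.coeffs[l]) ** 2), rtol=1e-10
            )

    @pytest.mark.parametrize("seed", range(8))
    def test_cartesian_cross_path_agreement(self, seed):
        cs = make_charged(seed, net=seed % 2)
        origin = center_of_geometry(cs)
        direct = spherical_moments(cs, origin, 3)
        via_cart = cart_to_spherical(cartesian_moments(cs, origin))
        overall = max(np.abs(np.concatenate(direct.coeffs)).max(), 1.0)
        for l in range(4):
            scale = max(np.abs(direct.coeffs[l]).max(), 1e-12)
            diff = np.abs(direct.coeffs[l] - via_cart.coeffs[l]).max()
            assert diff < 1e-9 * scale + 1e-14 * overall

    def test_zdipole_maps_to_l1_m0_channel(self):
        cm = cartesian_moments(ChargeSet([1, -1], [[0, 0, 0.5], [0, 0, -0.5]]), (0, 0, 0))
        sm = cart_to_spherical(cm)
        assert abs(sm.q(0, 0)) < 1e-14
        assert abs(sm.q(1, 0)) > 0.1
        assert abs(sm.q(1, 1)) < 1e-14


class TestCenters:
    def test_center_of_charge_examples(self):
        cs = ChargeSet([1, 1], [[1, 0, 0], [-1, 0, 0]])
        assert np.allclose(center_of_charge(cs), 0)
        cs = ChargeSet([2, 1], [[1, 0, 0], [-2, 0, 0]])
        assert np.allclose(center_of_charge(cs), 0)

    def test_center_of_charge_neutral_raises(self):
        with pytest.raises(DegenerateInputError):
            center_of_charge(ChargeSet([1, -1], [[1, 0, 0], [-1, 0, 0]]))

    def test_extent_nonnegative_and_outermost(self):
        cs = ChargeSet([1, 1, 1], [[0, 0, 0], [1, 0, 0], [0, 2, 0]])
        assert extent(cs, center=(0, 0, 0)) == 2.0

    def test_center_of_dipole_symmetry_and_translation(self):
        pair = ChargeSet([1, -1], [[0, 0, 0.5], [0, 0, -0.5]])
        assert np.allclose(center_of_dipole(pair), 0, atol=1e-12)
        shifted = pair.translated((1, 2, 3))
        assert np.allclose(center_of_dipole(shifted), (1, 2, 3), atol=1e-10)

    @pytest.mark.parametrize("seed", [2, 7, 13])
    def test_center_of_dipole_minimizes_quadrupole_norm(self, seed):
        from scipy.optimize import minimize

        cs = make_neutral(seed)
        cod = center_of_dipole(cs)

        def f(x):
            return np.linalg.norm(cartesian_moments(cs, x, 2).Theta) ** 2

        res = minimize(f, center_of_geometry(cs), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        assert np.linalg.norm(cod - res.x) < 1e-6

    def test_center_of_dipole_zero_dipole_raises(self, fixtures):
        with pytest.raises(DegenerateInputError):
            center_of_dipole(fixtures["zero_dipole_quadrupole"])


class TestPrincipalQuadrupole:
    def test_diagonal_tensor(self):
        pq = quadrupole_principal_axes(np.diag([2.0, -1.0, -1.0]))
        assert np.isclose(pq.lambda1, 2.0)
        assert np.allclose(np.abs(pq.v1), [1, 0, 0])

    def test_zero_tensor_flagged_degenerate(self):
        pq = quadrupole_principal_axes(np.zeros((3, 3)))
        assert pq.degenerate and np.allclose(pq.eigenvalues, 0)

    def test_reconstruction_and_ordering(self, rng):
        cs = make_charged(21)
        Theta = cartesian_moments(cs, center_of_charge(cs), 2).Theta
        pq = quadrupole_principal_axes(Theta)
        V, lam = pq.eigenvectors, pq.eigenvalues
        assert np.allclose(V @ np.diag(lam) @ V.T, Theta, atol=1e-10)
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-10)
        assert abs(lam[0]) >= abs(lam[1]) >= abs(lam[2])
        assert abs(lam.sum()) < 1e-10 * max(abs(lam).max(), 1)
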