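"""Closed-form 1- and 2-charge solvers: construction identities and fallbacks."""

import numpy as np
import pytest

from opca import (
    ChargeSet,
    DegenerateInputError,
    Ppca2Config,
    cartesian_moments,
    center_of_charge,
    center_of_dipole,
    center_of_geometry,
    coulomb_potential,
    extent,
    opca1,
    opca2_neutral,
    ppca2,
    ppca2_charged,
    ppca2_neutral,
    quadrupole_principal_axes,
    rms_error,
    sphere_grid,
)
from conftest import make_charged, make_neutral


class TestOpca1:
    def test_single_charge_is_its_own_approximation(self):
        cs = ChargeSet([1.5], [[0.3, -0.2, 1.0]])
        res = opca1(cs)
        assert np.allclose(res.approx.q, cs.q) and np.allclose(res.approx.r, cs.r)

    def test_weighted_mean_placement(self):
        cs = ChargeSet([2.0, 1.0], [[1, 0, 0], [-2, 0, 0]])
        res = opca1(cs)
        assert np.isclose(res.approx.q[0], 3.0)
        assert np.allclose(res.approx.r[0], 0, atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_dipole_matches_about_any_origin(self, seed, rng):
        cs = make_charged(seed)
        res = opca1(cs)
        for _ in range(3):
            o = rng.uniform(-3, 3, 3)
            p_orig = cartesian_moments(cs, o, 1).p
            p_appr = cartesian_moments(res.approx, o, 1).p
            assert np.allclose(p_orig, p_appr, atol=1e-10)
        assert res.matched_order >= 1

    def test_neutral_input_rejected(self, fixtures):
        with pytest.raises(DegenerateInputError, match="2-charge"):
            opca1(fixtures["pure_dipole"])


class TestOpca2Neutral:
    def test_physical_pair_reproduces_itself(self, fixtures):
        pair = fixtures["pure_dipole"]
        res = opca2_neutral(pair)
        assert res.fallback == "none"
        order = np.argsort(res.approx.q)
        orig = np.argsort(pair.q)
        assert np.allclose(np.sort(res.approx.q), np.sort(pair.q), atol=1e-10)
        assert np.allclose(res.approx.r[order], pair.r[orig], atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 2, 4, 6])
    def test_construction_identities(self, seed):
        cs = make_neutral(seed)
        res = opca2_neutral(cs)
        cm_o = cartesian_moments(cs, (0, 0, 0), 1)
        cm_a = cartesian_moments(res.approx, (0, 0, 0), 1)
        assert abs(cm_a.M) < 1e-12
        assert np.allclose(cm_a.p, cm_o.p, atol=1e-10)
        cod = center_of_dipole(cs)
        pair_quad = cartesian_moments(res.approx, cod, 2).Theta
        assert np.abs(pair_quad).max() < 1e-10

    def test_imaginary_charge_falls_back_to_small_separation(self, fixtures):
        cs = fixtures["imaginary_charge"]
        cfg = Ppca2Config(d_sep=0.1)
        res = opca2_neutral(cs, cfg)
        assert res.fallback == "small_separation"
        assert np.isclose(np.linalg.norm(res.approx.r[0] - res.approx.r[1]), cfg.d_sep)

    def test_zero_dipole_rejected(self, fixtures):
        with pytest.raises(DegenerateInputError, match="solve_opca"):
            opca2_neutral(fixtures["zero_dipole_quadrupole"])


class TestPpca2Neutral:
    @pytest.mark.parametrize("seed", [1, 3, 5])
    def test_monopole_and_dipole_preserved(self, seed):
        cs = make_neutral(seed)
        res = ppca2_neutral(cs)
        cm_o = cartesian_moments(cs, (0, 0, 0), 1)
        cm_a = cartesian_moments(res.approx, (0, 0, 0), 1)
        assert abs(cm_a.M - cm_o.M) < 1e-12
        assert np.abs(cm_a.p - cm_o.p).max() < 1e-12

    def test_pair_centered_at_center_of_dipole_when_inside(self):
        # search a set whose center of dipole is inside the bound
        for seed in range(50):
            cs = make_neutral(seed)
            cod = center_of_dipole(cs)
            if np.linalg.norm(cod - center_of_geometry(cs)) < extent(cs):
                break
        res = ppca2_neutral(cs)
        assert res.fallback == "none"
        assert np.allclose(res.approx.r.mean(axis=0), cod, atol=1e-10)

    def test_bound_shift_engages_when_cod_outside(self, fixtures):
        cs = fixtures["cod_outside"]
        cfg = Ppca2Config()
        res = ppca2_neutral(cs, cfg)
        assert res.fallback == "bound_shift"
        cog = center_of_geometry(cs)
        bound = cfg.bound_factor * extent(cs)
        for pos in res.approx.r:
            assert np.linalg.norm(pos - cog) <= bound * (1 + 1e-9)
        # moments still preserved after the shift
        assert abs(res.approx.q.sum()) < 1e-12
        p_o = cartesian_moments(cs, (0, 0, 0), 1).p
        p_a = cartesian_moments(res.approx, (0, 0, 0), 1).p
        assert np.allclose(p_a, p_o, atol=1e-10)


class TestPpca2Charged:
    def test_kappa_ratio_pair_reproduces_itself(self):
        # charges 2 and 3 at distances 1.5 : 1 on a line through their
        # center of charge realize the kappa = 1.5 construction exactly
        cs = ChargeSet([2.0, 3.0], [[1.5, 0, 0], [-1.0, 0, 0]])
        res = ppca2_charged(cs)
        assert np.allclose(np.sort(res.approx.q), [2.0, 3.0], atol=1e-10)
        got = res.approx.r[np.argsort(res.approx.q)]
        want = cs.r[np.argsort(cs.q)]
        assert np.allclose(np.abs(got), np.abs(want), atol=1e-8)

    @pytest.mark.parametrize("seed,net", [(0, 1), (3, -1), (8, 1)])
    def test_construction_identities(self, seed, net):
        cs = make_charged(seed, net=net)
        res = ppca2_charged(cs)
        assert np.isclose(res.approx.q.sum(), cs.net_charge, atol=1e-12)
        coc = center_of_charge(cs)
        assert np.allclose(center_of_charge(res.approx), coc, atol=1e-10)
        lam1 = quadrupole_principal_axes(cartesian_moments(cs, coc, 2).Theta).lambda1
        pq_a = quadrupole_principal_axes(cartesian_moments(res.approx, coc, 2).Theta)
        assert np.isclose(pq_a.lambda1, lam1, rtol=1e-9)

    def test_neutral_rejected(self, fixtures):
        with pytest.raises(DegenerateInputError):
            ppca2_charged(fixtures["pure_dipole"])

    def test_degenerate_quadrupole_splits_monopole(self):
        cs = ChargeSet([2.0], [[0.5, 0.5, 0.5]])
        res = ppca2_charged(cs)
        assert res.fallback == "degenerate"
        assert np.allclose(res.approx.q, [1.0, 1.0])
        assert np.allclose(res.approx.r, [[0.5, 0.5, 0.5]] * 2)


class TestDispatch:
    def test_neutral_branch(self):
        res = ppca2(make_neutral(2))
        assert "branch=neutral" in res.diagnostics

    def test_charged_branch(self):
        res = ppca2(make_charged(2))
        assert "branch=charged" in res.diagnostics

    def test_half_tolerance_counts_as_neutral(self):
        cfg = Ppca2Config()
        base = make_neutral(6)
        q = base.q.copy()
        q[0] += cfg.neutral_tol / 2
        res = ppca2(ChargeSet(q, base.r), cfg)
        assert "branch=neutral" in res.diagnostics

    def test_config_validation(self):
        with pytest.raises(ValueError):
            Ppca2Config(d_sep=-1)
        with pytest.raises(ValueError):
            Ppca2Config(kappa=1.0)
        with pytest.raises(ValueError):
            Ppca2Config(bound_factor=0.5)


class TestSeparationTrends:
    """Mid-field RMS as a function of the pair separation."""

    def _rms_at(self, cs, d_sep, R_factor=2.0):
        a = extent(cs)
        pts, _ = sphere_grid(center_of_geometry(cs), R_factor * a, 400)
        ref = coulomb_potential(cs, pts)
        res = ppca2_neutral(cs, Ppca2Config(d_sep=d_sep))
        return rms_error(ref, coulomb_potential(res.approx, pts))

    def test_imaginary_charge_case_error_decreases_to_small_separation(self, fixtures):
        cs = fixtures["imaginary_charge"]
        errs = [self._rms_at(cs, d) for d in (1.6, 0.8, 0.4, 0.2, 0.1, 0.05)]
        assert all(e2 <= e1 * (1 + 1e-6) for e1, e2 in zip(errs, errs[1:]))

    def test_real_solution_case_has_interior_optimum(self):
        for seed in range(50):
            cs = make_neutral(seed)
            res = opca2_neutral(cs)
            if res.fallback == "none":
                break
        s_opt = np.linalg.norm(res.approx.r[0] - res.approx.r[1])
        grid = np.geomspace(s_opt / 8, min(2 * s_opt, 3 * extent(cs)), 10)
        errs = [self._rms_at(cs, d) for d in grid]
        k = int(np.argmin(errs))
        assert 0 < k < len(grid) - 1
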