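"""Pseudo-energy terms, analytic gradients, and the Saupe tensor fit."""

import dataclasses

import numpy as np
import pytest

from fcdg import energy as en
from fcdg.energy import (AlignmentTensor, ChiralRestraint, CompiledSystem,
                         InsufficientRDCError, NOERestraint, RDCRestraint,
                         RestraintSet, chi2, chiral_volume, e_chir, e_dist,
                         e_noe, e_rdc, e_total, fit_tensor_svd, q_factor)
from fcdg.moltop import BoundsMatrix, StereoElement


def _fd_gradient(fun, coords, h=1e-6):
    g = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(coords.shape[1]):
            for s, sign in ((h, 1.0), (-h, -1.0)):
                c = coords.copy()
                c[i, k] += s
                g[i, k] += sign * fun(c)
    return g / (2 * h)


def _perturbed(rigid_fixture, scale=0.05, seed=2):
    g = rigid_fixture.graph
    rng = np.random.default_rng(seed)
    return g.reference_coords + scale * rng.normal(size=(g.n_atoms, 3))


class TestEDist:
    def test_zero_inside_bounds(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        b = BoundsMatrix(np.array([[0, 1.0], [1.0, 0]]),
                         np.array([[0, 2.0], [2.0, 0]]))
        e, g = e_dist(coords, b, 2.0)
        assert e == 0.0
        np.testing.assert_allclose(g, 0.0)

    def test_unit_violation_energy(self):
        """One pair 1 Å above its upper bound at K=2 gives E = ½·2·1² = 1."""
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        b = BoundsMatrix(np.array([[0, 1.0], [1.0, 0]]),
                         np.array([[0, 2.0], [2.0, 0]]))
        e, _ = e_dist(coords, b, 2.0)
        assert e == pytest.approx(1.0)

    def test_gradient_matches_central_differences(self, rigid_fixture, rigid_smoothed):
        coords = _perturbed(rigid_fixture, scale=0.2)
        _, g = e_dist(coords, rigid_smoothed, 2.0)
        gn = _fd_gradient(lambda c: e_dist(c, rigid_smoothed, 2.0)[0], coords)
        assert np.linalg.norm(g - gn) / np.linalg.norm(gn) < 1e-5


class TestChiralVolume:
    ELEMENT = StereoElement("stereocenter", 0, (0, 1, 2, 3))

    def test_unit_tetrahedron(self):
        coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
        v, _ = chiral_volume(coords, self.ELEMENT)
        assert v == pytest.approx(1.0)

    def test_sign_flips_under_inversion(self):
        coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
        v, _ = chiral_volume(-coords, self.ELEMENT)
        assert v == pytest.approx(-1.0)

    def test_coplanar_is_zero(self):
        coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0], [0, 0, 0]])
        v, _ = chiral_volume(coords, self.ELEMENT)
        assert v == pytest.approx(0.0)


class TestEChir:
    def test_distorted_planar_group(self):
        """V = 0.5 Å³ against a planarity target at K = 2 gives E = 0.25."""
        el = StereoElement("sp2-planar", 3, (0, 1, 2, 3))
        coords = np.array([[1.0, 0, 0], [0, 1.0, 0], [0.0, 0, 1.0], [0, 0, 0]])
        v, _ = chiral_volume(coords, el)
        coords[2, 2] *= 0.5 / v  # scale so V = 0.5
        e, _ = e_chir(coords, [ChiralRestraint(el, 0.0, 2.0)])
        assert e == pytest.approx(0.25)

    def test_gradient_matches_central_differences(self, rigid_fixture):
        coords = _perturbed(rigid_fixture)
        restraints = [
            ChiralRestraint(e, 1.5, 2.0)
            for e in rigid_fixture.elements if e.kind == "stereocenter"
        ]
        _, g = e_chir(coords, restraints)
        gn = _fd_gradient(lambda c: e_chir(c, restraints)[0], coords)
        assert np.linalg.norm(g - gn) / np.linalg.norm(gn) < 1e-5


class TestENoe:
    def test_satisfied_restraint_is_zero(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        e, _ = e_noe(coords, [NOERestraint((0,), (1,), 3.0, 100.0)])
        assert e == pytest.approx(0.0)

    def test_log_unit_violation(self):
        """d_calc = e·d_exp at K = 2 gives E = ½·2·ln²(1/e) = 1."""
        coords = np.array([[0.0, 0, 0], [3.0 * np.e, 0, 0]])
        e, _ = e_noe(coords, [NOERestraint((0,), (1,), 3.0, 2.0)])
        assert e == pytest.approx(1.0)

    def test_stiffness_ratio_vs_harmonic(self):
        """At d0 = 3 Å the log-normal curvature is 1/d0² = 1/9 of a harmonic's."""
        d0, k, h = 3.0, 2.0, 1e-4

        def e_ln(d):
            return 0.5 * k * np.log(d0 / d) ** 2

        def e_h(d):
            return 0.5 * k * (d0 - d) ** 2

        curv_ln = (e_ln(d0 + h) - 2 * e_ln(d0) + e_ln(d0 - h)) / h ** 2
        curv_h = (e_h(d0 + h) - 2 * e_h(d0) + e_h(d0 - h)) / h ** 2
        assert curv_ln / curv_h == pytest.approx(1.0 / 9.0, rel=1e-4)
        # and the implementation reproduces the log-normal curvature
        coords = np.array([[0.0, 0, 0], [d0, 0, 0]])
        rs = [NOERestraint((0,), (1,), d0, k)]

        def e_impl(d):
            c = coords.copy()
            c[1, 0] = d
            return e_noe(c, rs)[0]

        curv_impl = (e_impl(d0 + h) - 2 * e_impl(d0) + e_impl(d0 - h)) / h ** 2
        assert curv_impl == pytest.approx(k / d0 ** 2, rel=1e-3)

    def test_group_averaging_uses_r6_mean(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        deff, _, _ = en._group_distance(coords, (0,), (1, 2))
        expect = ((2.0 ** -6 + 4.0 ** -6) / 2) ** (-1 / 6)
        assert deff == pytest.approx(expect)

    def test_coincident_atoms_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="d_calc"):
            e_noe(coords, [NOERestraint((0,), (1,), 3.0, 1.0)])

    def test_gradient_matches_central_differences(self, rigid_fixture, data_restraints):
        rs, _ = data_restraints
        coords = _perturbed(rigid_fixture)
        _, g = e_noe(coords, rs.noe)
        gn = _fd_gradient(lambda c: e_noe(c, rs.noe)[0], coords)
        assert np.linalg.norm(g - gn) / np.linalg.norm(gn) < 1e-5


class TestTensorFit:
    def test_exact_recovery(self, rigid_fixture, data_restraints):
        rs, tensors = data_restraints
        g = rigid_fixture.graph
        rows = rs.rdc_by_medium("medium_1")
        t, dcalc = fit_tensor_svd(g.reference_coords, g.symbols, rows, "medium_1")
        np.testing.assert_allclose(t.matrix, tensors[0].matrix, atol=1e-8)
        resid = np.array([r.d_exp for r in rows]) - dcalc
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_too_few_couplings(self, rigid_fixture, data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        with pytest.raises(InsufficientRDCError, match="medium_1"):
            fit_tensor_svd(g.reference_coords, g.symbols,
                           rs.rdc_by_medium("medium_1")[:4], "medium_1")

    def test_noisy_fit_equals_normal_equations_oracle(self, rigid_fixture,
                                                      data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        rng = np.random.default_rng(9)
        rows = [dataclasses.replace(r, d_exp=r.d_exp + rng.normal(0, 1.0))
                for r in rs.rdc_by_medium("medium_1")]
        t, dcalc = fit_tensor_svd(g.reference_coords, g.symbols, rows, "medium_1")
        A = np.array([en._restraint_row(g.reference_coords, g.symbols, r)
                      for r in rows])
        b = np.array([r.d_exp for r in rows])
        s_oracle = np.linalg.solve(A.T @ A, A.T @ b)
        np.testing.assert_allclose(t.s, s_oracle, atol=1e-10)
        resid_impl = float(np.sum((b - dcalc) ** 2))
        resid_oracle = float(np.sum((b - A @ s_oracle) ** 2))
        assert resid_impl == pytest.approx(resid_oracle, abs=1e-10)

    def test_traceless_symmetric_invariant(self, data_restraints):
        _, tensors = data_restraints
        for t in tensors:
            m = t.matrix
            np.testing.assert_allclose(m, m.T, atol=1e-14)
            assert abs(np.trace(m)) < 1e-12


class TestERdc:
    def test_exact_couplings_zero_energy(self, rigid_fixture, data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        energies, grad, _, _ = e_rdc(g.reference_coords, g.symbols, rs.rdc)
        assert sum(energies.values()) == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(grad, 0.0, atol=1e-8)

    def test_zero_force_constant_kills_term(self, rigid_fixture, data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        rows = [dataclasses.replace(r, k=0.0, d_exp=r.d_exp + 100.0)
                for r in rs.rdc]
        energies, grad, _, _ = e_rdc(_perturbed(rigid_fixture), g.symbols, rows)
        assert sum(energies.values()) == 0.0
        np.testing.assert_allclose(grad, 0.0)

    def test_gradient_matches_central_differences_with_refit(
            self, rigid_fixture, data_restraints):
        """The finite-difference oracle refits the tensors at every evaluation."""
        rs, _ = data_restraints
        g = rigid_fixture.graph
        coords = _perturbed(rigid_fixture)
        _, grad, _, _ = e_rdc(coords, g.symbols, rs.rdc)

        def etot(c):
            e, _, _, _ = e_rdc(c, g.symbols, rs.rdc)
            return sum(e.values())

        gn = _fd_gradient(etot, coords)
        assert np.linalg.norm(grad - gn) / np.linalg.norm(gn) < 1e-5

    def test_fit_stationarity_in_tensor_space(self, rigid_fixture, data_restraints):
        """After the SVD refit, dE_RDC/dS vanishes along all 5 tensor directions."""
        rs, _ = data_restraints
        g = rigid_fixture.graph
        coords = _perturbed(rigid_fixture)
        rows = rs.rdc_by_medium("medium_2")
        tensor, _ = fit_tensor_svd(coords, g.symbols, rows, "medium_2")
        A = np.array([en._restraint_row(coords, g.symbols, r) for r in rows])
        b = np.array([r.d_exp for r in rows])
        k = rows[0].k

        def e_of_s(s):
            return 0.5 * k * float(np.sum((b - A @ s) ** 2))

        h = 1e-6
        scale = max(1.0, abs(e_of_s(tensor.s)))
        for direction in np.eye(5):
            de = (e_of_s(tensor.s + h * direction)
                  - e_of_s(tensor.s - h * direction)) / (2 * h)
            assert abs(de) / scale < 1e-8


class TestFitStatistics:
    def test_chi2_cases(self):
        assert chi2([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert chi2([3.0, 4.0], [0.0, 0.0]) == pytest.approx(25.0)
        rng = np.random.default_rng(0)
        a, b, w = rng.normal(size=20), rng.normal(size=20), rng.uniform(0.1, 2, 20)
        loop = sum(wi * (ai - bi) ** 2 for ai, bi, wi in zip(a, b, w))
        assert chi2(a, b, w) == pytest.approx(loop, rel=1e-14)
        with pytest.raises(ValueError):
            chi2([1.0], [1.0, 2.0])

    def test_q_factor_cases(self):
        d = np.array([2.0, -3.0, 5.0])
        assert q_factor(d, d) == 0.0
        assert q_factor(d, np.zeros(3)) == pytest.approx(1.0)
        q = q_factor(d, 0.5 * d)
        assert q_factor(d, 0.5 * d, root=True) == pytest.approx(np.sqrt(q))
        with pytest.raises(ValueError):
            q_factor([0.0, 0.0], [1.0, 1.0])


class TestETotal:
    def test_zero_at_full_satisfaction(self, rigid_fixture, rigid_smoothed,
                                       data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        rep = e_total(g.reference_coords, rigid_smoothed, rs, g.symbols)
        assert rep.etotal == pytest.approx(0.0, abs=1e-10)

    def test_total_is_sum_of_parts(self, rigid_fixture, rigid_smoothed,
                                   data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        rep = e_total(_perturbed(rigid_fixture), rigid_smoothed, rs, g.symbols)
        assert rep.etotal == pytest.approx(
            rep.edist + rep.echir + rep.enoe + rep.erdc, abs=1e-12)
        assert min(rep.edist, rep.echir, rep.enoe, rep.erdc) >= 0.0

    def test_gradient_additivity(self, rigid_fixture, rigid_smoothed,
                                 data_restraints):
        rs, _ = data_restraints
        g = rigid_fixture.graph
        coords = _perturbed(rigid_fixture)
        rep = e_total(coords, rigid_smoothed, rs, g.symbols)
        gd = e_dist(coords, rigid_smoothed, rs.k_dist)[1]
        gc = e_chir(coords, rs.chiral)[1]
        gn = e_noe(coords, rs.noe)[1]
        gr = e_rdc(coords, g.symbols, rs.rdc)[1]
        np.testing.assert_allclose(rep.gradient, gd + gc + gn + gr, atol=1e-12)

    def test_rotation_translation_invariance(self, rigid_fixture, rigid_smoothed,
                                             data_restraints):
        from scipy.spatial.transform import Rotation

        rs, _ = data_restraints
        g = rigid_fixture.graph
        coords = _perturbed(rigid_fixture)
        e0 = e_total(coords, rigid_smoothed, rs, g.symbols).etotal
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -2.0, 1.0])
        e1 = e_total(moved, rigid_smoothed, rs, g.symbols).etotal
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_inversion_flips_only_chiral_volumes(self, rigid_fixture,
                                                 rigid_smoothed):
        from fcdg.synthetic import holonomic_restraints

        rs = holonomic_restraints(rigid_fixture)
        g = rigid_fixture.graph
        coords = _perturbed(rigid_fixture)
        rep0 = e_total(coords, rigid_smoothed, rs, g.symbols)
        rep1 = e_total(-coords, rigid_smoothed, rs, g.symbols)
        assert rep1.edist == pytest.approx(rep0.edist, rel=1e-12)
        for el in (e for e in rigid_fixture.elements if e.kind != "sp2-planar"):
            v0, _ = chiral_volume(coords, el)
            v1, _ = chiral_volume(-coords, el)
            assert v1 == pytest.approx(-v0, rel=1e-12)


class TestCompiledSystem:
    def test_kernel_matches_reference_path(self, rigid_fixture, rigid_smoothed,
                                           data_restraints):
        """The JIT kernel and the modular numpy terms compute the same model."""
        rs, _ = data_restraints
        g = rigid_fixture.graph
        sys_ = CompiledSystem(rigid_smoothed, rs, g.symbols)
        rng = np.random.default_rng(12)
        for scale in (0.02, 0.1, 0.4):
            coords = g.reference_coords + scale * rng.normal(size=(g.n_atoms, 3))
            ref = e_total(coords, rigid_smoothed, rs, g.symbols)
            e_k, g_k = sys_.energy_grad(coords)
            assert e_k == pytest.approx(ref.etotal, rel=1e-9, abs=1e-9)
            np.testing.assert_allclose(g_k, ref.gradient, atol=1e-6)
            rep_k = sys_.report(coords)
            assert rep_k.edist == pytest.approx(ref.edist, rel=1e-9, abs=1e-12)
            assert rep_k.enoe == pytest.approx(ref.enoe, rel=1e-9, abs=1e-12)
            # 4D phase agrees too
            c4 = np.hstack([coords, 0.3 * rng.normal(size=(g.n_atoms, 1))])
            ref4 = e_total(c4, rigid_smoothed, rs, g.symbols)
            e4, g4 = sys_.energy_grad(c4)
            assert e4 == pytest.approx(ref4.etotal, rel=1e-9, abs=1e-9)
            np.testing.assert_allclose(g4, ref4.gradient, atol=1e-6)
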