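"""Annealing protocol, dimensionality reduction, minimization, ensembles."""

import numpy as np
import pytest

from fcdg import dynamics
from fcdg.dynamics import (AnnealSchedule, anneal, energy_steps, minimize,
                           reduce_to_3d, run_ensemble)
from fcdg.energy import RestraintSet, e_total
from fcdg.moltop import BoundsMatrix


def _pair_system(target=1.5):
    b = BoundsMatrix(np.array([[0.0, target], [target, 0.0]]),
                     np.array([[0.0, target], [target, 0.0]]))
    return b, RestraintSet(k_dist=2.0)


class TestSchedule:
    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            AnnealSchedule(time_step=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(hot_steps=0)

    def test_defaults_follow_protocol(self):
        s = AnnealSchedule()
        assert (s.time_step, s.hot_steps, s.cool_steps) == (5.0, 5000, 5000)


class TestAnneal:
    def test_deterministic_given_seed(self, rigid_smoothed, holonomic_restraints,
                                      rigid_fixture):
        sched = AnnealSchedule(5.0, 30, 30, 1.0)
        x0 = np.hstack([rigid_fixture.graph.reference_coords,
                        np.zeros((rigid_fixture.graph.n_atoms, 1))])
        a = anneal(x0, rigid_smoothed, holonomic_restraints, sched,
                   np.random.default_rng(5), rigid_fixture.graph.symbols)
        b = anneal(x0, rigid_smoothed, holonomic_restraints, sched,
                   np.random.default_rng(5), rigid_fixture.graph.symbols)
        np.testing.assert_array_equal(a, b)

    def test_stationary_at_minimum_with_zero_temperature(self):
        bounds, rs = _pair_system()
        sched = AnnealSchedule(5.0, 10, 10, t_hot=0.0)
        x0 = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        out = anneal(x0, bounds, rs, sched, np.random.default_rng(0))
        np.testing.assert_allclose(out, x0, atol=1e-12)


class TestReduceTo3D:
    def test_zero_fourth_axis_is_identity(self, rigid_smoothed,
                                          holonomic_restraints, rigid_fixture):
        g = rigid_fixture.graph
        x4 = np.hstack([g.reference_coords, np.zeros((g.n_atoms, 1))])
        out = reduce_to_3d(x4, rigid_smoothed, holonomic_restraints, g.symbols)
        np.testing.assert_allclose(out, g.reference_coords, atol=1e-12)

    def test_compression_contract(self, rigid_smoothed, holonomic_restraints,
                                  rigid_fixture):
        g = rigid_fixture.graph
        rng = np.random.default_rng(1)
        x4 = np.hstack([g.reference_coords, 0.8 * rng.normal(size=(g.n_atoms, 1))])
        d_before = np.linalg.norm(
            x4[:, None, :3] - x4[None, :, :3], axis=-1)
        out = reduce_to_3d(x4, rigid_smoothed, holonomic_restraints, g.symbols,
                           compression_steps=400)
        assert out.shape == (g.n_atoms, 3)
        # contract: the dropped component was compressed below tolerance, so
        # truncation perturbs every pair distance by less than the 4D extent
        d_after = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.all(np.isfinite(d_after))


class TestMinimize:
    def test_satisfied_structure_unchanged(self, rigid_fixture, rigid_smoothed,
                                           holonomic_restraints):
        g = rigid_fixture.graph
        rec = minimize(g.reference_coords, rigid_smoothed, holonomic_restraints,
                       g.symbols)
        np.testing.assert_allclose(rec.coords, g.reference_coords, atol=1e-9)
        assert rec.energy.etotal == pytest.approx(0.0, abs=1e-12)
        assert rec.converged

    def test_quadratic_pair_converges_to_target(self):
        bounds, rs = _pair_system(target=1.5)
        start = np.array([[0.0, 0, 0], [2.4, 0, 0]])
        rec = minimize(start, bounds, rs, tol=1e-9)
        d = np.linalg.norm(rec.coords[0] - rec.coords[1])
        assert d == pytest.approx(1.5, abs=1e-6)

    def test_energy_never_increases(self, rigid_fixture, rigid_smoothed,
                                    holonomic_restraints):
        g = rigid_fixture.graph
        rng = np.random.default_rng(3)
        start = g.reference_coords + 0.3 * rng.normal(size=(g.n_atoms, 3))
        e_start = e_total(start, rigid_smoothed, holonomic_restraints,
                          g.symbols).etotal
        rec = minimize(start, rigid_smoothed, holonomic_restraints, g.symbols)
        assert rec.energy.etotal <= e_start + 1e-12

    def test_record_energy_is_reproducible(self, rigid_fixture, rigid_smoothed,
                                           holonomic_restraints):
        g = rigid_fixture.graph
        rng = np.random.default_rng(4)
        start = g.reference_coords + 0.1 * rng.normal(size=(g.n_atoms, 3))
        rec = minimize(start, rigid_smoothed, holonomic_restraints, g.symbols)
        again = e_total(rec.coords, rigid_smoothed, holonomic_restraints,
                        g.symbols).etotal
        assert again == pytest.approx(rec.energy.etotal, abs=1e-9)


class TestRunEnsemble:
    def test_single_structure(self, rigid_fixture, rigid_bounds,
                              holonomic_restraints):
        recs = run_ensemble(rigid_fixture.graph, rigid_bounds,
                            holonomic_restraints, 1,
                            AnnealSchedule(5.0, 40, 40, 1.0), seed=1,
                            elements=rigid_fixture.elements,
                            compression_steps=100, quench_cycles=0)
        assert len(recs) == 1
        assert recs[0].configuration is not None

    def test_master_seed_reproducibility(self, rigid_fixture, rigid_bounds,
                                         holonomic_restraints):
        kwargs = dict(n_structures=3, schedule=AnnealSchedule(5.0, 40, 40, 1.0),
                      seed=99, elements=rigid_fixture.elements,
                      compression_steps=100, quench_cycles=0)
        a = run_ensemble(rigid_fixture.graph, rigid_bounds,
                         holonomic_restraints, **kwargs)
        b = run_ensemble(rigid_fixture.graph, rigid_bounds,
                         holonomic_restraints, **kwargs)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.coords, rb.coords)
            assert ra.configuration == rb.configuration

    def test_rejects_empty_request(self, rigid_fixture, rigid_bounds,
                                   holonomic_restraints):
        with pytest.raises(ValueError):
            run_ensemble(rigid_fixture.graph, rigid_bounds,
                         holonomic_restraints, 0,
                         AnnealSchedule(5.0, 10, 10, 1.0), seed=1)

    def test_relaxation_succeeds_in_most_replicates(self, prior_ensemble):
        """Restraint-free structures minimize to (near) zero pseudo-energy."""
        e = np.array([r.energy.etotal for r in prior_ensemble])
        assert np.mean(e < 1e-3) >= 0.95

    def test_floating_chirality_flips_every_element(self, prior_ensemble,
                                                    rigid_fixture):
        """Both signs of every free element occur across the prior ensemble."""
        keys = [r.configuration for r in prior_ensemble]
        n_free = len([e for e in rigid_fixture.elements
                      if not e.fixed and e.kind != "sp2-planar"])
        for pos in range(n_free):
            signs = {k[pos] for k in keys}
            assert signs == {"+", "-"}

    def test_fixed_reference_sign_never_flips(self, prior_ensemble,
                                              rigid_fixture):
        """The pinned enantiomer-reference elements keep their reference sign
        in every minimized structure."""
        from fcdg.energy import chiral_volume

        g = rigid_fixture.graph
        fixed = [e for e in rigid_fixture.elements
                 if e.fixed and e.kind != "sp2-planar"]
        ref_signs = [np.sign(chiral_volume(g.reference_coords, e)[0])
                     for e in fixed]
        for rec in prior_ensemble:
            for e, s_ref in zip(fixed, ref_signs):
                v, _ = chiral_volume(rec.coords, e)
                assert np.sign(v) == s_ref

    def test_energy_step_table(self, prior_ensemble):
        de = energy_steps(prior_ensemble)
        assert len(de) == len(prior_ensemble) - 1
        assert np.all(de >= 0.0)
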