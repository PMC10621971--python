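"""Cell-grid decomposition, force correctness, integration and boundaries."""
import numpy as np
import pytest

from particell import (
    ConstantForce,
    DPDParams,
    EngineError,
    GaussianNoise,
    Harmonic,
    Morse,
    Universe,
)
from particell.engine import (
    CellGrid,
    brute_force_pairs,
    candidate_pairs,
    compute_forces,
    reference_pairs,
)


def fill_random(u, n, rng, tname="A"):
    for _ in range(n):
        u.create_particle(tname, rng.uniform(0, u.dims, 3))


def pair_key_set(ps):
    return {(min(a, b), max(a, b)) for a, b in zip(ps.i.tolist(), ps.j.tolist())}


class TestCellGrid:
    def test_counts_floor_of_box_over_cutoff(self):
        u = Universe(dims=(10, 10, 10), cutoff=5.0, dt=0.01)
        grid = CellGrid(u, np.zeros((0, 3)))
        assert tuple(grid.cell_counts) == (2, 2, 2)

    def test_fractional_cell_size(self):
        u = Universe(dims=(10, 10, 10), cutoff=3.0, dt=0.01)
        grid = CellGrid(u, np.zeros((0, 3)))
        assert tuple(grid.cell_counts) == (3, 3, 3)
        np.testing.assert_allclose(grid.cell_size, 10.0 / 3.0)

    def test_particle_reindexed_after_crossing(self):
        u = Universe(dims=(10, 10, 10), cutoff=2.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        p = u.create_particle("A", (1.0, 1.0, 1.0))
        grid = CellGrid(u, np.array([p.position]))
        assert grid.cell_of(0) == (0, 0, 0)
        p.position[:] = (3.5, 1.0, 1.0)
        grid = CellGrid(u, np.array([p.position]))
        assert grid.cell_of(0) == (1, 0, 0)

    def test_oversized_cutoff_rejected_under_periodic(self):
        with pytest.raises(ValueError):
            Universe(dims=(10, 10, 10), boundary="periodic", cutoff=11.0)

    def test_sort_cell_orders_by_projection_with_stable_ties(self, rng):
        u = Universe(dims=(10, 10, 10), cutoff=5.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        for x in (1.0, 3.0, 2.0, 3.0):
            u.create_particle("A", (x, 1.0, 1.0))
        pos = np.array([p.position for p in u.particles.values()])
        grid = CellGrid(u, pos)
        ordered = grid.sort_cell((0, 0, 0))[(1, 0, 0)]
        assert list(ordered) == [0, 2, 1, 3]  # ties broken by row index

    def test_empty_cell_has_empty_lists(self):
        u = Universe(dims=(10, 10, 10), cutoff=5.0, dt=0.01)
        grid = CellGrid(u, np.zeros((0, 3)))
        assert len(grid.rows_in_cell((1, 1, 1))) == 0


class TestPairEnumeration:
    @pytest.mark.parametrize("boundary", ["periodic", "reflective"])
    @pytest.mark.parametrize("cutoff", [1.0, 2.0, 5.0])
    def test_all_paths_agree_with_brute_force(self, boundary, cutoff, rng):
        u = Universe(dims=(10, 10, 10), boundary=boundary, cutoff=cutoff, dt=0.01)
        u.register_type(name="A", mass=1.0)
        fill_random(u, 150, rng)
        pos = np.array([p.position for p in u.particles.values()])
        grid = CellGrid(u, pos)
        fast = pair_key_set(candidate_pairs(u, grid))
        ref = pair_key_set(reference_pairs(u, grid))
        brute = pair_key_set(brute_force_pairs(u, pos))
        assert fast == brute
        assert ref == brute


class TestForceStage:
    def test_no_bindings_gives_zero_forces(self, rng):
        u = Universe(dims=(10, 10, 10), cutoff=2.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        fill_random(u, 50, rng)
        f, pe, *_ = compute_forces(u)
        assert np.all(f == 0.0)
        assert pe == 0.0

    @pytest.mark.parametrize("boundary", ["periodic", "reflective"])
    def test_cell_list_forces_equal_all_pairs_oracle(self, boundary, rng):
        u = Universe(dims=(10, 10, 10), boundary=boundary, cutoff=2.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        fill_random(u, 200, rng)
        pot = Morse(d=0.5, a=2.0, r0=1.0, r_min=0.05, r_max=2.0)
        u.bind_potential(pot, "A", "A")
        f, pe, *_ = compute_forces(u)
        pos = np.array([p.position for p in u.particles.values()])
        bf = brute_force_pairs(u, pos)
        uu, du = pot.evaluate(bf.r)
        fvec = (-du / bf.r)[:, None] * bf.dx
        expect = np.zeros_like(f)
        np.add.at(expect, bf.i, fvec)
        np.add.at(expect, bf.j, -fvec)
        assert np.abs(f - expect).max() <= 1e-10
        assert pe == pytest.approx(uu.sum(), abs=1e-10)

    def test_bound_mode_scopes_to_same_cluster(self):
        u = Universe(dims=(10, 10, 10), cutoff=3.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        c1 = u.create_cluster()
        c2 = u.create_cluster()
        a = u.create_particle("A", (4.0, 5, 5), cluster=c1.id)
        b = u.create_particle("A", (5.5, 5, 5), cluster=c1.id)
        c = u.create_particle("A", (6.4, 5, 5), cluster=c2.id)
        u.bind_potential(Harmonic(1.0, 1.0, r_max=3.0), "A", "A", mode="bound")
        f, *_ = compute_forces(u)
        # c interacts with nobody: different top-level cluster
        np.testing.assert_allclose(f[2], 0.0, atol=1e-14)
        assert np.abs(f[0]).max() > 0

    def test_unbound_mode_is_complementary(self):
        u = Universe(dims=(10, 10, 10), cutoff=3.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        c1 = u.create_cluster()
        a = u.create_particle("A", (4.0, 5, 5), cluster=c1.id)
        b = u.create_particle("A", (5.5, 5, 5), cluster=c1.id)
        c = u.create_particle("A", (6.4, 5, 5))
        u.bind_potential(Harmonic(1.0, 1.0, r_max=3.0), "A", "A", mode="unbound")
        f, *_ = compute_forces(u)
        # a-b share a cluster: no interaction between them, both feel only c
        assert np.abs(f[2]).max() > 0
        np.testing.assert_allclose(f[0] + f[1] + f[2], 0.0, atol=1e-12)

    def test_frozen_particles_accumulate_forces_but_never_move(self):
        u = Universe(dims=(10, 10, 10), cutoff=3.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        a = u.create_particle("A", (4.5, 5, 5), frozen=True)
        b = u.create_particle("A", (6.0, 5, 5))
        u.bind_potential(Harmonic(1.0, 1.0, r_max=3.0), "A", "A")
        start = a.position.copy()
        u.step(20)
        assert np.all(a.position == start)
        assert np.abs(a.force).max() > 0


class TestIntegration:
    def test_static_universe_advances_time_only(self):
        u = Universe(dims=(10, 10, 10), cutoff=1.0, dt=0.25, seed=0)
        u.register_type(name="A", mass=1.0)
        p = u.create_particle("A", (5, 5, 5))
        u.step(4)
        np.testing.assert_array_equal(p.position, (5, 5, 5))
        assert u.time == pytest.approx(1.0)
        assert u.step_count == 4

    def test_overdamped_closed_form_displacement(self):
        """r advances by n*dt*f/m exactly under forward Euler drag dynamics."""
        u = Universe(dims=(50, 50, 50), boundary="reflective", cutoff=1.0, dt=0.01)
        u.register_type(name="A", mass=2.0, dynamics="overdamped")
        p = u.create_particle("A", (5, 25, 25))
        u.bind_force(ConstantForce((3.0, 0, 0)), "A")
        n = 250
        u.step(n)
        assert p.position[0] == pytest.approx(5 + n * 0.01 * 3.0 / 2.0, rel=1e-12)

    def test_momentum_conserved_with_pair_forces_only(self, rng):
        u = Universe(dims=(8, 8, 8), boundary="periodic", cutoff=2.0, dt=0.005, seed=2)
        u.register_type(name="A", mass=1.0)
        fill_random(u, 60, rng)
        u.bind_potential(Morse(d=0.2, a=2.0, r0=1.0, r_min=0.2, r_max=2.0), "A", "A")
        p0 = sum(p.mass * p.velocity for p in u.particles.values())
        u.step(1000)
        p1 = sum(p.mass * p.velocity for p in u.particles.values())
        assert np.abs(p1 - p0).max() <= 1e-9

    def test_identical_seeds_give_bitwise_identical_trajectories(self, rng):
        def build():
            u = Universe(dims=(6, 6, 6), boundary="periodic", cutoff=1.0, dt=0.01, seed=11)
            u.register_type(name="A", mass=1.0)
            r = np.random.default_rng(5)
            for _ in range(40):
                u.create_particle("A", r.uniform(0, 6, 3))
            u.bind_dpd(DPDParams(alpha=10, gamma=4.5, sigma=3.0, rc=1.0), "A", "A")
            u.bind_force(GaussianNoise(gamma=1.0, kT=0.5), "A")
            return u

        u1, u2 = build(), build()
        u1.step(50)
        u2.step(50)
        for p, q in zip(u1.particles.values(), u2.particles.values()):
            assert np.array_equal(p.position, q.position)
            assert np.array_equal(p.velocity, q.velocity)

    def test_nonfinite_position_aborts_with_particle_id(self):
        u = Universe(dims=(10, 10, 10), cutoff=1.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        p = u.create_particle("A", (5, 5, 5))
        p.position[0] = np.nan
        with pytest.raises(EngineError, match=rf"particle {p.id}"):
            u.step()


class TestBoundaries:
    def test_periodic_wrap(self):
        from particell.core import wrap_position

        pos, vel = wrap_position((10.3, 5, 5), (1, 0, 0), np.array([10.0] * 3), ("periodic",) * 3)
        assert pos[0] == pytest.approx(0.3)
        assert vel[0] == 1.0

    def test_reflective_mirror_negates_velocity(self):
        from particell.core import wrap_position

        pos, vel = wrap_position(
            (-0.2, 5, 5), (-1.0, 0, 0), np.array([10.0] * 3), ("reflective",) * 3
        )
        assert pos[0] == pytest.approx(0.2)
        assert vel[0] == 1.0

    def test_wrapping_idempotent_once_in_range(self):
        from particell.core import wrap_position

        dims = np.array([10.0] * 3)
        for boundary in (("periodic",) * 3, ("reflective",) * 3):
            pos, vel = wrap_position((17.4, -3.2, 5.0), (1, 1, 1), dims, boundary)
            pos2, vel2 = wrap_position(pos, vel, dims, boundary)
            np.testing.assert_array_equal(pos, pos2)
            np.testing.assert_array_equal(vel, vel2)


class TestEnergy:
    def test_rest_universe_has_zero_energies(self):
        u = Universe(dims=(10, 10, 10), cutoff=1.0, dt=0.01)
        u.register_type(name="A", mass=1.0)
        u.create_particle("A", (2, 2, 2))
        u.create_particle("A", (8, 8, 8))
        assert u.total_energy() == (0.0, 0.0)

    def test_potential_total_equals_all_pairs_sum(self, rng):
        u = Universe(dims=(10, 10, 10), boundary="periodic", cutoff=2.5, dt=0.01)
        u.register_type(name="A", mass=1.0)
        fill_random(u, 80, rng)
        pot = Harmonic(0.7, 1.2, r_max=2.5)
        u.bind_potential(pot, "A", "A")
        _, pe = u.total_energy()
        pos = np.array([p.position for p in u.particles.values()])
        bf = brute_force_pairs(u, pos)
        assert pe == pytest.approx(pot.evaluate(bf.r)[0].sum(), abs=1e-10)

    def test_oscillator_energy_drift_shrinks_linearly_with_dt(self):
        from particell.models import build_oscillator
        from particell.models.oscillator import energy_envelope

        envelopes = []
        for dt in (0.02, 0.01, 0.005):
            u = build_oscillator(dt=dt)
            envelopes.append(energy_envelope(u, int(3.2 / dt)))
        orders = [np.log2(envelopes[i] / envelopes[i + 1]) for i in range(2)]
        assert all(0.7 <= o <= 1.3 for o in orders)
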