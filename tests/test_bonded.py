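"""Bond/Angle/Dihedral energies, analytic forces, and dissociation."""
import math

import numpy as np
import pytest

from particell import Harmonic, Universe
from particell.bonded import (
    Angle,
    Bond,
    BondedGeometryError,
    Dihedral,
    angle_energy_forces,
    angle_value,
    bond_energy_forces,
    cull_dissociated,
    dihedral_energy_forces,
    dihedral_value,
)

POT = Harmonic(k=1.3, r0=1.1)


def random_positions(rng, n=4, scale=1.0):
    return {i: rng.normal(0.0, scale, 3) for i in range(n)}


class TestBond:
    def test_rest_length_is_stationary(self):
        positions = {0: np.zeros(3), 1: np.array([1.1, 0, 0])}
        e, fmap = bond_energy_forces(Bond(0, 0, 1, POT), positions)
        assert e == 0.0
        assert np.all(fmap[0] == 0.0) and np.all(fmap[1] == 0.0)

    def test_forces_match_numerical_gradient(self, rng, numgrad):
        bond = Bond(0, 0, 1, POT)
        for _ in range(25):
            positions = random_positions(rng, 2)
            e, fmap = bond_energy_forces(bond, positions)
            ng = numgrad(lambda pp: bond_energy_forces(bond, pp)[0], positions, [0, 1])
            for pid in (0, 1):
                np.testing.assert_allclose(fmap[pid], -ng[pid], atol=1e-6)

    def test_newtons_third_law_exact(self, rng):
        bond = Bond(0, 0, 1, POT)
        positions = random_positions(rng, 2)
        _, fmap = bond_energy_forces(bond, positions)
        assert np.all(fmap[0] + fmap[1] == 0.0)

    def test_coincident_endpoints_rejected(self):
        positions = {0: np.zeros(3), 1: np.zeros(3)}
        with pytest.raises(BondedGeometryError):
            bond_energy_forces(Bond(0, 0, 1, POT), positions)

    def test_same_particle_twice_rejected(self):
        with pytest.raises(ValueError):
            Bond(0, 3, 3, POT)


class TestAngle:
    def test_orthogonal_arms(self):
        positions = {0: np.array([1.0, 0, 0]), 1: np.zeros(3), 2: np.array([0, 1.0, 0])}
        assert angle_value(positions, 0, 1, 2) == pytest.approx(math.pi / 2)

    def test_forces_match_numerical_gradient(self, rng, numgrad):
        ang = Angle(0, 0, 1, 2, POT)
        worst = 0.0
        for _ in range(25):
            positions = random_positions(rng, 3)
            _, fmap = angle_energy_forces(ang, positions)
            ng = numgrad(lambda pp: angle_energy_forces(ang, pp)[0], positions, [0, 1, 2])
            for pid in (0, 1, 2):
                worst = max(worst, float(np.abs(fmap[pid] + ng[pid]).max()))
        assert worst < 1e-5

    def test_net_force_and_torque_vanish(self, rng):
        ang = Angle(0, 0, 1, 2, POT)
        positions = random_positions(rng, 3)
        _, fmap = angle_energy_forces(ang, positions)
        net = sum(fmap.values())
        np.testing.assert_allclose(net, 0.0, atol=1e-10)
        pivot = positions[1]
        torque = sum(np.cross(positions[pid] - pivot, fmap[pid]) for pid in fmap)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_zero_length_arm_rejected(self):
        positions = {0: np.zeros(3), 1: np.zeros(3), 2: np.array([1.0, 0, 0])}
        with pytest.raises(BondedGeometryError):
            angle_energy_forces(Angle(0, 0, 1, 2, POT), positions)

    def test_near_collinear_guard_returns_finite_zero_forces(self):
        positions = {
            0: np.array([-1.0, 1e-12, 0.0]),
            1: np.zeros(3),
            2: np.array([1.0, 0.0, 0.0]),
        }
        e, fmap = angle_energy_forces(Angle(0, 0, 1, 2, POT), positions)
        assert np.isfinite(e)
        for f in fmap.values():
            assert np.all(f == 0.0)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        positions = {
            0: np.array([0.0, 1.0, 0.0]),
            1: np.zeros(3),
            2: np.array([1.0, 0.0, 0.0]),
            3: np.array([1.0, 1.0, 0.0]),
        }
        assert dihedral_value(positions, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_pi(self):
        positions = {
            0: np.array([0.0, 1.0, 0.0]),
            1: np.zeros(3),
            2: np.array([1.0, 0.0, 0.0]),
            3: np.array([1.0, -1.0, 0.0]),
        }
        assert abs(dihedral_value(positions, 0, 1, 2, 3)) == pytest.approx(math.pi)

    def test_forces_match_numerical_gradient(self, rng, numgrad):
        dih = Dihedral(0, 0, 1, 2, 3, POT)
        worst = 0.0
        for _ in range(25):
            positions = random_positions(rng, 4)
            try:
                _, fmap = dihedral_energy_forces(dih, positions)
            except BondedGeometryError:
                continue
            ng = numgrad(
                lambda pp: dihedral_energy_forces(dih, pp)[0], positions, range(4)
            )
            for pid in range(4):
                scale = max(1.0, float(np.abs(ng[pid]).max()))
                worst = max(worst, float(np.abs(fmap[pid] + ng[pid]).max()) / scale)
        assert worst < 1e-5

    def test_translation_invariance(self, rng):
        dih = Dihedral(0, 0, 1, 2, 3, POT)
        positions = random_positions(rng, 4)
        e1, f1 = dihedral_energy_forces(dih, positions)
        shifted = {k: v + np.array([2.2, -1.7, 0.4]) for k, v in positions.items()}
        e2, f2 = dihedral_energy_forces(dih, shifted)
        assert e1 == pytest.approx(e2, rel=1e-12)
        for pid in range(4):
            np.testing.assert_allclose(f1[pid], f2[pid], atol=1e-9)

    def test_degenerate_plane_rejected(self):
        positions = {
            0: np.zeros(3),
            1: np.array([1.0, 0, 0]),
            2: np.array([2.0, 0, 0]),
            3: np.array([3.0, 1.0, 0]),
        }
        with pytest.raises(BondedGeometryError):
            dihedral_energy_forces(Dihedral(0, 0, 1, 2, 3, POT), positions)


class TestDissociation:
    def test_below_threshold_retained(self):
        registry = {0: Bond(0, 0, 1, POT, dissociation_energy=1.0)}
        assert cull_dissociated(registry, {0: 0.9}) == []
        assert 0 in registry

    def test_above_threshold_destroyed(self):
        registry = {0: Bond(0, 0, 1, POT, dissociation_energy=1.0)}
        destroyed = cull_dissociated(registry, {0: 1.1})
        assert [b.id for b in destroyed] == [0]
        assert registry == {}

    def test_no_threshold_never_destroyed(self):
        registry = {0: Bond(0, 0, 1, POT)}
        assert cull_dissociated(registry, {0: 1e9}) == []
        assert 0 in registry


class TestEngineIntegration:
    def _molecule(self):
        """A four-particle toy molecule with a bond, an angle and a dihedral."""
        u = Universe(dims=(20, 20, 20), boundary="reflective", cutoff=1.0, dt=1e-3, seed=0)
        u.register_type(name="atom", mass=1.0)
        pts = [(9, 10, 10), (10, 10, 10), (10.6, 11, 10), (11, 11, 11)]
        ids = [u.create_particle("atom", p).id for p in pts]
        u.create_bond(Harmonic(50, 1.0), ids[0], ids[1])
        u.create_bond(Harmonic(50, 1.0), ids[1], ids[2])
        u.create_bond(Harmonic(50, 1.0), ids[2], ids[3])
        u.create_angle(Harmonic(5, 2.0), ids[0], ids[1], ids[2])
        u.create_dihedral(Harmonic(1, 1.5), *ids)
        return u, ids

    def test_molecule_forces_sum_to_zero_each_step(self):
        u, _ = self._molecule()
        for _ in range(50):
            u.step()
            net = sum(p.force for p in u.particles.values())
            np.testing.assert_allclose(net, 0.0, atol=1e-10)

    def test_bonds_act_beyond_global_cutoff(self):
        u = Universe(dims=(20, 20, 20), boundary="reflective", cutoff=1.0, dt=1e-3, seed=0)
        u.register_type(name="atom", mass=1.0)
        a = u.create_particle("atom", (5, 10, 10))
        b = u.create_particle("atom", (15, 10, 10))  # 10 length units apart
        u.create_bond(Harmonic(1.0, 1.0), a.id, b.id)
        u.step()
        assert abs(a.force[0]) > 0.0

    def test_destroying_particle_sweeps_bonded_registries(self):
        u, ids = self._molecule()
        u.destroy_particle(ids[1])
        assert len(u.bonds) == 1  # only the 2-3 bond survives
        assert len(u.angles) == 0
        assert len(u.dihedrals) == 0

    def test_dissociation_happens_at_first_crossing(self):
        """A quasi-statically stretched bond breaks at the first step whose
        energy exceeds the threshold, never before."""
        u = Universe(dims=(30, 30, 30), boundary="reflective", cutoff=1.0, dt=0.01, seed=0)
        u.register_type(name="atom", mass=1.0, frozen_default=True)
        a = u.create_particle("atom", (10, 10, 10))
        b = u.create_particle("atom", (11, 10, 10))
        pot = Harmonic(1.0, 1.0)
        threshold = 0.25
        u.create_bond(pot, a.id, b.id, dissociation_energy=threshold)

        pull = 0.01

        def stretch(universe, time):
            if b.id in universe.particles:
                universe.particles[b.id].position[0] += pull

        u.on_event(stretch, period_steps=1)
        broken_at = None
        for _ in range(200):
            length_before = u.distance(a.position, b.position)
            u.step()
            if not u.bonds:
                broken_at = length_before  # energy evaluated pre-stretch
                break
        assert broken_at is not None
        e_break = pot.energy(broken_at)
        e_before = pot.energy(broken_at - pull)
        assert e_break > threshold
        assert e_before <= threshold
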