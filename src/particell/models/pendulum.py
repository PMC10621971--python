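"""Double pendulum from bonded particles.

A frozen pivot particle, two Newtonian bobs connected pivot-bob1-bob2 by
stiff harmonic bonds, and a constant downward explicit force on the bobs.
Motion is confined to the x-y plane.  With stiff bonds the bond lengths
stay close to the rest length and the system approximates the classical
rigid double pendulum.
"""
from __future__ import annotations

import math

import numpy as np

from ..core import Universe
from ..forces import ConstantForce
from ..potentials import Harmonic


def build_pendulum(
    k=200.0,
    g=2.0,
    m=1.0,
    rest=1.0,
    theta1=math.pi / 3,
    theta2=math.pi / 2,
    dt=1e-3,
    seed=0,
    box=10.0,
) -> Universe:
    """Angles are measured from the downward vertical."""
    u = Universe(
        dims=(box, box, box),
        boundary="reflective",
        cutoff=1.0,
        dt=dt,
        seed=seed,
        plane_axis=2,
    )
    u.register_type(name="pivot", mass=1.0, frozen_default=True)
    u.register_type(name="bob", mass=m)
    top = np.array([box / 2.0, box * 0.8, box / 2.0])
    pivot = u.create_particle("pivot", top)
    r1 = top + rest * np.array([math.sin(theta1), -math.cos(theta1), 0.0])
    r2 = r1 + rest * np.array([math.sin(theta2), -math.cos(theta2), 0.0])
    b1 = u.create_particle("bob", r1)
    b2 = u.create_particle("bob", r2)
    bond_pot = Harmonic(k, rest)
    u.create_bond(bond_pot, pivot.id, b1.id)
    u.create_bond(bond_pot, b1.id, b2.id)
    if g != 0:
        u.bind_force(ConstantForce((0.0, -m * g, 0.0)), "bob")
    return u
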