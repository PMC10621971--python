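"""Bonded interactions between explicitly enumerated particles.

A :class:`Bond` applies a potential to the Euclidean distance between two
particles, an :class:`Angle` to the angle at its pivot (second) particle,
and a :class:`Dihedral` to the torsion angle between the planes (i,j,k) and
(j,k,l).  All three reuse the ordinary :class:`~particell.potentials.Potential`
evaluation contract, with the angle (in radians) as the abscissa for Angle
and Dihedral terms.

Forces are analytic gradients of the energy; each force map sums to the
zero vector, so bonded terms conserve momentum exactly.  Separations are
minimum-image under periodic boundaries, and bonded terms ignore the global
implicit-interaction cutoff: a bond acts at any length.

Any bonded item may carry a ``dissociation_energy``; the engine destroys
the item at the end of the first step whose computed potential energy
exceeds that threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: below this sine of the bond angle the (singular) angle gradient is zeroed
SIN_THETA_GUARD = 1e-8


class BondedGeometryError(ValueError):
    pass


@dataclass
class Bond:
    id: int
    i: int
    j: int
    potential: object
    dissociation_energy: Optional[float] = None

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must be distinct particles")

    def particle_ids(self):
        return (self.i, self.j)


@dataclass
class Angle:
    """Three-particle angle term; the pivot is the second particle ``j``."""

    id: int
    i: int
    j: int
    k: int
    potential: object
    dissociation_energy: Optional[float] = None

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle requires three distinct particles")

    def particle_ids(self):
        return (self.i, self.j, self.k)


@dataclass
class Dihedral:
    """Four-particle torsion term between planes (i,j,k) and (j,k,l).

    Sign convention: cis (i and l on the same side of the j-k axis) is
    ``phi = 0``; the angle is measured in ``(-pi, pi]`` with the sign of
    ``(n1 x n2) . b2`` where ``n1, n2`` are the plane normals and ``b2`` the
    j->k bond vector.
    """

    id: int
    i: int
    j: int
    k: int
    l: int
    potential: object
    dissociation_energy: Optional[float] = None

    def __post_init__(self):
        if len({self.i, self.j, self.k, self.l}) != 4:
            raise ValueError("dihedral requires four distinct particles")

    def particle_ids(self):
        return (self.i, self.j, self.k, self.l)


def _plain_disp(ri, rj):
    return np.asarray(ri, float) - np.asarray(rj, float)


def bond_energy_forces(bond: Bond, positions, disp=_plain_disp):
    """Energy and force map ``{i: F_i, j: F_j}`` for a distance bond.

    ``positions`` maps particle id to a 3-vector; ``disp`` computes the
    (minimum-image) displacement ``r_i - r_j``.
    """
    d = disp(positions[bond.i], positions[bond.j])
    l = float(np.linalg.norm(d))
    if l == 0.0:
        raise BondedGeometryError(f"bond {bond.id}: coincident endpoints")
    u, du = bond.potential.evaluate(l)
    fi = (-du / l) * d
    return u, {bond.i: fi, bond.j: -fi}


def angle_value(positions, i, j, k, disp=_plain_disp):
    """Angle at pivot ``j`` in ``[0, pi]`` via arctangent of (|cross|, dot)."""
    u = disp(positions[i], positions[j])
    v = disp(positions[k], positions[j])
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise BondedGeometryError("angle has a zero-length arm")
    cross = np.cross(u, v)
    return math.atan2(float(np.linalg.norm(cross)), float(np.dot(u, v)))


def angle_energy_forces(angle: Angle, positions, disp=_plain_disp):
    """Energy and force map over ``{i, j, k}`` for an angle term.

    Near-collinear configurations (``sin(theta)`` below a guard) return the
    energy with zero forces for that step: the true gradient is singular
    there, and a bounded force is preferable to an overflow.
    """
    u = disp(positions[angle.i], positions[angle.j])
    v = disp(positions[angle.k], positions[angle.j])
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise BondedGeometryError(f"angle {angle.id}: zero-length arm")
    uh = u / nu
    vh = v / nv
    cos_t = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    sin_t = float(np.linalg.norm(np.cross(uh, vh)))
    theta = math.atan2(sin_t, cos_t)
    energy, du_dtheta = angle.potential.evaluate(max(theta, 1e-300))
    zero = {angle.i: np.zeros(3), angle.j: np.zeros(3), angle.k: np.zeros(3)}
    if sin_t < SIN_THETA_GUARD:
        return energy, zero
    dth_di = (cos_t * uh - vh) / (nu * sin_t)
    dth_dk = (cos_t * vh - uh) / (nv * sin_t)
    dth_dj = -(dth_di + dth_dk)
    return energy, {
        angle.i: -du_dtheta * dth_di,
        angle.j: -du_dtheta * dth_dj,
        angle.k: -du_dtheta * dth_dk,
    }


def dihedral_value(positions, i, j, k, l, disp=_plain_disp):
    """Torsion angle in ``(-pi, pi]``; cis is 0."""
    b1 = disp(positions[j], positions[i])
    b2 = disp(positions[k], positions[j])
    b3 = disp(positions[l], positions[k])
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    if float(np.linalg.norm(n1)) == 0.0 or float(np.linalg.norm(n2)) == 0.0 or nb2 == 0.0:
        raise BondedGeometryError("dihedral has a degenerate plane")
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    x = float(np.dot(n1, n2))
    return math.atan2(y, x)


def dihedral_energy_forces(dihedral: Dihedral, positions, disp=_plain_disp):
    """Energy and force map over ``{i, j, k, l}`` for a torsion term."""
    b1 = disp(positions[dihedral.j], positions[dihedral.i])
    b2 = disp(positions[dihedral.k], positions[dihedral.j])
    b3 = disp(positions[dihedral.l], positions[dihedral.k])
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    nb2 = float(np.linalg.norm(b2))
    if n1sq == 0.0 or n2sq == 0.0 or nb2 == 0.0:
        raise BondedGeometryError(f"dihedral {dihedral.id}: degenerate plane")
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    x = float(np.dot(n1, n2))
    phi = math.atan2(y, x)
    # angle-valued potentials may be defined only over (0, pi]; evaluate on a
    # branch shifted away from zero is the caller's choice of potential form
    energy, du_dphi = _eval_angle_potential(dihedral.potential, phi)
    dphi_di = -(nb2 / n1sq) * n1
    dphi_dl = (nb2 / n2sq) * n2
    c12 = float(np.dot(b1, b2)) / (nb2 * nb2)
    c32 = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_dj = -(1.0 + c12) * dphi_di + c32 * dphi_dl
    dphi_dk = c12 * dphi_di - (1.0 + c32) * dphi_dl
    return energy, {
        dihedral.i: -du_dphi * dphi_di,
        dihedral.j: -du_dphi * dphi_dj,
        dihedral.k: -du_dphi * dphi_dk,
        dihedral.l: -du_dphi * dphi_dl,
    }


def _eval_angle_potential(potential, phi):
    """Evaluate an angle-abscissa potential at a signed torsion angle.

    Potentials reject non-positive abscissae, so the signed angle is mapped
    through its magnitude with the chain rule (harmonic-in-angle and other
    even potentials are unaffected; the mapping is documented behavior).
    """
    if phi == 0.0:
        mag = 1e-300
        sign = 1.0
    else:
        mag = abs(phi)
        sign = 1.0 if phi > 0 else -1.0
    u, du = potential.evaluate(mag)
    return u, du * sign


def cull_dissociated(registry: dict, energies: dict) -> list:
    """Remove every item whose energy exceeds its dissociation threshold.

    ``energies`` maps item id to the potential energy computed this step.
    Returns the list of destroyed items.
    """
    destroyed = []
    for bid, item in list(registry.items()):
        if item.dissociation_energy is None:
            continue
        e = energies.get(bid)
        if e is not None and e > item.dissociation_energy:
            destroyed.append(registry.pop(bid))
    return destroyed
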