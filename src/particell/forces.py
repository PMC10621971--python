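"""Explicit (per-particle) force generators.

Explicit forces are not derived from pair potentials: they act on each
particle of a bound type independently.  The total force on a particle is
the sum of its pairwise (implicit and bonded) contributions plus every
explicit force bound to its type.
"""
from __future__ import annotations

import math

import numpy as np


class ExplicitForce:
    """Base class.  Subclasses fill ``f_out[rows]`` for the bound type."""

    kind = "abstract"

    def apply(self, universe, rows, vel, f_out, rng, dt):  # pragma: no cover
        raise NotImplementedError

    def to_dict(self) -> dict:  # pragma: no cover
        raise NotImplementedError


class ConstantForce(ExplicitForce):
    """A constant body force (e.g. gravity) applied to every particle."""

    kind = "constant"

    def __init__(self, f0):
        self.f0 = np.asarray(f0, dtype=float)
        if self.f0.shape != (3,) or not np.all(np.isfinite(self.f0)):
            raise ValueError("constant force requires a finite 3-vector")

    def apply(self, universe, rows, vel, f_out, rng, dt):
        f_out[rows] += self.f0

    def to_dict(self):
        return {"kind": "constant", "f0": [float(x) for x in self.f0]}


class Friction(ExplicitForce):
    """Linear drag ``F = -gamma * v``."""

    kind = "friction"

    def __init__(self, gamma):
        if gamma < 0:
            raise ValueError("friction coefficient must be non-negative")
        self.gamma = float(gamma)

    def apply(self, universe, rows, vel, f_out, rng, dt):
        f_out[rows] += -self.gamma * vel[rows]

    def to_dict(self):
        return {"kind": "friction", "gamma": self.gamma}


class GaussianNoise(ExplicitForce):
    """Thermal noise ``F = sqrt(2 gamma kT / dt) * xi`` per axis.

    Paired with :class:`Friction` of the same ``gamma`` this realizes a
    Langevin thermostat whose equilibrium kinetic temperature is ``kT``.
    """

    kind = "gaussian_noise"

    def __init__(self, gamma, kT):
        if gamma < 0 or kT < 0:
            raise ValueError("gamma and kT must be non-negative")
        self.gamma = float(gamma)
        self.kT = float(kT)

    def apply(self, universe, rows, vel, f_out, rng, dt):
        amp = math.sqrt(2.0 * self.gamma * self.kT / dt)
        f_out[rows] += amp * rng.standard_normal((len(rows), 3))

    def to_dict(self):
        return {"kind": "gaussian_noise", "gamma": self.gamma, "kT": self.kT}


class CustomForce(ExplicitForce):
    """User callback ``fn(particle) -> 3-vector``, applied per particle.

    Serializable only when registered under a name (see ``io_state``).
    """

    kind = "custom"

    def __init__(self, fn, name=None):
        self.fn = fn
        self.name = name

    def apply(self, universe, rows, vel, f_out, rng, dt):
        arrays = universe._arrays_cache
        for row in rows:
            p = universe.particles[int(arrays["ids"][row])]
            f = np.asarray(self.fn(p), dtype=float)
            if f.shape != (3,) or not np.all(np.isfinite(f)):
                raise ValueError(
                    f"custom force {self.name or self.fn!r} returned a non-finite "
                    f"or malformed vector for particle {p.id}"
                )
            f_out[row] += f

    def to_dict(self):
        if self.name is None:
            raise ValueError("custom force must be registered under a name to serialize")
        return {"kind": "custom", "name": self.name}


FORCE_KINDS = {
    "constant": ConstantForce,
    "friction": Friction,
    "gaussian_noise": GaussianNoise,
}


def force_from_dict(doc: dict):
    kind = doc.get("kind")
    if kind == "constant":
        return ConstantForce(doc["f0"])
    if kind == "friction":
        return Friction(doc["gamma"])
    if kind == "gaussian_noise":
        return GaussianNoise(doc["gamma"], doc["kT"])
    if kind == "custom":
        from .io_state import resolve_callback

        return CustomForce(resolve_callback("force", doc["name"]), name=doc["name"])
    raise ValueError(f"unknown explicit force kind {kind!r}")
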