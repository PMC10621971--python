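"""Pairwise potential process objects.

A :class:`Potential` maps a scalar separation (or, for bonded angle terms,
an angle in radians) to an energy and its derivative.  The engine converts
the scalar derivative into a vector force on particle *i* as
``-(dU/dr) * (r_i - r_j) / r``, which makes every pair force satisfy
Newton's third law by construction.

Evaluation contract
-------------------
- ``r >= r_max`` returns exactly ``(0, 0)`` (strict cutoff).
- ``r < r_min`` evaluates at ``r_min`` (abscissa clamp), bounding the force
  for deeply overlapping particles created at runtime.
- ``r <= 0`` raises (singular separation).

Potentials compose by addition: ``a + b`` builds a summation process object
that forwards evaluation to its children and returns the sum of their
results, to arbitrary nesting depth.

Functional conventions (documented constants of this package):

- harmonic       ``U = k (r - r0)^2``
- lennard_jones  ``U = A / r^12 - B / r^6``
- morse          ``U = d [(1 - exp(-a (r - r0)))^2 - 1]``
- coulomb        ``U = q / r``  (unit-free charge product)
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class PotentialError(ValueError):
    pass


class Potential:
    """Base class for all pair potentials."""

    kind = "abstract"

    def __init__(self, r_min=0.0, r_max=np.inf):
        if not (0 <= r_min < r_max):
            raise PotentialError("require 0 <= r_min < r_max")
        self.r_min = float(r_min)
        self.r_max = float(r_max)

    # subclasses implement the raw functional form (no range handling)
    def _energy(self, r):  # pragma: no cover - abstract
        raise NotImplementedError

    def _derivative(self, r):  # pragma: no cover - abstract
        raise NotImplementedError

    def evaluate(self, r):
        """Return ``(U(r), dU/dr)`` applying the range contract.

        Accepts a scalar or an ndarray; the return matches the input shape.
        """
        scalar = np.isscalar(r) or np.ndim(r) == 0
        r = np.atleast_1d(np.asarray(r, dtype=float))
        if np.any(r <= 0):
            raise PotentialError("potential evaluated at non-positive separation")
        rc = np.maximum(r, self.r_min) if self.r_min > 0 else r
        u = np.asarray(self._energy(rc), dtype=float)
        du = np.asarray(self._derivative(rc), dtype=float)
        # clamped region: energy held at U(r_min), force bounded there
        outside = r >= self.r_max
        u = np.where(outside, 0.0, u)
        du = np.where(outside, 0.0, du)
        if scalar:
            return float(u[0]), float(du[0])
        return u, du

    def energy(self, r):
        return self.evaluate(r)[0]

    def __add__(self, other):
        if not isinstance(other, Potential):
            return NotImplemented
        return SumPotential(self, other)

    # ------------------------------------------------------------- serialization
    def to_dict(self) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def _range_dict(self):
        d = {}
        if self.r_min > 0:
            d["r_min"] = self.r_min
        if np.isfinite(self.r_max):
            d["r_max"] = self.r_max
        return d


class Harmonic(Potential):
    """``U = k (r - r0)^2`` with stiffness ``k > 0`` and rest length ``r0``."""

    kind = "harmonic"

    def __init__(self, k, r0, r_min=0.0, r_max=np.inf):
        if not (k > 0):
            raise PotentialError("harmonic requires k > 0")
        if r0 < 0:
            raise PotentialError("harmonic requires r0 >= 0")
        super().__init__(r_min, r_max)
        self.k = float(k)
        self.r0 = float(r0)

    def _energy(self, r):
        return self.k * (r - self.r0) ** 2

    def _derivative(self, r):
        return 2.0 * self.k * (r - self.r0)

    def to_dict(self):
        return {"kind": "harmonic", "k": self.k, "r0": self.r0, **self._range_dict()}


class LennardJones(Potential):
    """``U = A / r^12 - B / r^6``; minimum at ``r* = (2A/B)^(1/6)``."""

    kind = "lennard_jones"

    def __init__(self, A, B, r_min=0.0, r_max=np.inf):
        if A <= 0 or B <= 0:
            raise PotentialError("lennard_jones requires A > 0 and B > 0")
        super().__init__(r_min, r_max)
        self.A = float(A)
        self.B = float(B)

    @property
    def r_star(self) -> float:
        return (2.0 * self.A / self.B) ** (1.0 / 6.0)

    def _energy(self, r):
        return self.A / r**12 - self.B / r**6

    def _derivative(self, r):
        return -12.0 * self.A / r**13 + 6.0 * self.B / r**7

    def to_dict(self):
        return {"kind": "lennard_jones", "A": self.A, "B": self.B, **self._range_dict()}


class Morse(Potential):
    """``U = d [(1 - exp(-a (r - r0)))^2 - 1]``: depth ``d``, minimum at ``r0``."""

    kind = "morse"

    def __init__(self, d, a, r0, r_min=0.0, r_max=np.inf):
        if d <= 0 or a <= 0 or r0 < 0:
            raise PotentialError("morse requires d > 0, a > 0, r0 >= 0")
        super().__init__(r_min, r_max)
        self.d = float(d)
        self.a = float(a)
        self.r0 = float(r0)

    def _energy(self, r):
        e = np.exp(-self.a * (r - self.r0))
        return self.d * ((1.0 - e) ** 2 - 1.0)

    def _derivative(self, r):
        e = np.exp(-self.a * (r - self.r0))
        return 2.0 * self.d * self.a * e * (1.0 - e)

    def to_dict(self):
        return {
            "kind": "morse",
            "d": self.d,
            "a": self.a,
            "r0": self.r0,
            **self._range_dict(),
        }


class Coulomb(Potential):
    """``U = q / r`` with unit-free charge product ``q`` (may be negative)."""

    kind = "coulomb"

    def __init__(self, q, r_min=0.0, r_max=np.inf):
        if q == 0:
            raise PotentialError("coulomb requires a non-zero charge product")
        super().__init__(r_min, r_max)
        self.q = float(q)

    def _energy(self, r):
        return self.q / r

    def _derivative(self, r):
        return -self.q / r**2

    def to_dict(self):
        return {"kind": "coulomb", "q": self.q, **self._range_dict()}


class SumPotential(Potential):
    """Summation process object: forwards evaluation to both children and
    returns the sum of their results (children apply their own ranges)."""

    kind = "sum"

    def __init__(self, a: Potential, b: Potential):
        Potential.__init__(self, 0.0, max(a.r_max, b.r_max))
        self.a = a
        self.b = b

    def evaluate(self, r):
        ua, dua = self.a.evaluate(r)
        ub, dub = self.b.evaluate(r)
        return ua + ub, dua + dub

    def to_dict(self):
        return {"kind": "sum", "a": self.a.to_dict(), "b": self.b.to_dict()}


class CustomPotential(Potential):
    """User energy function ``fn(r) -> U``; derivative by central differences
    with step ``h = 1e-6 (r_max - r_min)``.

    The function is sampled over its range at construction; a NaN or Inf
    anywhere in the sample raises immediately.
    """

    kind = "custom"

    def __init__(self, fn, r_min, r_max, name=None, _check_samples=64):
        if not np.isfinite(r_max):
            raise PotentialError("custom potential requires a finite r_max")
        super().__init__(r_min, r_max)
        self.fn = fn
        self.name = name
        self._h = 1e-6 * (self.r_max - self.r_min)
        lo = self.r_min if self.r_min > 0 else 1e-9 * self.r_max
        sample = np.linspace(lo, self.r_max, _check_samples)
        try:
            vals = np.asarray([float(fn(float(x))) for x in sample], dtype=float)
        except (ValueError, TypeError, ArithmeticError) as exc:
            raise PotentialError(f"custom potential failed in range: {exc}") from None
        if not np.all(np.isfinite(vals)):
            bad = sample[~np.isfinite(vals)][0]
            raise PotentialError(f"custom potential is non-finite near r={bad:.6g}")

    def _energy(self, r):
        r = np.atleast_1d(r)
        return np.array([self.fn(float(x)) for x in r])

    def _derivative(self, r):
        r = np.atleast_1d(r)
        h = self._h
        return np.array(
            [(self.fn(float(x) + h) - self.fn(float(x) - h)) / (2.0 * h) for x in r]
        )

    def to_dict(self):
        if self.name is None:
            raise ValueError(
                "custom potential must be registered under a name to serialize"
            )
        return {
            "kind": "custom",
            "name": self.name,
            "r_min": self.r_min,
            "r_max": self.r_max,
        }


@dataclass(frozen=True)
class DPDParams:
    """Transport-DPD pair interaction parameters (Groot-Warren forms).

    - conservative  ``F^C = alpha (1 - r/rc) rhat``
    - dissipative   ``F^D = -gamma (1 - r/rc)^2 (rhat . v_rel) rhat``
    - random        ``F^R = sigma (1 - r/rc) xi rhat / sqrt(dt)``, xi ~ N(0,1)

    The fluctuation-dissipation balance ``sigma^2 = 2 gamma kT`` gives an
    equilibrium kinetic temperature ``kT``; use :meth:`thermalized` to
    construct parameters that satisfy it.
    """

    alpha: float = 25.0
    gamma: float = 4.5
    sigma: float = 3.0
    rc: float = 1.0

    def __post_init__(self):
        if self.gamma < 0 or self.sigma < 0:
            raise PotentialError("dpd requires gamma >= 0 and sigma >= 0")
        if self.rc <= 0:
            raise PotentialError("dpd requires rc > 0")

    @classmethod
    def thermalized(cls, alpha, gamma, kT, rc=1.0):
        return cls(alpha=alpha, gamma=gamma, sigma=math.sqrt(2.0 * gamma * kT), rc=rc)

    def conservative_energy(self, r):
        """Potential of the conservative term: ``(alpha rc / 2)(1 - r/rc)^2``."""
        r = np.asarray(r, dtype=float)
        w = np.where(r < self.rc, 1.0 - r / self.rc, 0.0)
        return 0.5 * self.alpha * self.rc * w**2

    def to_dict(self):
        return {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "rc": self.rc,
        }


def dpd_pair_force(params: DPDParams, r_vec, v_rel, rng, dt):
    """Force on particle *i* from one DPD pair (*i*, *j*).

    ``r_vec = r_i - r_j`` and ``v_rel = v_i - v_j``.  The random term is
    scaled by ``1/sqrt(dt)`` so that the integrated impulse has the proper
    Wiener scaling.  Returns the zero vector for ``|r_vec| >= rc``.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise PotentialError("dpd pair force at zero separation")
    if r >= params.rc:
        return np.zeros(3)
    rhat = r_vec / r
    w = 1.0 - r / params.rc
    v_rel = np.asarray(v_rel, dtype=float)
    fc = params.alpha * w
    fd = -params.gamma * w * w * float(np.dot(rhat, v_rel))
    fr = params.sigma * w * float(rng.standard_normal()) / math.sqrt(dt)
    return (fc + fd + fr) * rhat


_BUILTINS = {
    "harmonic": Harmonic,
    "lennard_jones": LennardJones,
    "morse": Morse,
    "coulomb": Coulomb,
}


def make_potential(kind: str, **params) -> Potential:
    """Factory for built-in potentials, e.g. ``make_potential('harmonic', k=1, r0=1)``."""
    if kind not in _BUILTINS:
        raise PotentialError(
            f"unknown potential kind {kind!r}; choose from {sorted(_BUILTINS)}"
        )
    return _BUILTINS[kind](**params)


def make_custom_potential(fn, r_min, r_max, name=None) -> CustomPotential:
    return CustomPotential(fn, r_min, r_max, name=name)


def sum_potentials(a: Potential, b: Potential) -> SumPotential:
    return SumPotential(a, b)


def potential_from_dict(doc: dict) -> Potential:
    """Rebuild a potential from its dictionary form (see ``to_dict``)."""
    kind = doc.get("kind")
    if kind == "sum":
        return SumPotential(potential_from_dict(doc["a"]), potential_from_dict(doc["b"]))
    if kind == "custom":
        from .io_state import resolve_callback

        fn = resolve_callback("potential", doc["name"])
        return CustomPotential(fn, doc["r_min"], doc["r_max"], name=doc["name"])
    if kind not in _BUILTINS:
        raise PotentialError(f"unknown potential kind {kind!r}")
    params = {k: v for k, v in doc.items() if k != "kind"}
    return _BUILTINS[kind](**params)
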