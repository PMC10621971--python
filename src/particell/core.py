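"""Core domain objects: particle types, particles, clusters, and the universe.

A :class:`Universe` owns the simulation domain (a half-open box ``[0, L)``
per axis with periodic or reflective boundaries), the global interaction
cutoff, the time step, and registries for every model object: particle
types, particles, clusters, bonded interactions, implicit/explicit force
bindings, species flux rules, reactions, and scheduled events.

Particles are discrete agents with position, velocity, a per-step force
accumulator, and an optional chemical state vector aligned with the species
declared by their type.  Clusters group particles (or other clusters) so
that pairwise interactions can be scoped to partners within the same
top-level cluster (*bound*) or across clusters (*unbound*).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .binding import BindingTable

DYNAMICS = ("newtonian", "overdamped")
BOUNDARIES = ("periodic", "reflective")

#: Order in which named child RNG streams are spawned from the root seed.
RNG_STREAMS = ("dpd", "noise", "events", "model")


class ParticellError(Exception):
    """Base class for all errors raised by this package."""


class RegistrationError(ParticellError):
    """Invalid registration of a model object (duplicate name, bad reference)."""


class EngineError(ParticellError):
    """Internal inconsistency detected during simulation stepping."""


@dataclass(frozen=True)
class ParticleType:
    """Categorical descriptor that particles instantiate and inherit from.

    ``mass`` is the inertial mass for Newtonian dynamics and the drag
    coefficient for overdamped (Langevin) dynamics.  ``radius`` is used for
    placement and rendering only and never enters the force calculation.
    """

    name: str
    mass: float = 1.0
    radius: float = 0.5
    dynamics: str = "newtonian"
    species: tuple = ()
    frozen_default: bool = False

    def __post_init__(self):
        if not self.name:
            raise RegistrationError("particle type requires a non-empty name")
        if not (self.mass > 0):
            raise RegistrationError(f"type {self.name!r}: mass must be positive")
        if self.radius < 0:
            raise RegistrationError(f"type {self.name!r}: radius must be non-negative")
        if self.dynamics not in DYNAMICS:
            raise RegistrationError(
                f"type {self.name!r}: dynamics must be one of {DYNAMICS}"
            )
        object.__setattr__(self, "species", tuple(self.species))
        if len(set(self.species)) != len(self.species):
            raise RegistrationError(f"type {self.name!r}: duplicate species names")


class Particle:
    """A discrete agent: position, velocity, force accumulator and state."""

    __slots__ = (
        "id",
        "type",
        "position",
        "velocity",
        "force",
        "state",
        "cluster_id",
        "mass_override",
        "radius_override",
        "frozen",
    )

    def __init__(self, pid: int, ptype: ParticleType, position, velocity=None):
        self.id = pid
        self.type = ptype
        self.position = np.asarray(position, dtype=float).copy()
        self.velocity = (
            np.zeros(3) if velocity is None else np.asarray(velocity, dtype=float).copy()
        )
        self.force = np.zeros(3)
        self.state = np.zeros(len(ptype.species))
        self.cluster_id: Optional[int] = None
        self.mass_override: Optional[float] = None
        self.radius_override: Optional[float] = None
        self.frozen = ptype.frozen_default

    @property
    def mass(self) -> float:
        return self.type.mass if self.mass_override is None else self.mass_override

    @mass.setter
    def mass(self, value: float):
        if not (value > 0):
            raise ValueError("mass must be positive")
        self.mass_override = float(value)

    @property
    def radius(self) -> float:
        return self.type.radius if self.radius_override is None else self.radius_override

    @radius.setter
    def radius(self, value: float):
        if value < 0:
            raise ValueError("radius must be non-negative")
        self.radius_override = float(value)

    def species_value(self, name: str) -> float:
        return float(self.state[self.type.species.index(name)])

    def set_species(self, name: str, value: float):
        self.state[self.type.species.index(name)] = value

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Particle {self.id} type={self.type.name} r={self.position}>"


@dataclass
class Cluster:
    """A particle grouping whose elements are particles or other clusters."""

    id: int
    member_particles: set = field(default_factory=set)
    member_clusters: set = field(default_factory=set)
    parent_id: Optional[int] = None


def wrap_position(position, velocity, dims, boundary):
    """Apply boundary conditions to one position/velocity pair.

    Periodic axes wrap the coordinate into ``[0, L)``; reflective axes mirror
    the coordinate about the violated wall and negate the normal velocity
    component.  Returns new ``(position, velocity)`` arrays.
    """
    pos = np.array(position, dtype=float)
    vel = np.array(velocity, dtype=float)
    for ax in range(3):
        L = dims[ax]
        if boundary[ax] == "periodic":
            pos[ax] = pos[ax] % L
            if pos[ax] >= L:  # guard against x % L == L from rounding
                pos[ax] = 0.0
        else:
            # Fold onto [0, 2L); landing in the upper half means an odd
            # number of reflections, which flips the normal velocity.
            y = pos[ax] % (2.0 * L)
            if y >= L:
                pos[ax] = 2.0 * L - y
                vel[ax] = -vel[ax]
            else:
                pos[ax] = y
            if pos[ax] >= L:
                pos[ax] = np.nextafter(L, 0.0)
    return pos, vel


class Universe:
    """Simulation domain, registries and the global clock.

    Parameters
    ----------
    dims:
        Box edge lengths; each axis spans ``[0, L)``.
    boundary:
        Either a single mode applied to all axes or a per-axis triple of
        ``"periodic"`` / ``"reflective"``.
    cutoff:
        Global implicit-interaction cutoff.  Under periodic boundaries the
        cutoff may not exceed half the smallest periodic edge, so that the
        minimum-image convention identifies a unique interacting image.
    dt:
        Integration time step.
    seed:
        Root seed; named child streams (``dpd``, ``noise``, ``events``,
        ``model``) are spawned deterministically from it.
    plane_axis:
        Optional axis index; forces and velocities along this axis are
        zeroed each step, confining motion to a plane (used by the
        two-dimensional multicellular models).
    species_substeps:
        Number of sub-intervals used to integrate species transport within
        each simulation step.
    """

    def __init__(
        self,
        dims=(10.0, 10.0, 10.0),
        boundary="periodic",
        cutoff=1.0,
        dt=0.01,
        seed=0,
        plane_axis: Optional[int] = None,
        species_substeps: int = 1,
    ):
        self.dims = np.asarray(dims, dtype=float)
        if self.dims.shape != (3,) or not np.all(self.dims > 0):
            raise ValueError("dims must be three positive lengths")
        if isinstance(boundary, str):
            boundary = (boundary,) * 3
        self.boundary = tuple(boundary)
        if len(self.boundary) != 3 or any(b not in BOUNDARIES for b in self.boundary):
            raise ValueError(f"boundary entries must be one of {BOUNDARIES}")
        if not (cutoff > 0):
            raise ValueError("cutoff must be positive")
        for ax in range(3):
            if self.boundary[ax] == "periodic" and cutoff > self.dims[ax] / 2.0:
                raise ValueError(
                    "cutoff may not exceed half the box edge on periodic axis "
                    f"{ax} (cutoff={cutoff}, L={self.dims[ax]})"
                )
        if not (dt > 0):
            raise ValueError("dt must be positive")
        if species_substeps < 1:
            raise ValueError("species_substeps must be >= 1")
        self.cutoff = float(cutoff)
        self.dt = float(dt)
        self.time = 0.0
        self.step_count = 0
        self.rng_seed = int(seed)
        self.plane_axis = plane_axis
        self.species_substeps = int(species_substeps)

        self.rng = {}
        children = np.random.SeedSequence(self.rng_seed).spawn(len(RNG_STREAMS))
        for name, ss in zip(RNG_STREAMS, children):
            self.rng[name] = np.random.Generator(np.random.PCG64(ss))

        self.types: dict[str, ParticleType] = {}
        self.particles: dict[int, Particle] = {}
        self.clusters: dict[int, Cluster] = {}
        self.bonds: dict[int, object] = {}
        self.angles: dict[int, object] = {}
        self.dihedrals: dict[int, object] = {}
        self.bindings = BindingTable()
        self.flux_rules: list = []
        self.reactions: dict[str, list] = {}
        self.events: dict[int, object] = {}

        self._next_particle_id = 0
        self._next_cluster_id = 0
        self._next_bonded_id = 0
        self._next_event_id = 0
        self.species_clamp_count = 0
        self.last_potential_energy = 0.0
        self._pair_cache = None

    # ------------------------------------------------------------------ types
    def register_type(self, spec=None, /, **kwargs) -> ParticleType:
        """Register a particle type (from a spec or keyword fields)."""
        if spec is None:
            spec = ParticleType(**kwargs)
        if spec.name in self.types:
            raise RegistrationError(f"type {spec.name!r} already registered")
        self.types[spec.name] = spec
        return spec

    def type_index(self, name: str) -> int:
        return list(self.types).index(name)

    def _resolve_type(self, ptype) -> ParticleType:
        if isinstance(ptype, ParticleType):
            if self.types.get(ptype.name) is not ptype:
                raise RegistrationError(
                    f"type {ptype.name!r} is not registered with this universe"
                )
            return ptype
        if ptype not in self.types:
            raise RegistrationError(f"unknown particle type {ptype!r}")
        return self.types[ptype]

    # -------------------------------------------------------------- particles
    def create_particle(
        self, ptype, position, velocity=None, cluster=None, frozen=None
    ) -> Particle:
        spec = self._resolve_type(ptype)
        position = np.asarray(position, dtype=float)
        if position.shape != (3,) or not np.all(np.isfinite(position)):
            raise ValueError(f"position must be a finite 3-vector, got {position}")
        if velocity is not None:
            velocity = np.asarray(velocity, dtype=float)
            if velocity.shape != (3,) or not np.all(np.isfinite(velocity)):
                raise ValueError("velocity must be a finite 3-vector")
        pid = self._next_particle_id
        self._next_particle_id += 1
        p = Particle(pid, spec, position, velocity)
        p.position, p.velocity = wrap_position(
            p.position, p.velocity, self.dims, self.boundary
        )
        if frozen is not None:
            p.frozen = bool(frozen)
        self.particles[pid] = p
        if cluster is not None:
            self.add_to_cluster(cluster, pid)
        return p

    def destroy_particle(self, pid: int):
        """Remove a particle, its cluster membership, and every bonded item
        referencing it.  Ids are never reused."""
        if pid not in self.particles:
            raise KeyError(f"unknown particle id {pid}")
        p = self.particles.pop(pid)
        if p.cluster_id is not None and p.cluster_id in self.clusters:
            self.clusters[p.cluster_id].member_particles.discard(pid)
        for registry in (self.bonds, self.angles, self.dihedrals):
            doomed = [bid for bid, b in registry.items() if pid in b.particle_ids()]
            for bid in doomed:
                del registry[bid]

    # --------------------------------------------------------------- clusters
    def create_cluster(self, members: Iterable[int] = (), parent=None) -> Cluster:
        cid = self._next_cluster_id
        self._next_cluster_id += 1
        c = Cluster(cid)
        self.clusters[cid] = c
        if parent is not None:
            self.add_subcluster(parent, cid)
        for pid in members:
            self.add_to_cluster(cid, pid)
        return c

    def add_to_cluster(self, cid: int, pid: int):
        if cid not in self.clusters:
            raise KeyError(f"unknown cluster id {cid}")
        if pid not in self.particles:
            raise KeyError(f"unknown particle id {pid}")
        p = self.particles[pid]
        if p.cluster_id is not None and p.cluster_id != cid:
            self.clusters[p.cluster_id].member_particles.discard(pid)
        p.cluster_id = cid
        self.clusters[cid].member_particles.add(pid)

    def add_subcluster(self, parent_cid: int, child_cid: int):
        if parent_cid not in self.clusters or child_cid not in self.clusters:
            raise KeyError("unknown cluster id")
        # acyclicity: walking up from the parent must never reach the child
        seen = set()
        cur = parent_cid
        while cur is not None:
            if cur == child_cid:
                raise ValueError("cluster membership would create a cycle")
            if cur in seen:
                raise ValueError("corrupt cluster hierarchy")
            seen.add(cur)
            cur = self.clusters[cur].parent_id
        child = self.clusters[child_cid]
        if child.parent_id is not None:
            self.clusters[child.parent_id].member_clusters.discard(child_cid)
        child.parent_id = parent_cid
        self.clusters[parent_cid].member_clusters.add(child_cid)

    def top_cluster_of(self, pid: int) -> Optional[int]:
        """Top-level cluster id for a particle (None if unclustered)."""
        p = self.particles[pid]
        cid = p.cluster_id
        if cid is None:
            return None
        while self.clusters[cid].parent_id is not None:
            cid = self.clusters[cid].parent_id
        return cid

    # ---------------------------------------------------------------- spatial
    def minimum_image(self, dr):
        """Minimum-image displacement for periodic axes (vectorized)."""
        dr = np.asarray(dr, dtype=float)
        out = dr.copy()
        for ax in range(3):
            if self.boundary[ax] == "periodic":
                L = self.dims[ax]
                out[..., ax] -= L * np.round(out[..., ax] / L)
        return out

    def displacement(self, ri, rj):
        """Minimum-image vector ``r_i - r_j``."""
        return self.minimum_image(np.asarray(ri, float) - np.asarray(rj, float))

    def distance(self, ri, rj) -> float:
        return float(np.linalg.norm(self.displacement(ri, rj)))

    def neighbor_query(self, particle, distance: float):
        """All particles whose minimum-image distance to ``particle`` is
        ``<= distance``, excluding the particle itself (ordered by id)."""
        if isinstance(particle, Particle):
            p = particle
        else:
            p = self.particles[particle]
        others = [q for q in self.particles.values() if q.id != p.id]
        if not others:
            return []
        pos = np.array([q.position for q in others])
        dr = self.minimum_image(pos - p.position)
        dist = np.linalg.norm(dr, axis=1)
        hits = [q for q, d in zip(others, dist) if d <= distance]
        hits.sort(key=lambda q: q.id)
        return hits

    # --------------------------------------------------------------- bindings
    def bind_potential(self, potential, type_a, type_b, mode="all"):
        a = self._resolve_type(type_a).name
        b = self._resolve_type(type_b).name
        self.bindings.bind_implicit(a, b, potential, mode)

    def bind_dpd(self, params, type_a, type_b):
        a = self._resolve_type(type_a).name
        b = self._resolve_type(type_b).name
        self.bindings.bind_dpd(a, b, params)

    def bind_force(self, force, ptype):
        name = self._resolve_type(ptype).name
        self.bindings.bind_explicit(name, force)

    # ----------------------------------------------------------------- bonded
    def _new_bonded_id(self) -> int:
        bid = self._next_bonded_id
        self._next_bonded_id += 1
        return bid

    def create_bond(self, potential, i, j, dissociation_energy=None):
        from .bonded import Bond

        b = Bond(self._new_bonded_id(), int(i), int(j), potential, dissociation_energy)
        for pid in b.particle_ids():
            if pid not in self.particles:
                raise KeyError(f"unknown particle id {pid}")
        self.bonds[b.id] = b
        return b

    def create_angle(self, potential, i, j, k, dissociation_energy=None):
        from .bonded import Angle

        a = Angle(
            self._new_bonded_id(), int(i), int(j), int(k), potential, dissociation_energy
        )
        for pid in a.particle_ids():
            if pid not in self.particles:
                raise KeyError(f"unknown particle id {pid}")
        self.angles[a.id] = a
        return a

    def create_dihedral(self, potential, i, j, k, l, dissociation_energy=None):
        from .bonded import Dihedral

        d = Dihedral(
            self._new_bonded_id(),
            int(i),
            int(j),
            int(k),
            int(l),
            potential,
            dissociation_energy,
        )
        for pid in d.particle_ids():
            if pid not in self.particles:
                raise KeyError(f"unknown particle id {pid}")
        self.dihedrals[d.id] = d
        return d

    # ---------------------------------------------------------------- species
    def add_flux(self, kind, species, type_a, type_b, k, cutoff, direction=None):
        from .species import FluxRule

        rule = FluxRule(
            kind=kind,
            species=species,
            type_a=self._resolve_type(type_a).name,
            type_b=self._resolve_type(type_b).name,
            k=k,
            cutoff=cutoff,
            direction=direction,
        )
        for tname in (rule.type_a, rule.type_b):
            if species not in self.types[tname].species:
                raise RegistrationError(
                    f"type {tname!r} does not declare species {species!r}"
                )
        if rule.cutoff > self.cutoff:
            raise RegistrationError(
                f"flux cutoff {rule.cutoff} exceeds universe cutoff {self.cutoff}"
            )
        self.flux_rules.append(rule)
        return rule

    def add_reaction(self, ptype, callback, name=None):
        tname = self._resolve_type(ptype).name
        self.reactions.setdefault(tname, []).append((name, callback))

    # ----------------------------------------------------------------- events
    def on_event(self, callback, period_steps=1, name=None):
        from .events import EventSpec

        handle = self._next_event_id
        self._next_event_id += 1
        self.events[handle] = EventSpec(
            id=handle, period_steps=int(period_steps), callback=callback, name=name
        )
        return handle

    def remove_event(self, handle: int):
        if handle not in self.events:
            raise KeyError(f"unknown event handle {handle}")
        del self.events[handle]

    # ------------------------------------------------------------ integration
    def step(self, n: int = 1) -> bool:
        """Advance ``n`` steps.  Returns False if an event requested a stop."""
        from .engine import step as engine_step

        for _ in range(n):
            if not engine_step(self):
                return False
        return True

    def total_energy(self):
        from .engine import total_energy as engine_energy

        return engine_energy(self)

    # -------------------------------------------------------------- utilities
    def particles_of_type(self, ptype) -> list:
        name = self._resolve_type(ptype).name
        return [p for p in self.particles.values() if p.type.name == name]

    def __len__(self):
        return len(self.particles)
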