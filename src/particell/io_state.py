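"""JSON serialization of complete simulation state, plus trajectory output.

The state document is human-readable JSON with stable, sorted keys and
full-precision (round-trippable) numbers.  It captures everything needed to
continue a run bitwise-identically: the universe header, the states of all
named random streams, the type table, particle records, clusters, bonded
tables, binding table, flux rules, reactions and events.

Code is not serialized.  Custom potentials, custom forces, reactions and
event callbacks are referenced by a registered name: importing a document
that mentions a name requires the same name to be registered (typically by
importing the model module that defines it) in the current process.
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Callable

import numpy as np

from .core import Cluster, Particle, ParticleType, Universe
from .forces import force_from_dict
from .potentials import DPDParams, potential_from_dict

SCHEMA_VERSION = 1

_SECTIONS = (
    "universe",
    "rng",
    "types",
    "particles",
    "clusters",
    "bonds",
    "angles",
    "dihedrals",
    "bindings",
    "flux_rules",
    "reactions",
    "events",
)


class StateError(ValueError):
    """Malformed, incomplete or unresolvable state document."""


# ------------------------------------------------------------------ registry
_CALLBACKS: dict[tuple, Callable] = {}


def register_callback(namespace: str, name: str, fn: Callable):
    """Register a callback under ``(namespace, name)`` for serialization.

    Namespaces in use: ``potential``, ``force``, ``reaction``, ``event``.
    Re-registering the same name replaces the previous entry.
    """
    _CALLBACKS[(namespace, name)] = fn
    return fn


def resolve_callback(namespace: str, name: str) -> Callable:
    try:
        return _CALLBACKS[(namespace, name)]
    except KeyError:
        raise StateError(
            f"cannot resolve {namespace} callback {name!r}: register it with "
            f"register_callback({namespace!r}, {name!r}, fn) before importing"
        ) from None


def callback(namespace: str, name: str):
    """Decorator form of :func:`register_callback`."""

    def deco(fn):
        return register_callback(namespace, name, fn)

    return deco


# ----------------------------------------------------------------- utilities
def _vec(x):
    return [float(v) for v in np.asarray(x).ravel()]


def _rng_state(gen: np.random.Generator) -> dict:
    state = gen.bit_generator.state
    return json.loads(json.dumps(state))  # plain JSON types


# ------------------------------------------------------------------- export
def to_json(universe: Universe, indent: int = 1) -> str:
    """Serialize the complete universe state to a JSON string.

    May be called between steps only (never from inside an event that is
    still mutating state for the current step).
    """
    doc = {"schema_version": SCHEMA_VERSION}
    doc["universe"] = {
        "dims": _vec(universe.dims),
        "boundary": list(universe.boundary),
        "cutoff": universe.cutoff,
        "dt": universe.dt,
        "time": universe.time,
        "step_count": universe.step_count,
        "seed": universe.rng_seed,
        "plane_axis": universe.plane_axis,
        "species_substeps": universe.species_substeps,
        "next_particle_id": universe._next_particle_id,
        "next_cluster_id": universe._next_cluster_id,
        "next_bonded_id": universe._next_bonded_id,
        "next_event_id": universe._next_event_id,
        "species_clamp_count": universe.species_clamp_count,
    }
    doc["rng"] = {name: _rng_state(gen) for name, gen in universe.rng.items()}
    doc["types"] = [
        {
            "name": t.name,
            "mass": t.mass,
            "radius": t.radius,
            "dynamics": t.dynamics,
            "species": list(t.species),
            "frozen_default": t.frozen_default,
        }
        for t in universe.types.values()
    ]
    particles = []
    for p in universe.particles.values():
        rec = {
            "id": p.id,
            "type": p.type.name,
            "position": _vec(p.position),
            "velocity": _vec(p.velocity),
            "state": _vec(p.state),
            "frozen": p.frozen,
        }
        if p.cluster_id is not None:
            rec["cluster"] = p.cluster_id
        if p.mass_override is not None:
            rec["mass"] = p.mass_override
        if p.radius_override is not None:
            rec["radius"] = p.radius_override
        particles.append(rec)
    doc["particles"] = particles
    doc["clusters"] = [
        {
            "id": c.id,
            "particles": sorted(c.member_particles),
            "clusters": sorted(c.member_clusters),
            "parent": c.parent_id,
        }
        for c in universe.clusters.values()
    ]
    for section, registry in (
        ("bonds", universe.bonds),
        ("angles", universe.angles),
        ("dihedrals", universe.dihedrals),
    ):
        doc[section] = [
            {
                "id": b.id,
                "particles": list(b.particle_ids()),
                "potential": b.potential.to_dict(),
                "dissociation_energy": b.dissociation_energy,
            }
            for b in registry.values()
        ]
    doc["bindings"] = {
        "implicit": [
            {"types": [a, b], "mode": mode, "potential": pot.to_dict()}
            for (a, b, mode), pots in universe.bindings.implicit.items()
            for pot in pots
        ],
        "dpd": [
            {"types": [a, b], **params.to_dict()}
            for (a, b), plist in universe.bindings.dpd.items()
            for params in plist
        ],
        "explicit": [
            {"type": tname, "force": force.to_dict()}
            for tname, forces in universe.bindings.explicit.items()
            for force in forces
        ],
    }
    doc["flux_rules"] = [rule.to_dict() for rule in universe.flux_rules]
    reactions = []
    for tname, rxns in universe.reactions.items():
        for name, _fn in rxns:
            if name is None:
                raise StateError(
                    f"a reaction on type {tname!r} has no registered name and "
                    "cannot be serialized"
                )
            reactions.append({"type": tname, "name": name})
    doc["reactions"] = reactions
    events = []
    for handle, ev in universe.events.items():
        if ev.name is None:
            raise StateError(
                f"event {handle} has no registered name and cannot be serialized; "
                "remove it or register its callback under a name"
            )
        events.append({"id": handle, "name": ev.name, "period_steps": ev.period_steps})
    doc["events"] = events
    return json.dumps(doc, indent=indent, sort_keys=True)


# ------------------------------------------------------------------- import
def _require(doc: dict, section: str):
    if section not in doc:
        raise StateError(f"state document is missing section {section!r}")
    return doc[section]


def validate_state(doc: dict):
    """Check the document structure against the shipped schema's requirements."""
    if not isinstance(doc, dict):
        raise StateError("state document must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise StateError(
            f"unsupported schema_version {version!r}; this build reads version "
            f"{SCHEMA_VERSION}"
        )
    schema = load_schema()
    for section in schema.get("required", _SECTIONS):
        if section == "schema_version":
            continue
        _require(doc, section)
    header = doc["universe"]
    for key in (
        "dims",
        "boundary",
        "cutoff",
        "dt",
        "time",
        "step_count",
        "seed",
    ):
        if key not in header:
            raise StateError(f"universe header is missing field {key!r}")


def load_schema() -> dict:
    with resources.files("particell").joinpath("state_schema.json").open() as fh:
        return json.load(fh)


def from_json(text: str) -> Universe:
    """Rebuild a universe from a state document produced by :func:`to_json`."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StateError(f"malformed JSON state document: {exc}") from None
    validate_state(doc)
    header = doc["universe"]
    u = Universe(
        dims=header["dims"],
        boundary=header["boundary"],
        cutoff=header["cutoff"],
        dt=header["dt"],
        seed=header["seed"],
        plane_axis=header.get("plane_axis"),
        species_substeps=header.get("species_substeps", 1),
    )
    for trec in doc["types"]:
        u.register_type(
            ParticleType(
                name=trec["name"],
                mass=trec["mass"],
                radius=trec["radius"],
                dynamics=trec["dynamics"],
                species=tuple(trec["species"]),
                frozen_default=trec["frozen_default"],
            )
        )
    for prec in doc["particles"]:
        if prec["type"] not in u.types:
            raise StateError(
                f"particle {prec['id']} references unknown type {prec['type']!r}"
            )
        p = Particle(prec["id"], u.types[prec["type"]], prec["position"], prec["velocity"])
        p.state = np.asarray(prec["state"], dtype=float)
        if len(p.state) != len(p.type.species):
            raise StateError(
                f"particle {prec['id']}: state length {len(p.state)} does not "
                f"match the {len(p.type.species)} species of type {prec['type']!r}"
            )
        p.frozen = bool(prec["frozen"])
        if "mass" in prec:
            p.mass_override = float(prec["mass"])
        if "radius" in prec:
            p.radius_override = float(prec["radius"])
        u.particles[p.id] = p
    for crec in doc["clusters"]:
        c = Cluster(crec["id"])
        u.clusters[c.id] = c
    for crec in doc["clusters"]:
        c = u.clusters[crec["id"]]
        c.parent_id = crec["parent"]
        for pid in crec["particles"]:
            if pid not in u.particles:
                raise StateError(f"cluster {c.id} references unknown particle {pid}")
            c.member_particles.add(pid)
            u.particles[pid].cluster_id = c.id
        for cid in crec["clusters"]:
            if cid not in u.clusters:
                raise StateError(f"cluster {c.id} references unknown cluster {cid}")
            c.member_clusters.add(cid)
    creators = {
        "bonds": u.create_bond,
        "angles": u.create_angle,
        "dihedrals": u.create_dihedral,
    }
    for section, create in creators.items():
        for brec in doc[section]:
            pot = potential_from_dict(brec["potential"])
            try:
                item = create(
                    pot, *brec["particles"], dissociation_energy=brec["dissociation_energy"]
                )
            except KeyError as exc:
                raise StateError(
                    f"{section[:-1]} {brec['id']} references a missing particle: {exc}"
                ) from None
            # preserve the original bonded id
            registry = getattr(u, section)
            del registry[item.id]
            item.id = brec["id"]
            registry[item.id] = item
    binding = doc["bindings"]
    for rec in binding.get("implicit", []):
        a, b = rec["types"]
        u.bind_potential(potential_from_dict(rec["potential"]), a, b, rec["mode"])
    for rec in binding.get("dpd", []):
        a, b = rec["types"]
        params = {k: v for k, v in rec.items() if k != "types"}
        u.bind_dpd(DPDParams(**params), a, b)
    for rec in binding.get("explicit", []):
        u.bind_force(force_from_dict(rec["force"]), rec["type"])
    for rec in doc["flux_rules"]:
        a, b = rec["types"]
        u.add_flux(
            rec["kind"],
            rec["species"],
            a,
            b,
            rec["k"],
            rec["cutoff"],
            direction=rec.get("direction"),
        )
    for rec in doc["reactions"]:
        fn = resolve_callback("reaction", rec["name"])
        u.add_reaction(rec["type"], fn, name=rec["name"])
    for rec in doc["events"]:
        fn = resolve_callback("event", rec["name"])
        handle = u.on_event(fn, period_steps=rec["period_steps"], name=rec["name"])
        if handle != rec["id"]:
            ev = u.events.pop(handle)
            ev.id = rec["id"]
            u.events[rec["id"]] = ev
    u.time = header["time"]
    u.step_count = header["step_count"]
    u._next_particle_id = header.get(
        "next_particle_id", (max(u.particles) + 1) if u.particles else 0
    )
    u._next_cluster_id = header.get(
        "next_cluster_id", (max(u.clusters) + 1) if u.clusters else 0
    )
    bonded_ids = [*u.bonds, *u.angles, *u.dihedrals]
    u._next_bonded_id = header.get(
        "next_bonded_id", (max(bonded_ids) + 1) if bonded_ids else 0
    )
    u._next_event_id = header.get(
        "next_event_id", (max(u.events) + 1) if u.events else 0
    )
    u.species_clamp_count = header.get("species_clamp_count", 0)
    for name, state in doc["rng"].items():
        if name in u.rng:
            u.rng[name].bit_generator.state = state
    return u


def save_state(universe: Universe, path):
    with open(path, "w") as fh:
        fh.write(to_json(universe))


def load_state(path) -> Universe:
    with open(path) as fh:
        return from_json(fh.read())


# ------------------------------------------------------------- trajectories
def write_xyz_frame(fh, universe: Universe, comment: str = ""):
    """Append one XYZ frame (type name as the element column)."""
    fh.write(f"{len(universe.particles)}\n")
    fh.write(f"{comment or f'step={universe.step_count} time={universe.time:.6g}'}\n")
    for p in universe.particles.values():
        x, y, z = p.position
        fh.write(f"{p.type.name} {x:.9g} {y:.9g} {z:.9g}\n")


def trajectory_columns(universe: Universe) -> list:
    names = []
    for t in universe.types.values():
        for s in t.species:
            if s not in names:
                names.append(s)
    return (
        ["step", "time", "id", "type", "x", "y", "z", "vx", "vy", "vz", "cluster"]
        + names
    )


def trajectory_rows(universe: Universe) -> list:
    cols = trajectory_columns(universe)
    species_names = cols[11:]
    rows = []
    for p in universe.particles.values():
        row = [
            universe.step_count,
            universe.time,
            p.id,
            p.type.name,
            *(float(v) for v in p.position),
            *(float(v) for v in p.velocity),
            p.cluster_id if p.cluster_id is not None else "",
        ]
        for s in species_names:
            row.append(p.species_value(s) if s in p.type.species else "")
        rows.append(row)
    return rows
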