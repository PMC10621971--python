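"""Declarative simulation configuration.

A config file (YAML or JSON) describes a complete model: the universe
header, particle types, named potentials, type-pair bindings, explicit
forces, particles (or a named built-in fixture), bonded items, flux rules
and named events.  :func:`build_from_config` turns the document into a
ready-to-run :class:`~particell.core.Universe`.

Example::

    universe: {dims: [10, 10, 10], boundary: reflective, cutoff: 3, dt: 0.005, seed: 1}
    types:
      - {name: osc, mass: 1.0}
    potentials:
      spring: {kind: harmonic, k: 1.0, r0: 1.0, r_max: 3.0}
    bindings:
      - {potential: spring, types: [osc, osc]}
    particles:
      - {type: osc, position: [4.35, 5, 5]}
      - {type: osc, position: [5.65, 5, 5]}
    run: {steps: 1000, stride: 10}
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import Universe
from .forces import force_from_dict
from .io_state import resolve_callback
from .potentials import DPDParams, potential_from_dict


class ConfigError(ValueError):
    """Invalid configuration document."""


# Built-in named events attachable from config files.
def _print_status(universe, time):
    print(
        f"step={universe.step_count + 1} time={time:.6g} "
        f"particles={len(universe.particles)}"
    )


def _census_particle_counts(universe, time):
    counts = {name: len(universe.particles_of_type(name)) for name in universe.types}
    print(f"time={time:.6g} counts={counts}")


from .io_state import register_callback as _register

_register("event", "print_status", _print_status)
_register("event", "census_particle_counts", _census_particle_counts)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return doc


def _build_potential(name, spec, named):
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError(f"potential {name!r}: must be a mapping with a 'kind'")
    if spec["kind"] == "sum":
        try:
            a_name, b_name = spec["of"]
        except (KeyError, ValueError):
            raise ConfigError(
                f"potential {name!r}: sum requires 'of: [nameA, nameB]'"
            ) from None
        missing = [n for n in (a_name, b_name) if n not in named]
        if missing:
            raise ConfigError(f"potential {name!r}: unknown constituent {missing[0]!r}")
        return named[a_name] + named[b_name]
    if spec["kind"] == "custom":
        fn = resolve_callback("potential", spec["name"])
        from .potentials import CustomPotential

        return CustomPotential(fn, spec.get("r_min", 0.0), spec["r_max"], name=spec["name"])
    try:
        return potential_from_dict(spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"potential {name!r}: {exc}") from None


def build_from_config(doc: dict, seed=None) -> Universe:
    """Build a universe from a parsed config document.

    ``seed`` overrides the seed in the document (config fixtures receive it
    as their ``seed`` argument).
    """
    fixture = doc.get("fixture")
    if fixture is not None:
        from .models import FIXTURES

        name = fixture.get("name")
        if name not in FIXTURES:
            raise ConfigError(
                f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
            )
        params = dict(fixture.get("params", {}))
        if seed is not None:
            params["seed"] = seed
        return FIXTURES[name](**params)

    header = dict(doc.get("universe", {}))
    if seed is not None:
        header["seed"] = seed
    try:
        u = Universe(**header)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"universe: {exc}") from None

    for trec in doc.get("types", []):
        spec = dict(trec)
        if "species" in spec:
            spec["species"] = tuple(spec["species"])
        if "frozen" in spec:
            spec["frozen_default"] = spec.pop("frozen")
        try:
            u.register_type(**spec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"type {trec.get('name')!r}: {exc}") from None

    named = {}
    for name, spec in doc.get("potentials", {}).items():
        named[name] = _build_potential(name, spec, named)

    def lookup(name, where):
        if name not in named:
            raise ConfigError(f"{where}: unknown potential {name!r}")
        return named[name]

    for rec in doc.get("bindings", []):
        pot = lookup(rec["potential"], "bindings")
        a, b = rec["types"]
        u.bind_potential(pot, a, b, rec.get("mode", "all"))
    for rec in doc.get("dpd", []):
        a, b = rec["types"]
        params = {k: v for k, v in rec.items() if k != "types"}
        u.bind_dpd(DPDParams(**params), a, b)
    for rec in doc.get("forces", []):
        spec = {k: v for k, v in rec.items() if k != "type"}
        u.bind_force(force_from_dict(spec), rec["type"])

    for rec in doc.get("particles", []):
        count = int(rec.get("count", 1))
        rng = u.rng["model"]
        for _ in range(count):
            if "position" in rec:
                pos = rec["position"]
            else:
                region = rec.get("region")
                if region is None:
                    lo, hi = (0.0, 0.0, 0.0), tuple(u.dims)
                else:
                    lo, hi = region["low"], region["high"]
                pos = [rng.uniform(l, h) for l, h in zip(lo, hi)]
            p = u.create_particle(rec["type"], pos, velocity=rec.get("velocity"))
            for sname, val in rec.get("state", {}).items():
                p.set_species(sname, val)

    for section, creator in (
        ("bonds", u.create_bond),
        ("angles", u.create_angle),
        ("dihedrals", u.create_dihedral),
    ):
        for rec in doc.get(section, []):
            pot = lookup(rec["potential"], section)
            ids = rec["particles"]
            creator(pot, *ids, dissociation_energy=rec.get("dissociation_energy"))

    for rec in doc.get("flux", []):
        a, b = rec["types"]
        u.add_flux(
            rec.get("kind", "fick"),
            rec["species"],
            a,
            b,
            rec["k"],
            rec["cutoff"],
            direction=rec.get("direction"),
        )

    for rec in doc.get("events", []):
        fn = resolve_callback("event", rec["name"])
        u.on_event(fn, period_steps=rec.get("period_steps", 1), name=rec["name"])
    return u
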