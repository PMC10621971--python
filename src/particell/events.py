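"""Scheduled events: user instructions injected into the simulation loop.

An event fires during the Update stage, after integration, species update
and dissociation, at every step whose (1-based) completed-step count is a
multiple of its period.  Events due at the same step fire in registration
order.  Callbacks receive ``(universe, time)`` and may freely create or
destroy particles and bonds: mutations take effect before the next Force
stage.  A callback returning a truthy value stops the enclosing run loop.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional


@dataclass
class EventSpec:
    id: int
    period_steps: int
    callback: Callable
    name: Optional[str] = None

    def __post_init__(self):
        if self.period_steps < 1:
            raise ValueError("event period must be >= 1 step")


def register_event(universe, callback, period_steps: int = 1, name=None) -> int:
    """Register a callback; returns an opaque handle usable for removal."""
    return universe.on_event(callback, period_steps=period_steps, name=name)


def remove_event(universe, handle: int):
    universe.remove_event(handle)


def select_random_particle(universe, ptype, rng=None):
    """Uniformly random live particle of a type, or None if there is none.

    Draws from the universe's ``events`` random stream unless an explicit
    generator is supplied.
    """
    spec = universe._resolve_type(ptype)
    pool = universe.particles_of_type(spec)
    if not pool:
        return None
    rng = universe.rng["events"] if rng is None else rng
    return pool[int(rng.integers(len(pool)))]
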