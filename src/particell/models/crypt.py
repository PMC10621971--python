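"""Two-dimensional agent-based model of clonal dynamics in the colonic crypt.

The crypt is unfolded onto a planar sheet: the horizontal axis is periodic
(as if wrapped around the crypt cylinder) and the vertical axis runs from
the proliferative region toward the crypt base, which acts as a removal
boundary.  Each cell is an overdamped particle carrying a cell-cycle state
machine with four phases (G1, S, G2, M).  Phase durations are
deterministic except G1, which is drawn per cell from a normal
distribution truncated at zero.  Cycling happens only for cells inside the
proliferative zone; a cell completing M divides, placing a daughter at a
small random offset and copying its clone identification, and cells are
removed when they reach the base edge.

Because clone identifications are assigned once at t=0 and only ever
copied, the number of distinct clones among live cells can never increase;
neutral drift plus removal at the base drives the population toward
monoclonality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import Universe
from ..potentials import Morse

PHASES = ("G1", "S", "G2", "M")


@dataclass
class CellCycleState:
    phase: str = "G1"
    remaining: float = 0.0
    clone_id: int = 0
    g1_mean: float = 2.0
    g1_sd: float = 0.5
    s_dur: float = 1.0
    g2_dur: float = 1.0
    m_dur: float = 1.0

    def draw_g1(self, rng) -> float:
        return max(0.0, float(rng.normal(self.g1_mean, self.g1_sd)))

    def duration_of(self, phase: str, rng) -> float:
        if phase == "G1":
            return self.draw_g1(rng)
        return {"S": self.s_dur, "G2": self.g2_dur, "M": self.m_dur}[phase]


@dataclass
class CryptGeometry:
    """Unfolded crypt: periodic width, removal at the top (base) edge."""

    width: float = 20.0
    height: float = 10.0
    proliferative_frac: float = 2.0 / 3.0
    removal_margin: float = 0.5

    def in_proliferative_zone(self, y: float) -> bool:
        return y < self.proliferative_frac * self.height

    def past_base(self, y: float) -> bool:
        return y >= self.height - self.removal_margin


def crypt_step_rule(state: CellCycleState, y: float, dt: float, geometry, rng):
    """Advance one cell by ``dt``; returns actions from {advance, divide, remove}.

    The phase clock runs only inside the proliferative zone.  Completing M
    emits ``divide`` and re-enters G1 with a freshly drawn duration (the
    daughter's state is constructed by the caller, inheriting the parent's
    clone id).  Crossing the base boundary emits ``remove``.
    """
    if geometry.past_base(y):
        return ["remove"]
    actions = []
    if geometry.in_proliferative_zone(y):
        state.remaining -= dt
        while state.remaining <= 0.0:
            idx = PHASES.index(state.phase)
            nxt = PHASES[(idx + 1) % len(PHASES)]
            if state.phase == "M":
                actions.append("divide")
            state.phase = nxt
            state.remaining += state.duration_of(nxt, rng)
            actions.append("advance")
    return actions


def count_clones(states) -> int:
    """Number of distinct clone identifications among live cells."""
    if isinstance(states, dict):
        states = states.values()
    return len({s.clone_id for s in states})


class CryptModel:
    """Owns per-cell cycle state and applies the agent rule each step."""

    def __init__(self, universe: Universe, geometry: CryptGeometry, daughter_offset=0.1):
        self.universe = universe
        self.geometry = geometry
        self.daughter_offset = daughter_offset
        self.states: dict[int, CellCycleState] = {}
        self.rng = universe.rng["model"]
        universe.on_event(self._apply_rule, period_steps=1)

    def add_cell(self, position, clone_id, fresh_phase=True) -> int:
        p = self.universe.create_particle("cell", position)
        st = CellCycleState(clone_id=clone_id)
        if fresh_phase:
            # desynchronize the initial population across the whole cycle
            st.phase = PHASES[int(self.rng.integers(len(PHASES)))]
            st.remaining = self.rng.uniform(0.0, st.duration_of(st.phase, self.rng) + 1e-9)
        else:
            st.remaining = st.draw_g1(self.rng)
        self.states[p.id] = st
        return p.id

    def _apply_rule(self, universe, time):
        g = self.geometry
        for pid in list(self.states):
            p = universe.particles.get(pid)
            if p is None:
                continue
            actions = crypt_step_rule(self.states[pid], float(p.position[1]), universe.dt, g, self.rng)
            for act in actions:
                if act == "remove":
                    universe.destroy_particle(pid)
                    del self.states[pid]
                    break
                if act == "divide":
                    theta = self.rng.uniform(0.0, 2.0 * math.pi)
                    offset = self.daughter_offset * np.array(
                        [math.cos(theta), math.sin(theta), 0.0]
                    )
                    daughter = universe.create_particle("cell", p.position + offset)
                    dstate = CellCycleState(clone_id=self.states[pid].clone_id)
                    dstate.remaining = dstate.draw_g1(self.rng)
                    self.states[daughter.id] = dstate

    def census(self) -> dict:
        return {
            "time": self.universe.time,
            "n_cells": len(self.states),
            "n_clones": count_clones(self.states),
        }


#: Cell-cell mechanics: Morse adhesion with stiff enough short-range
#: repulsion to keep the sheet near one cell per unit area.
CRYPT_MORSE = {"d": 0.08, "a": 5.0, "r0": 1.0}
CRYPT_CUTOFF = 1.75


def build_crypt(
    n_columns=20,
    n_rows=10,
    geometry=None,
    dt=0.05,
    seed=0,
    daughter_offset=0.1,
    **_,
):
    """Initial crypt sheet: ``n_columns x n_rows`` cells, one clone each."""
    geometry = geometry or CryptGeometry(width=float(n_columns), height=float(n_rows))
    u = Universe(
        dims=(geometry.width, geometry.height + 0.5, 1.0),
        boundary=("periodic", "reflective", "reflective"),
        cutoff=CRYPT_CUTOFF,
        dt=dt,
        seed=seed,
        plane_axis=2,
    )
    u.register_type(name="cell", mass=1.0, dynamics="overdamped")
    pot = Morse(
        CRYPT_MORSE["d"], CRYPT_MORSE["a"], CRYPT_MORSE["r0"], r_min=0.7, r_max=CRYPT_CUTOFF
    )
    u.bind_potential(pot, "cell", "cell")
    model = CryptModel(u, geometry, daughter_offset=daughter_offset)
    clone = 0
    for i in range(n_columns):
        for j in range(n_rows):
            model.add_cell((i + 0.5, j + 0.5, 0.5), clone_id=clone)
            clone += 1
    return u, model


def run_crypt_replicate(
    seed=0,
    t_end=1100.0,
    census_every=1.0,
    n_columns=20,
    n_rows=10,
    stop_at_clones=1,
    **kwargs,
) -> pd.DataFrame:
    """One replicate; returns censuses of population size and clone count.

    Stops early once the clone count reaches ``stop_at_clones`` (clone
    counts can only fall, so nothing after that point changes the
    monoclonality analysis).
    """
    u, model = build_crypt(n_columns=n_columns, n_rows=n_rows, seed=seed, **kwargs)
    rows = [model.census()]
    stride = max(1, int(round(census_every / u.dt)))
    n_steps = int(round(t_end / u.dt))
    for s in range(1, n_steps + 1):
        u.step()
        if s % stride == 0:
            rows.append(model.census())
            if rows[-1]["n_clones"] <= stop_at_clones:
                break
    return pd.DataFrame(rows)
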