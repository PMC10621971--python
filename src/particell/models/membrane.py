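"""Active pumping of a species across a deformable membrane.

Two fluid-filled compartments of transport-DPD particles are separated by
a bonded elastic membrane sheet (periodic in-plane).  Every fluid particle
carries a solute amount that diffuses within its compartment by Fickian
flux.  A channel particle embedded in the membrane actively pumps solute:
it withdraws from nearby lower-compartment particles and releases to
nearby upper-compartment particles, creating and maintaining a
concentration discontinuity across the membrane.  Both pump transfers are
conservative, so the total solute amount over all particles is constant.
"""
from __future__ import annotations

import numpy as np

from ..core import Universe
from ..potentials import DPDParams, Harmonic


def build_membrane_pump(
    nx=6,
    ny=6,
    fluid_per_compartment=72,
    pump_rate=5.0,
    initial_lower=1.0,
    initial_upper=0.0,
    dt=0.01,
    seed=0,
    **_,
) -> Universe:
    """Membrane sheet at mid-height; fluids above and below; one channel."""
    H = 12.0
    u = Universe(
        dims=(float(nx), float(ny), H),
        boundary=("periodic", "periodic", "reflective"),
        cutoff=1.5,
        dt=dt,
        seed=seed,
    )
    species = ("solute",)
    u.register_type(name="fluid_lo", mass=1.0, species=species)
    u.register_type(name="fluid_up", mass=1.0, species=species)
    u.register_type(name="membrane", mass=2.0)
    u.register_type(name="channel", mass=2.0, species=species, frozen_default=True)

    fluid = DPDParams(alpha=15.0, gamma=4.5, sigma=3.0, rc=1.0)
    wall = DPDParams(alpha=25.0, gamma=4.5, sigma=0.0, rc=1.0)
    for a in ("fluid_lo", "fluid_up"):
        for b in ("fluid_lo", "fluid_up"):
            if a <= b:
                u.bind_dpd(fluid, a, b)
        for b in ("membrane", "channel"):
            u.bind_dpd(wall, a, b)

    # membrane: square sheet bonded to 4-neighbors with periodic wrap
    z_mid = H / 2.0
    mem_ids = np.zeros((nx, ny), dtype=np.int64)
    for i in range(nx):
        for j in range(ny):
            tname = "channel" if (i, j) == (nx // 2, ny // 2) else "membrane"
            p = u.create_particle(tname, (i + 0.5, j + 0.5, z_mid))
            mem_ids[i, j] = p.id
    bond = Harmonic(25.0, 1.0)
    for i in range(nx):
        for j in range(ny):
            u.create_bond(bond, int(mem_ids[i, j]), int(mem_ids[(i + 1) % nx, j]))
            u.create_bond(bond, int(mem_ids[i, j]), int(mem_ids[i, (j + 1) % ny]))

    rng = u.rng["model"]
    for tname, z_lo, z_hi, c0 in (
        ("fluid_lo", 0.8, z_mid - 0.8, initial_lower),
        ("fluid_up", z_mid + 0.8, H - 0.8, initial_upper),
    ):
        for _ in range(fluid_per_compartment):
            pos = [rng.uniform(0, nx), rng.uniform(0, ny), rng.uniform(z_lo, z_hi)]
            p = u.create_particle(tname, pos)
            p.set_species("solute", c0)

    # intra-compartment diffusion
    u.add_flux("fick", "solute", "fluid_lo", "fluid_lo", 1.0, 1.0)
    u.add_flux("fick", "solute", "fluid_up", "fluid_up", 1.0, 1.0)
    # active transport: lower fluid -> channel -> upper fluid
    if pump_rate > 0:
        u.add_flux(
            "pump", "solute", "fluid_lo", "channel", pump_rate, 1.5, direction="ab"
        )
        u.add_flux(
            "pump", "solute", "channel", "fluid_up", 2.0 * pump_rate, 1.5, direction="ab"
        )
    return u


def compartment_totals(universe: Universe) -> dict:
    """Total solute amount in each compartment, the channel, and overall."""
    totals = {"lower": 0.0, "upper": 0.0, "channel": 0.0}
    for p in universe.particles.values():
        if p.type.name == "fluid_lo":
            totals["lower"] += p.species_value("solute")
        elif p.type.name == "fluid_up":
            totals["upper"] += p.species_value("solute")
        elif p.type.name == "channel":
            totals["channel"] += p.species_value("solute")
    totals["both"] = totals["lower"] + totals["upper"] + totals["channel"]
    return totals
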