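"""Particle-attached chemical species: transport fluxes and reactions.

Each particle carries a state vector aligned with the species declared by
its type.  The state evolves as the sum of pairwise transport fluxes with
nearby particles and local intra-particle reactions,

    dC_i/dt = sum_j Q_ij + Q_i^reaction.

Two built-in flux laws are provided.

Fickian diffusion (antisymmetric, mass conserving)::

    Q_ij = k (C_j - C_i) (1 - r/r_cut)^2    for r <= r_cut, else 0

Active pumping (conservative transfer from a source to a target particle)::

    Q = k C_source (1 - r/r_cut)^2          for r <= r_cut, else 0

When particles sit on a regular grid with spacing ``h`` and the cutoff
excludes diagonal neighbors, choosing the flux constant from a diffusion
coefficient ``D`` as ``k = D / (h^2 (1 - h/r_cut)^2)`` makes the particle
update identical to the forward-time central-space (FTCS) finite-difference
discretization of the diffusion equation with coefficient ``D dt / h^2``.

Species are integrated in ``n`` sub-intervals of the simulation step to
tame the stiffness of fast diffusion; all updates within a sub-interval are
simultaneous (no sequential bias), and negative concentrations produced by
overshooting are clamped to zero with a counted warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

FLUX_KINDS = ("fick", "pump")


@dataclass(frozen=True)
class FluxRule:
    """Per-(species, type-pair) transport law.

    For ``kind='pump'``, ``direction`` names the source->target orientation:
    ``'ab'`` pumps from ``type_a`` particles into ``type_b`` particles,
    ``'ba'`` the reverse.
    """

    kind: str
    species: str
    type_a: str
    type_b: str
    k: float
    cutoff: float
    direction: Optional[str] = None

    def __post_init__(self):
        if self.kind not in FLUX_KINDS:
            raise ValueError(f"flux kind must be one of {FLUX_KINDS}")
        if self.k < 0:
            raise ValueError("flux constant must be non-negative")
        if self.cutoff <= 0:
            raise ValueError("flux cutoff must be positive")
        if self.kind == "pump":
            if self.direction not in ("ab", "ba"):
                raise ValueError("pump rule requires direction 'ab' or 'ba'")

    def to_dict(self):
        d = {
            "kind": self.kind,
            "species": self.species,
            "types": [self.type_a, self.type_b],
            "k": self.k,
            "cutoff": self.cutoff,
        }
        if self.direction is not None:
            d["direction"] = self.direction
        return d


def fickian_flux(k, c_i, c_j, r, r_cutoff):
    """Rate of change of the species on particle *i* due to Fickian exchange
    with particle *j*.  Antisymmetric under i <-> j; zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    w = np.where(r <= r_cutoff, (1.0 - r / r_cutoff) ** 2, 0.0)
    out = k * (np.asarray(c_j, float) - np.asarray(c_i, float)) * w
    return float(out) if np.ndim(out) == 0 else out


def flux_constant_from_diffusivity(D, r, r_cutoff):
    """Flux constant reproducing diffusion coefficient ``D`` at spacing ``r``.

    ``k = D / (r^2 (1 - r/r_cutoff)^2)``: with this ``k`` the Fickian flux
    equals ``D (C_j - C_i) / r^2`` exactly.
    """
    if not (0 < r < r_cutoff):
        raise ValueError("flux-diffusivity relation requires 0 < r < r_cutoff")
    return D / (r**2 * (1.0 - r / r_cutoff) ** 2)


def pump_flux(k, c_source, r, r_cutoff):
    """Transfer rate from the source to the target particle of a pump rule."""
    r = np.asarray(r, dtype=float)
    w = np.where(r <= r_cutoff, (1.0 - r / r_cutoff) ** 2, 0.0)
    out = k * np.asarray(c_source, float) * w
    return float(out) if np.ndim(out) == 0 else out


# --------------------------------------------------------------- integration
def _species_layout(universe):
    """Global species table: union of declared species in registration order,
    plus a per-type column map (-1 where a type does not declare a species)."""
    names = []
    for t in universe.types.values():
        for s in t.species:
            if s not in names:
                names.append(s)
    col = {s: c for c, s in enumerate(names)}
    type_map = {}
    for tname, t in universe.types.items():
        m = np.full(len(names), -1, dtype=np.int64)
        for local, s in enumerate(t.species):
            m[col[s]] = local
        type_map[tname] = m
    return names, col, type_map


def integrate_species(universe, pairs, arrays):
    """Integrate all state vectors over one simulation step.

    Fluxes use the pair geometry computed during the Force stage.  Each of
    the ``universe.species_substeps`` sub-intervals accumulates every
    pairwise flux and local reaction at the current concentrations and then
    applies a simultaneous forward-Euler update.
    """
    if not universe.flux_rules and not universe.reactions:
        return
    parts = arrays["particles"]
    n = len(parts)
    if n == 0:
        return
    names, col, type_map = _species_layout(universe)
    if not names:
        return
    S = len(names)
    C = np.zeros((n, S))
    for row, p in enumerate(parts):
        m = type_map[p.type.name]
        declared = m >= 0
        C[row, declared] = p.state[m[declared]]

    tc = arrays["type_code"]
    type_codes = arrays["type_codes"]
    # pre-select pairs and weights per rule (geometry is fixed within a step)
    plans = []
    for rule in universe.flux_rules:
        if not len(pairs):
            break
        ca, cb = type_codes[rule.type_a], type_codes[rule.type_b]
        ti, tj = tc[pairs.i], tc[pairs.j]
        if ca == cb:
            match = (ti == ca) & (tj == ca)
        else:
            match = ((ti == ca) & (tj == cb)) | ((ti == cb) & (tj == ca))
        sel = match & (pairs.r <= rule.cutoff)
        if not sel.any():
            continue
        i_rows = pairs.i[sel]
        j_rows = pairs.j[sel]
        w = (1.0 - pairs.r[sel] / rule.cutoff) ** 2
        if rule.kind == "pump":
            # orient each pair source -> target
            src_is_a = tc[i_rows] == ca if rule.direction == "ab" else tc[i_rows] == cb
            src = np.where(src_is_a, i_rows, j_rows)
            dst = np.where(src_is_a, j_rows, i_rows)
            plans.append(("pump", rule, src, dst, w))
        else:
            plans.append(("fick", rule, i_rows, j_rows, w))

    sub = universe.species_substeps
    dt_sub = universe.dt / sub
    clamped = 0
    for _ in range(sub):
        dC = np.zeros_like(C)
        for kind, rule, a_rows, b_rows, w in plans:
            s = col[rule.species]
            if kind == "fick":
                q = rule.k * (C[b_rows, s] - C[a_rows, s]) * w
                np.add.at(dC[:, s], a_rows, q)
                np.add.at(dC[:, s], b_rows, -q)
            else:
                q = rule.k * C[a_rows, s] * w
                amount = q * dt_sub
                # cap total withdrawal at the available amount so pumping
                # conserves mass and never drives a source negative
                want = np.zeros(n)
                np.add.at(want, a_rows, amount)
                over = want > C[:, s]
                if over.any():
                    scale_per = np.ones(n)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        scale_per[over] = np.where(
                            want[over] > 0, C[over, s] / want[over], 0.0
                        )
                    amount = amount * scale_per[a_rows]
                np.add.at(dC[:, s], a_rows, -amount / dt_sub)
                np.add.at(dC[:, s], b_rows, amount / dt_sub)
        # local reactions
        for tname, rxns in universe.reactions.items():
            code = type_codes[tname]
            rows = np.where(tc == code)[0]
            if len(rows) == 0:
                continue
            m = type_map[tname]
            declared = m >= 0
            for _, fn in rxns:
                for row in rows:
                    local = np.zeros(len(universe.types[tname].species))
                    local[m[declared]] = C[row, declared]
                    incr = np.asarray(fn(local, dt_sub), dtype=float)
                    if not np.all(np.isfinite(incr)):
                        pid = int(arrays["ids"][row])
                        raise ValueError(
                            f"reaction on particle {pid} returned a non-finite increment"
                        )
                    dC[row, declared] += incr[m[declared]] / dt_sub
        C += dt_sub * dC
        neg = C < 0
        if neg.any():
            clamped += int(neg.sum())
            C[neg] = 0.0
    if clamped:
        universe.species_clamp_count += clamped
        log.warning(
            "clamped %d negative species values to zero (total %d); consider "
            "more sub-intervals or a smaller flux constant",
            clamped,
            universe.species_clamp_count,
        )
    for row, p in enumerate(parts):
        m = type_map[p.type.name]
        declared = m >= 0
        p.state[m[declared]] = C[row, declared]
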