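"""The simulation loop: spatial decomposition, forces, integration.

Each step performs three stages:

- **Prep**: force accumulators and cached energies are reset.
- **Force**: space is decomposed into a regular grid of cells whose edge is
  at least the global cutoff; particles are sorted into cells (*Sort*);
  pair interactions are evaluated within each cell (*Force Self*) and
  between neighboring cells (*Force Pair*), together with bonded terms,
  explicit forces, and species transport fluxes.
- **Update**: particle trajectories are advanced by explicit first-order
  forward integration (velocity-first for Newtonian dynamics, plain
  forward Euler for overdamped), boundary conditions are applied, species
  states are integrated in sub-intervals, bonded items whose energy
  exceeds their dissociation threshold are destroyed, and scheduled events
  run last.

The engine is single-threaded but preserves the Sort -> Force Pair / Force
Self task decomposition as an internal contract; pair enumeration is exact
(it matches an all-pairs minimum-image scan) and pairs at exactly the
cutoff distance are excluded (strict ``<``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import EngineError, Universe

#: Half-space of neighbor-cell directions; together with the self cell these
#: enumerate every unordered cell pair exactly once on grids with >= 3 cells
#: per periodic axis.
FORWARD_OFFSETS = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class PairSet:
    """Candidate interaction pairs: row indices, displacement and distance."""

    i: np.ndarray
    j: np.ndarray
    dx: np.ndarray  # minimum-image r_i - r_j, shape (n_pairs, 3)
    r: np.ndarray

    def __len__(self):
        return len(self.r)


class CellGrid:
    """Regular decomposition of the domain into cells of edge >= cutoff."""

    def __init__(self, universe: Universe, positions: np.ndarray):
        dims = universe.dims
        cutoff = universe.cutoff
        for ax in range(3):
            if universe.boundary[ax] == "periodic" and cutoff > dims[ax]:
                raise EngineError("cutoff exceeds the box edge on a periodic axis")
        self.cell_counts = np.maximum(1, np.floor(dims / cutoff).astype(np.int64))
        self.cell_size = dims / self.cell_counts
        self.periodic = np.array(
            [b == "periodic" for b in universe.boundary], dtype=bool
        )
        self.positions = positions
        n = len(positions)
        if n:
            coords = np.floor(positions / self.cell_size).astype(np.int64)
            self.coords = np.clip(coords, 0, self.cell_counts - 1)
        else:
            self.coords = np.zeros((0, 3), dtype=np.int64)
        self.linear = (
            self.coords[:, 0] * (self.cell_counts[1] * self.cell_counts[2])
            + self.coords[:, 1] * self.cell_counts[2]
            + self.coords[:, 2]
        )
        # the Sort stage: particles ordered by containing cell (stable in row
        # order, i.e. in particle registration order)
        self.order = np.argsort(self.linear, kind="stable")
        self.sorted_linear = self.linear[self.order]

    def cell_of(self, row: int):
        return tuple(int(c) for c in self.coords[row])

    def rows_in_cell(self, cell) -> np.ndarray:
        lin = (
            cell[0] * (self.cell_counts[1] * self.cell_counts[2])
            + cell[1] * self.cell_counts[2]
            + cell[2]
        )
        lo = np.searchsorted(self.sorted_linear, lin, "left")
        hi = np.searchsorted(self.sorted_linear, lin, "right")
        return self.order[lo:hi]

    def occupied_cells(self):
        seen = np.unique(self.sorted_linear)
        nyz = self.cell_counts[1] * self.cell_counts[2]
        for lin in seen:
            x, rem = divmod(int(lin), int(nyz))
            y, z = divmod(rem, int(self.cell_counts[2]))
            yield (x, y, z)

    def neighbor_cell(self, cell, offset):
        """Wrapped neighbor cell and its periodic shift vector, or None."""
        nb = []
        shift = np.zeros(3)
        for ax in range(3):
            c = cell[ax] + offset[ax]
            if self.periodic[ax]:
                w = c // self.cell_counts[ax]
                c -= w * self.cell_counts[ax]
                shift[ax] = w * self.cell_size[ax] * self.cell_counts[ax]
            elif not (0 <= c < self.cell_counts[ax]):
                return None, None
            nb.append(int(c))
        return tuple(nb), shift

    def sort_cell(self, cell) -> dict:
        """Ordered projections for each neighbor direction (the Sort task).

        For every forward offset, the cell's particle rows sorted ascending
        by projection onto the offset direction; ties broken by row index.
        """
        rows = self.rows_in_cell(cell)
        out = {}
        for off in FORWARD_OFFSETS:
            axis = np.asarray(off, dtype=float)
            axis /= np.linalg.norm(axis)
            proj = self.positions[rows] @ axis
            order = np.lexsort((rows, proj))
            out[off] = rows[order]
        return out


def brute_force_pairs(universe: Universe, positions: np.ndarray, cutoff=None) -> PairSet:
    """All-pairs minimum-image scan (the O(N^2) oracle and the fallback path
    for grids too coarse for half-space enumeration)."""
    cutoff = universe.cutoff if cutoff is None else cutoff
    n = len(positions)
    if n < 2:
        return PairSet(*(np.zeros(0, dtype=np.int64),) * 2, np.zeros((0, 3)), np.zeros(0))
    iu, ju = np.triu_indices(n, k=1)
    dx = universe.minimum_image(positions[iu] - positions[ju])
    r = np.linalg.norm(dx, axis=1)
    keep = (r < cutoff) & (r > 0)
    return PairSet(iu[keep], ju[keep], dx[keep], r[keep])


def candidate_pairs(universe: Universe, grid: CellGrid) -> PairSet:
    """Exact in-cutoff pair enumeration from the cell decomposition."""
    pos = grid.positions
    n = len(pos)
    if n < 2:
        return PairSet(*(np.zeros(0, dtype=np.int64),) * 2, np.zeros((0, 3)), np.zeros(0))
    ncells = grid.cell_counts
    if n <= 64 or np.any(grid.periodic & (ncells < 3)):
        # tiny systems: the all-pairs scan is cheaper than cell bookkeeping;
        # coarse periodic grids: half-space enumeration would double-count
        return brute_force_pairs(universe, pos)
    order = grid.order
    slin = grid.sorted_linear
    nyz = ncells[1] * ncells[2]
    offsets = np.array(((0, 0, 0),) + FORWARD_OFFSETS, dtype=np.int64)
    n_off = len(offsets)
    # neighbor cell of every particle for every direction, in one pass
    nb = grid.coords[None, :, :] + offsets[:, None, :]  # (n_off, n, 3)
    valid = np.ones((n_off, n), dtype=bool)
    for ax in range(3):
        if grid.periodic[ax]:
            nb[:, :, ax] %= ncells[ax]
        else:
            valid &= (nb[:, :, ax] >= 0) & (nb[:, :, ax] < ncells[ax])
    nlin = nb[:, :, 0] * nyz + nb[:, :, 1] * ncells[2] + nb[:, :, 2]
    nlin = np.where(valid, nlin, -1).ravel()
    start = np.searchsorted(slin, nlin, "left")
    end = np.searchsorted(slin, nlin, "right")
    counts = end - start
    tot = int(counts.sum())
    if tot == 0:
        return PairSet(*(np.zeros(0, dtype=np.int64),) * 2, np.zeros((0, 3)), np.zeros(0))
    i = np.repeat(np.tile(np.arange(n), n_off), counts)
    csum = np.concatenate(([0], np.cumsum(counts)))
    flat = np.arange(tot) - np.repeat(csum[:-1], counts) + np.repeat(start, counts)
    j = order[flat]
    # self-cell direction: keep each unordered pair once, drop self-pairs
    self_block = np.arange(tot) < csum[n]  # rows generated by the (0,0,0) offset
    keep = ~self_block | (j > i)
    i, j = i[keep], j[keep]
    dx = universe.minimum_image(pos[i] - pos[j])
    r = np.linalg.norm(dx, axis=1)
    keep = (r < universe.cutoff) & (r > 0)
    return PairSet(i[keep], j[keep], dx[keep], r[keep])


def reference_pairs(universe: Universe, grid: CellGrid) -> PairSet:
    """Sort / Force-Self / Force-Pair task decomposition, literally.

    A slow but explicit realization of the pruned cell-pair enumeration:
    used as an internal cross-check of :func:`candidate_pairs`.
    """
    pos = grid.positions
    cutoff = universe.cutoff
    got_i, got_j = [], []
    sorted_cells = {}
    for cell in grid.occupied_cells():
        sorted_cells[cell] = grid.sort_cell(cell)
    for cell in sorted_cells:
        rows = grid.rows_in_cell(cell)
        # Force Self
        for a_idx in range(len(rows)):
            for b_idx in range(a_idx + 1, len(rows)):
                got_i.append(rows[a_idx])
                got_j.append(rows[b_idx])
        # Force Pair, pruned by the Sort projections
        for off in FORWARD_OFFSETS:
            nb, shift = grid.neighbor_cell(cell, off)
            if nb is None or nb == cell or nb not in sorted_cells:
                continue
            axis = np.asarray(off, dtype=float)
            axis /= np.linalg.norm(axis)
            mine = sorted_cells[cell][off]
            theirs = sorted_cells[nb][off]
            their_proj = (pos[theirs] - shift) @ axis
            for a in mine:
                pa = float(pos[a] @ axis)
                # partners whose projection exceeds pa + cutoff cannot be in
                # range: |r| >= component along the pair axis
                hi = np.searchsorted(their_proj, pa + cutoff, "right")
                for b in theirs[:hi]:
                    got_i.append(a)
                    got_j.append(b)
    if not got_i:
        return PairSet(*(np.zeros(0, dtype=np.int64),) * 2, np.zeros((0, 3)), np.zeros(0))
    i = np.asarray(got_i, dtype=np.int64)
    j = np.asarray(got_j, dtype=np.int64)
    dx = universe.minimum_image(pos[i] - pos[j])
    r = np.linalg.norm(dx, axis=1)
    keep = (r < cutoff) & (r > 0)
    return PairSet(i[keep], j[keep], dx[keep], r[keep])


# --------------------------------------------------------------------- arrays
def gather_arrays(universe: Universe) -> dict:
    """Snapshot registry contents into flat arrays (row order = registry order)."""
    parts = list(universe.particles.values())
    n = len(parts)
    type_codes = {name: idx for idx, name in enumerate(universe.types)}
    top = {}
    for cid in universe.clusters:
        c = cid
        while universe.clusters[c].parent_id is not None:
            c = universe.clusters[c].parent_id
        top[cid] = c
    arrays = {
        "ids": np.fromiter((p.id for p in parts), dtype=np.int64, count=n),
        "pos": np.array([p.position for p in parts]) if n else np.zeros((0, 3)),
        "vel": np.array([p.velocity for p in parts]) if n else np.zeros((0, 3)),
        "mass": np.array([p.mass for p in parts]) if n else np.zeros(0),
        "type_code": np.fromiter(
            (type_codes[p.type.name] for p in parts), dtype=np.int64, count=n
        ),
        "frozen": np.fromiter((p.frozen for p in parts), dtype=bool, count=n),
        "newtonian": np.fromiter(
            (p.type.dynamics == "newtonian" for p in parts), dtype=bool, count=n
        ),
        "topcluster": np.fromiter(
            (
                -1 if p.cluster_id is None else top[p.cluster_id]
                for p in parts
            ),
            dtype=np.int64,
            count=n,
        ),
        "row_of": {p.id: row for row, p in enumerate(parts)},
        "particles": parts,
        "type_codes": type_codes,
    }
    return arrays


# --------------------------------------------------------------------- forces
def _accumulate(f, i, j, fvec):
    """Accumulate +/- pair forces (bincount is much faster than ufunc.at)."""
    n = len(f)
    for ax in range(3):
        f[:, ax] += np.bincount(i, weights=fvec[:, ax], minlength=n)
        f[:, ax] -= np.bincount(j, weights=fvec[:, ax], minlength=n)


def _apply_pairwise(f, pe, pairs, sel, potential, cutoff):
    """Evaluate one potential on selected pairs and accumulate +/- forces."""
    r = pairs.r[sel]
    if len(r) == 0:
        return pe
    u, du = potential.evaluate(r)
    within = r < cutoff
    u = np.where(within, u, 0.0)
    du = np.where(within, du, 0.0)
    scale = np.where(within, -du / r, 0.0)
    fvec = scale[:, None] * pairs.dx[sel]
    _accumulate(f, pairs.i[sel], pairs.j[sel], fvec)
    return pe + float(u.sum())


def compute_forces(universe: Universe, consume_rng: bool = True):
    """The Force stage.

    Fills a fresh force array from implicit, DPD, bonded and explicit
    contributions and returns ``(forces, potential_energy, bonded_energies,
    arrays, pairs)``.  With ``consume_rng=False`` the stochastic terms (DPD
    random force, thermal noise) are skipped so the call has no side effect
    on the universe's random streams (used for energy reporting).
    """
    arrays = gather_arrays(universe)
    universe._arrays_cache = arrays
    n = len(arrays["particles"])
    pos = arrays["pos"]
    vel = arrays["vel"]
    if n and not np.all(np.isfinite(pos)):
        bad = np.where(~np.all(np.isfinite(pos), axis=1))[0]
        pid = int(arrays["ids"][bad[0]])
        raise EngineError(f"non-finite position for particle {pid} during Force stage")
    grid = CellGrid(universe, pos)
    pairs = candidate_pairs(universe, grid)
    f = np.zeros((n, 3))
    pe = 0.0

    tc = arrays["type_code"]
    type_codes = arrays["type_codes"]
    if len(pairs):
        ti, tj = tc[pairs.i], tc[pairs.j]
        pair_lo = np.minimum(ti, tj)
        pair_hi = np.maximum(ti, tj)
        topc = arrays["topcluster"]
        bi, bj = topc[pairs.i], topc[pairs.j]
        bound_mask = (bi >= 0) & (bi == bj)
    # implicit potential bindings
    for (name_a, name_b, mode), pots in universe.bindings.implicit.items():
        if not len(pairs):
            break
        ca, cb = type_codes[name_a], type_codes[name_b]
        lo, hi = min(ca, cb), max(ca, cb)
        match = (pair_lo == lo) & (pair_hi == hi)
        if mode == "bound":
            match = match & bound_mask
        elif mode == "unbound":
            match = match & ~bound_mask
        for pot in pots:
            cutoff = min(pot.r_max, universe.cutoff)
            pe = _apply_pairwise(f, pe, pairs, match, pot, cutoff)
    # transport-DPD bindings
    for (name_a, name_b), plist in universe.bindings.dpd.items():
        if not len(pairs):
            break
        ca, cb = type_codes[name_a], type_codes[name_b]
        lo, hi = min(ca, cb), max(ca, cb)
        match = (pair_lo == lo) & (pair_hi == hi)
        for params in plist:
            sel = match & (pairs.r < params.rc)
            m = int(sel.sum())
            if m == 0:
                continue
            r = pairs.r[sel]
            rhat = pairs.dx[sel] / r[:, None]
            w = 1.0 - r / params.rc
            fmag = params.alpha * w
            vrel = vel[pairs.i[sel]] - vel[pairs.j[sel]]
            fmag = fmag - params.gamma * w * w * np.einsum("ij,ij->i", rhat, vrel)
            if consume_rng and params.sigma > 0:
                xi = universe.rng["dpd"].standard_normal(m)
                fmag = fmag + params.sigma * w * xi / math.sqrt(universe.dt)
            fvec = fmag[:, None] * rhat
            _accumulate(f, pairs.i[sel], pairs.j[sel], fvec)
            pe += float((0.5 * params.alpha * params.rc * w * w).sum())

    # bonded interactions (minimum-image, no global cutoff)
    from . import bonded as _bonded

    row_of = arrays["row_of"]
    disp = universe.displacement
    bonded_energies = {"bonds": {}, "angles": {}, "dihedrals": {}}
    any_bonded = universe.bonds or universe.angles or universe.dihedrals
    positions_by_id = (
        {pid: pos[row] for pid, row in row_of.items()} if any_bonded else {}
    )
    for registry, name, fn in (
        (universe.bonds, "bonds", _bonded.bond_energy_forces),
        (universe.angles, "angles", _bonded.angle_energy_forces),
        (universe.dihedrals, "dihedrals", _bonded.dihedral_energy_forces),
    ):
        for bid, item in registry.items():
            energy, fmap = fn(item, positions_by_id, disp)
            bonded_energies[name][bid] = energy
            pe += energy
            for pid, fv in fmap.items():
                f[row_of[pid]] += fv

    # explicit forces
    for tname, force_list in universe.bindings.explicit.items():
        rows = np.where(tc == type_codes[tname])[0]
        if len(rows) == 0:
            continue
        for force in force_list:
            if force.kind == "gaussian_noise" and not consume_rng:
                continue
            force.apply(universe, rows, vel, f, universe.rng["noise"], universe.dt)

    if universe.plane_axis is not None:
        f[:, universe.plane_axis] = 0.0

    if n and not np.all(np.isfinite(f)):
        bad_rows = np.where(~np.all(np.isfinite(f), axis=1))[0]
        pid = int(arrays["ids"][bad_rows[0]])
        raise EngineError(f"non-finite force on particle {pid} during Force stage")
    universe._pair_cache = pairs
    return f, pe, bonded_energies, arrays, pairs


def apply_boundary_arrays(pos, vel, dims, boundary):
    """Vectorized boundary application (in place)."""
    for ax in range(3):
        L = dims[ax]
        if boundary[ax] == "periodic":
            pos[:, ax] %= L
            pos[:, ax][pos[:, ax] >= L] = 0.0
        else:
            y = pos[:, ax] % (2.0 * L)
            upper = y >= L
            pos[:, ax] = np.where(upper, 2.0 * L - y, y)
            vel[:, ax] = np.where(upper, -vel[:, ax], vel[:, ax])
            edge = pos[:, ax] >= L
            pos[:, ax][edge] = np.nextafter(L, 0.0)


def step(universe: Universe) -> bool:
    """Advance one step.  Returns False if an event signalled a stop."""
    from . import bonded as _bonded
    from .species import integrate_species

    # Prep + Force
    f, pe, bonded_energies, arrays, pairs = compute_forces(universe)
    universe.last_potential_energy = pe

    # Update: integrate trajectories
    dt = universe.dt
    pos = arrays["pos"]
    vel = arrays["vel"]
    mass = arrays["mass"]
    mobile = ~arrays["frozen"]
    newton = arrays["newtonian"] & mobile
    over = ~arrays["newtonian"] & mobile
    if newton.any():
        vel[newton] += f[newton] * (dt / mass[newton])[:, None]
    if over.any():
        vel[over] = f[over] / mass[over][:, None]
    dr = np.zeros_like(pos)
    dr[mobile] = vel[mobile] * dt
    if universe.plane_axis is not None:
        dr[:, universe.plane_axis] = 0.0
        vel[:, universe.plane_axis] = 0.0
    pos += dr
    apply_boundary_arrays(pos, vel, universe.dims, universe.boundary)
    if len(pos) and not np.all(np.isfinite(pos)):
        bad = np.where(~np.all(np.isfinite(pos), axis=1))[0]
        pid = int(arrays["ids"][bad[0]])
        raise EngineError(f"non-finite position for particle {pid} during Update stage")
    for row, p in enumerate(arrays["particles"]):
        p.position[:] = pos[row]
        p.velocity[:] = vel[row]
        p.force[:] = f[row]

    # species transport and reactions (fluxes from the Force-stage geometry)
    integrate_species(universe, pairs, arrays)

    # dissociation
    for registry, key in (
        (universe.bonds, "bonds"),
        (universe.angles, "angles"),
        (universe.dihedrals, "dihedrals"),
    ):
        _bonded.cull_dissociated(registry, bonded_energies[key])

    # events fire last, in registration order
    completed = universe.step_count + 1
    stop = False
    for handle in list(universe.events):
        ev = universe.events.get(handle)
        if ev is None:
            continue
        if completed % ev.period_steps == 0:
            result = ev.callback(universe, completed * dt)
            if result is not None and bool(result):
                stop = True
    universe.step_count = completed
    universe.time = universe.step_count * universe.dt
    return not stop


def kinetic_energy(universe: Universe) -> float:
    """``sum 1/2 m v^2`` over Newtonian, non-frozen particles."""
    ke = 0.0
    for p in universe.particles.values():
        if p.type.dynamics == "newtonian" and not p.frozen:
            ke += 0.5 * p.mass * float(np.dot(p.velocity, p.velocity))
    return ke


def potential_energy(universe: Universe) -> float:
    """Total implicit + bonded potential energy at the current positions.

    Deterministic: the stochastic force terms are skipped, so calling this
    never perturbs the universe's random streams.
    """
    _, pe, _, _, _ = compute_forces(universe, consume_rng=False)
    return pe


def total_energy(universe: Universe):
    """Return ``(kinetic, potential)`` for the current configuration."""
    return kinetic_energy(universe), potential_energy(universe)
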