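"""Cellular-automaton engine of the branching evolutionary process (BEP).

Cells live on a 2D square lattice, one cell per point. A unit time step has
three phases: (1) every cell is marked dead with probability q0 and, if it
survives, marked to divide with probability p = min(1, p0 * 10**(f*k));
(2) dead cells are removed; (3) marked cells divide in outward-spiral order
from the lattice center (traversal direction of each spiral ring is flipped
at random to keep spatial symmetry). Before a division the parent genome is
mutated (each wild-type locus switches on with probability r) and the
daughter receives a copy, so both carry the new mutations. A daughter is
placed on an empty Moore neighbor if one exists; otherwise a direction is
drawn with probability proportional to 1/run_length and the run of occupied
points is shifted outward by one to free the neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SimParams

EMPTY = -1

# Moore neighborhood: 8 surrounding points
_DIRS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


class PlacementError(RuntimeError):
    """No direction can free a neighbor before the lattice boundary."""


class ConfigurationError(ValueError):
    pass


@dataclass
class TumorState:
    """Mutable world state of one run.

    ``occupancy`` maps lattice points to cell ids (EMPTY = -1). Per-cell
    arrays are indexed by cell id; ids are never reused, so dead cells keep
    their genome and parent for lineage queries.
    """

    params: SimParams
    occupancy: np.ndarray          # (L, L) int64, EMPTY or cell id
    genomes: np.ndarray            # (capacity, n_genes) bool
    positions: np.ndarray          # (capacity, 2) int64 row, col
    parents: np.ndarray            # (capacity,) int64, -1 for initial cells
    alive: np.ndarray              # (capacity,) bool
    n_cells_created: int
    time_step: int
    rng: np.random.Generator

    @property
    def population(self) -> int:
        return int(self.alive[: self.n_cells_created].sum())

    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.n_cells_created])

    def driver_counts(self, ids: np.ndarray) -> np.ndarray:
        d = self.params.n_drivers
        if d == 0:
            return np.zeros(len(ids), dtype=np.int64)
        return self.genomes[ids, :d].sum(axis=1)

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_cells_created + extra
        cap = self.genomes.shape[0]
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        for name in ("genomes", "positions", "parents", "alive"):
            arr = getattr(self, name)
            grown = np.zeros((new_cap,) + arr.shape[1:], dtype=arr.dtype)
            grown[:cap] = arr
            if name == "parents":
                grown[cap:] = -1
            setattr(self, name, grown)

    def _new_cell(self, row: int, col: int, genome: np.ndarray, parent: int) -> int:
        self._ensure_capacity(1)
        cid = self.n_cells_created
        self.n_cells_created += 1
        self.genomes[cid] = genome
        self.positions[cid] = (row, col)
        self.parents[cid] = parent
        self.alive[cid] = True
        self.occupancy[row, col] = cid
        return cid


def division_probability(driver_count: int | np.ndarray, params: SimParams):
    """p = min(1, p0 * 10**(f*k)); vectorized over driver counts."""
    p = params.base_division_prob * np.power(
        10.0, params.driver_strength * np.asarray(driver_count, dtype=float)
    )
    return np.minimum(p, 1.0)


def mutate_genome(genome: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Switch each wild-type (0) locus on with probability r; 1s never revert."""
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"mutation rate must be in [0,1], got {r}")
    hits = rng.random(genome.shape) < r
    return genome | hits


def _center_packing(side: int, k: int) -> np.ndarray:
    """The k lattice points closest (squared Euclidean) to the lattice center.

    Ties broken by (row, col) so the packing is deterministic.
    """
    c = (side - 1) / 2.0
    # search a window comfortably larger than the packing radius
    radius = max(2, int(math.ceil(math.sqrt(k / math.pi))) + 2)
    lo = max(0, int(c) - radius)
    hi = min(side, int(c) + radius + 2)
    pts = [(r, q) for r in range(lo, hi) for q in range(lo, hi)]
    pts.sort(key=lambda p: ((p[0] - c) ** 2 + (p[1] - c) ** 2, p[0], p[1]))
    if len(pts) < k:
        raise ConfigurationError("lattice too small for init_cells")
    return np.array(pts[:k], dtype=np.int64)


def init_state(params: SimParams, seed: int) -> TumorState:
    """Place init_cells all-wild-type cells packed around the lattice center."""
    side = params.lattice_side
    occupancy = np.full((side, side), EMPTY, dtype=np.int64)
    cap = max(64, 2 * params.init_cells)
    state = TumorState(
        params=params,
        occupancy=occupancy,
        genomes=np.zeros((cap, params.n_genes), dtype=bool),
        positions=np.zeros((cap, 2), dtype=np.int64),
        parents=np.full(cap, -1, dtype=np.int64),
        alive=np.zeros(cap, dtype=bool),
        n_cells_created=0,
        time_step=0,
        rng=np.random.default_rng(seed),
    )
    for row, col in _center_packing(side, params.init_cells):
        state._new_cell(int(row), int(col), np.zeros(params.n_genes, dtype=bool), -1)
    return state


def find_division_site(state: TumorState, parent_pos, rng=None):
    """Return (daughter (row,col), shift description or None).

    Empty Moore neighbor: chosen uniformly, no shift. Fully enclosed: a
    direction i is drawn with probability proportional to 1/l_i where l_i is
    the run of consecutive occupied points before the nearest empty point;
    that run is shifted outward by one and the freed neighbor returned.
    Directions whose run hits the boundary with no empty point are
    ineligible; if all 8 are, PlacementError is raised.
    """
    if rng is None:
        rng = state.rng
    occ = state.occupancy
    side = occ.shape[0]
    r0, c0 = int(parent_pos[0]), int(parent_pos[1])

    empties = []
    for dr, dc in _DIRS:
        rr, cc = r0 + dr, c0 + dc
        if 0 <= rr < side and 0 <= cc < side and occ[rr, cc] == EMPTY:
            empties.append((rr, cc))
    if empties:
        pick = empties[int(rng.integers(len(empties)))]
        return pick, None

    run_lengths = np.zeros(8)
    for i, (dr, dc) in enumerate(_DIRS):
        l = 0
        rr, cc = r0 + dr, c0 + dc
        while 0 <= rr < side and 0 <= cc < side and occ[rr, cc] != EMPTY:
            l += 1
            rr += dr
            cc += dc
        if 0 <= rr < side and 0 <= cc < side:
            run_lengths[i] = l  # empty point found after l occupied points
        # else: boundary reached, ineligible (weight 0)

    eligible = run_lengths > 0
    if not eligible.any():
        raise PlacementError("no direction reaches an empty point")
    weights = np.where(eligible, 1.0 / np.where(eligible, run_lengths, 1.0), 0.0)
    weights /= weights.sum()
    i = int(rng.choice(8, p=weights))
    dr, dc = int(_DIRS[i][0]), int(_DIRS[i][1])
    l = int(run_lengths[i])
    # shift the run outward by one point, farthest first
    for j in range(l, 0, -1):
        src_r, src_c = r0 + j * dr, c0 + j * dc
        dst_r, dst_c = r0 + (j + 1) * dr, c0 + (j + 1) * dc
        cid = occ[src_r, src_c]
        occ[dst_r, dst_c] = cid
        state.positions[cid] = (dst_r, dst_c)
    freed = (r0 + dr, c0 + dc)
    occ[freed] = EMPTY
    return freed, {"direction": (dr, dc), "run_length": l}


def _spiral_keys(state: TumorState, ids: np.ndarray, rng: np.random.Generator):
    """Sort order for dividing cells: outward square spiral from the center.

    Ring = Chebyshev distance from the lattice center; within a ring, cells
    are ordered by angle, and each ring's traversal direction is flipped
    with probability 1/2 per step (spatial-symmetry requirement).
    """
    c = (state.params.lattice_side - 1) / 2.0
    pos = state.positions[ids].astype(float)
    dr = pos[:, 0] - c
    dc = pos[:, 1] - c
    ring = np.maximum(np.abs(dr), np.abs(dc))
    ring_idx = np.ceil(ring).astype(np.int64)
    theta = np.arctan2(dc, dr)
    n_rings = int(ring_idx.max()) + 1 if len(ids) else 1
    flips = rng.random(n_rings) < 0.5
    signed = np.where(flips[ring_idx], -theta, theta)
    return np.lexsort((signed, ring_idx))


def step(state: TumorState, params: SimParams | None = None, rng=None) -> TumorState:
    """Advance one unit time step in place (also returns the state)."""
    if params is None:
        params = state.params
    if rng is None:
        rng = state.rng
    ids = state.alive_ids()
    if len(ids) == 0:
        state.time_step += 1
        return state

    # phase 1: simultaneous death / division marks from the pre-step state
    dies = rng.random(len(ids)) < params.death_prob
    p = division_probability(state.driver_counts(ids), params)
    divides = (~dies) & (rng.random(len(ids)) < p)

    # phase 2: remove dead cells
    dead = ids[dies]
    if len(dead):
        state.occupancy[state.positions[dead, 0], state.positions[dead, 1]] = EMPTY
        state.alive[dead] = False

    # phase 3: divisions in spiral order
    div_ids = ids[divides]
    if len(div_ids):
        order = _spiral_keys(state, div_ids, rng)
        div_ids = div_ids[order]
        # mutate parents up front (daughter copies the mutated genome)
        hits = rng.random((len(div_ids), params.n_genes)) < params.mutation_rate
        state.genomes[div_ids] |= hits
        state._ensure_capacity(len(div_ids))
        for cid in div_ids:
            cid = int(cid)
            try:
                (rr, cc), _ = find_division_site(state, state.positions[cid], rng)
            except PlacementError:
                continue  # division skipped this step
            state._new_cell(rr, cc, state.genomes[cid], cid)

    state.time_step += 1
    return state


@dataclass
class SimResult:
    final_state: TumorState
    growth_curve: list          # [(time_step, population)]
    snapshots: dict             # time_step -> occupancy copy (int64)


def run_simulation(
    params: SimParams, seed: int, snapshot_times: list[int] | None = None
) -> SimResult:
    """Run until population > max_cells, extinction, or max_steps reached."""
    snapshot_times = set(snapshot_times or [])
    state = init_state(params, seed)
    pop = state.population
    curve = [(0, pop)]
    snaps = {}
    if 0 in snapshot_times:
        snaps[0] = state.occupancy.copy()
    while 0 < pop <= params.max_cells and state.time_step < params.max_steps:
        step(state, params)
        pop = state.population
        curve.append((state.time_step, pop))
        if state.time_step in snapshot_times:
            snaps[state.time_step] = state.occupancy.copy()
    return SimResult(final_state=state, growth_curve=curve, snapshots=snaps)
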