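"""In-silico multiregional and single-cell sequencing of simulated tumors.

25 square sampling windows are laid out on a 5x5 grid over the lattice;
windows where at least half the points are occupied are eligible. Per
window and gene, the VAF is the fraction of occupied points whose cell
carries the mutation (the simulated genome is haploid and there is no
normal contamination, so VAF equals the cancer cell fraction). VAFs not
exceeding 0.3 are floored to 0, mimicking the detection limit of
multiregional sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import TumorState, EMPTY

VAF_FLOOR = 0.3
WINDOW_SIDE = 31
GRID_N = 5


class SamplingError(RuntimeError):
    pass


@dataclass
class VAFMatrix:
    """Genes/variants x regions(samples) variant-allele-fraction matrix."""

    values: np.ndarray        # (n_rows, n_samples) floats in [0,1]
    row_ids: list
    column_ids: list
    filtered_flag: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("VAFs must lie in [0,1]")
        self.values = v


def place_sampling_regions(
    lattice_side: int, window_side: int = WINDOW_SIDE, grid_n: int = GRID_N
) -> list[tuple[int, int, int, int]]:
    """25 pairwise-disjoint window spans (r0, r1, c0, c1), half-open.

    Centers sit on a grid_n x grid_n grid spaced s=(L-w)//(grid_n-1)... the
    offsets are {-2s,-s,0,s,2s} about the lattice center with
    s=(L-w)//(2*(grid_n//2)), which keeps the pattern symmetric under 90
    degree rotation about its own centroid and inside the lattice.
    """
    L, w = lattice_side, window_side
    if L < grid_n * w:
        raise ValueError(f"lattice side {L} too small for {grid_n} windows of {w}")
    half = grid_n // 2
    s = (L - w) // (2 * half)
    c0 = L // 2
    centers = [c0 + (k - half) * s for k in range(grid_n)]
    windows = []
    for rc in centers:
        for cc in centers:
            r_lo = rc - w // 2
            c_lo = cc - w // 2
            if r_lo < 0 or c_lo < 0 or r_lo + w > L or c_lo + w > L:
                raise ValueError("window layout exceeds lattice bounds")
            windows.append((r_lo, r_lo + w, c_lo, c_lo + w))
    return windows


def eligible_windows(state: TumorState, windows) -> list[int]:
    """Indices of windows with at least half their points occupied."""
    occ = state.occupancy
    out = []
    for i, (r0, r1, c0, c1) in enumerate(windows):
        block = occ[r0:r1, c0:c1]
        if 2 * int((block != EMPTY).sum()) >= block.size:
            out.append(i)
    return out


def window_vafs(state: TumorState, window) -> np.ndarray:
    """Per-gene mutated-cell fraction among occupied points of one window."""
    r0, r1, c0, c1 = window
    ids = state.occupancy[r0:r1, c0:c1].ravel()
    ids = ids[ids != EMPTY]
    if len(ids) == 0:
        return np.zeros(state.params.n_genes)
    return state.genomes[ids].mean(axis=0)


def multiregional_profile(
    state: TumorState,
    s: int,
    rng: np.random.Generator | None = None,
    window_side: int = WINDOW_SIDE,
    vaf_floor: float = VAF_FLOOR,
) -> VAFMatrix:
    """Sample s random eligible windows and build the n x s VAF matrix.

    VAFs that do not exceed ``vaf_floor`` (inclusive) are set to 0.
    """
    if rng is None:
        rng = state.rng
    windows = place_sampling_regions(state.params.lattice_side, window_side)
    elig = eligible_windows(state, windows)
    if len(elig) < s:
        raise SamplingError(f"only {len(elig)} eligible windows, need {s}")
    chosen = rng.choice(len(elig), size=s, replace=False)
    cols = []
    col_ids = []
    for j in sorted(int(elig[i]) for i in chosen):
        v = window_vafs(state, windows[j])
        v = np.where(v <= vaf_floor, 0.0, v)
        cols.append(v)
        col_ids.append(f"region{j:02d}")
    values = np.column_stack(cols)
    row_ids = [f"gene{g:03d}" for g in range(state.params.n_genes)]
    return VAFMatrix(values=values, row_ids=row_ids, column_ids=col_ids, filtered_flag=True)


def single_cell_profile(
    state: TumorState, m: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """n_genes x m binary matrix of m cells sampled without replacement."""
    if rng is None:
        rng = state.rng
    ids = state.alive_ids()
    if len(ids) < m:
        raise SamplingError(f"population {len(ids)} < requested m={m}")
    picked = rng.choice(ids, size=m, replace=False)
    return state.genomes[picked].T.astype(np.int8)
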