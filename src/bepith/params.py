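"""Simulation parameters for the branching evolutionary process (BEP) model.

The model grows a tumor on a 2D square lattice. Each cell carries a binary
genome of ``n_genes`` loci; the first ``n_drivers`` loci are driver genes.
Per unit time step a cell dies with probability ``death_prob`` and otherwise
divides with probability ``p0 * 10**(driver_strength * k)`` (capped at 1),
where ``k`` is its number of mutated drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class SimParams:
    """Parameter set of one BEP run.

    Defaults are the study conditions: a 300-gene genome, base division
    probability 1e-3, death probability 1e-7, 10 initial cells, growth until
    1e6 cells or 5e6 steps. The three fitted evolutionary parameters default
    to the setting selected by the ABC analysis (r=0.01, d=6, f=0.8).
    """

    n_genes: int = 300
    n_drivers: int = 6
    driver_strength: float = 0.8
    mutation_rate: float = 0.01
    base_division_prob: float = 0.001
    death_prob: float = 1e-7
    init_cells: int = 10
    max_cells: int = 1_000_000
    max_steps: int = 5_000_000
    lattice_side: int = 2048

    def __post_init__(self) -> None:
        if not (0 <= self.n_drivers <= self.n_genes):
            raise ValueError(
                f"n_drivers must be in [0, n_genes]: {self.n_drivers} vs {self.n_genes}"
            )
        for name in ("mutation_rate", "base_division_prob", "death_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.init_cells < 1:
            raise ValueError("init_cells must be >= 1")
        if self.lattice_side ** 2 < self.max_cells:
            raise ValueError(
                f"lattice too small: {self.lattice_side}^2 < max_cells={self.max_cells}"
            )
        if self.lattice_side ** 2 < self.init_cells:
            raise ValueError("lattice too small for init_cells")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        coerced = {}
        for k, v in d.items():
            typ = cls.__dataclass_fields__[k].type
            coerced[k] = int(v) if "int" in str(typ) else float(v)
        return cls(**coerced)


#: scaled-down profile used throughout the test-suite and the scaled
#: reproductions: same biology, smaller world (1e4 cells on a 200-side
#: lattice) so a run takes seconds instead of hours.
SCALED = dict(lattice_side=200, max_cells=10_000, max_steps=200_000)


def scaled_params(**overrides) -> SimParams:
    """SimParams with the scaled-down world; overrides win."""
    kw = dict(SCALED)
    kw.update(overrides)
    return SimParams(**kw)
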