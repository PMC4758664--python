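"""Founder/progressor methylation calls and methylation-variance analysis.

Differential methylation of a probe in a tumor sample is the beta-value
difference to the matched normal (d_beta). Founder hyper/hypomethylation:
d_beta > 0.3 (resp. < -0.3) in every sample of a case. Progressor
methylation: the maximal between-group mean d_beta difference over the
sample-tree bipartitions (d'_beta) exceeds a threshold chosen so the
permutation-estimated FDR is 0.1; calls are split hyper/hypo by the sign
of the sample-averaged d_beta. Variance analysis decomposes each probe's
total sum of squares over all samples into within-case (intratumor) and
between-case (intertumor) components, SS_T = SS_w + SS_b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FOUNDER_DELTA = 0.3
FDR_TARGET = 0.1
N_PERM = 100
THETA_GRID = np.round(np.arange(0.05, 0.6001, 0.01), 4)


@dataclass
class MethylationCall:
    probe_id: str
    case_id: str
    category: str       # founder / progressor
    direction: str      # hyper / hypo
    statistic: float
    threshold: float


@dataclass
class BetaMatrix:
    beta: pd.DataFrame          # probes x samples in [0,1]
    normal_beta: pd.DataFrame   # probes x cases
    cases: pd.Series            # sample -> case
    probe_annot: pd.DataFrame | None = None   # island category, promoter flag, ...

    def __post_init__(self):
        for df in (self.beta, self.normal_beta):
            v = df.to_numpy(float)
            if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
                raise ValueError("beta values must lie in [0,1]")

    def delta(self, case: str) -> pd.DataFrame:
        """Tumor beta minus matched-normal beta for one case's samples."""
        samples = self.cases.index[self.cases == case]
        return self.beta[samples].sub(self.normal_beta[case], axis=0)


def call_founder_methylation(
    delta: pd.DataFrame, case_id: str = "case", t: float = FOUNDER_DELTA
) -> list[MethylationCall]:
    """Founder hyper: d_beta > t in all samples; hypo: d_beta < -t in all."""
    if delta.shape[1] < 1:
        raise ValueError("need at least one sample")
    calls = []
    hyper = (delta > t).all(axis=1)
    hypo = (delta < -t).all(axis=1)
    for pid in delta.index[hyper]:
        calls.append(MethylationCall(pid, case_id, "founder", "hyper",
                                     float(delta.loc[pid].min()), t))
    for pid in delta.index[hypo]:
        calls.append(MethylationCall(pid, case_id, "founder", "hypo",
                                     float(delta.loc[pid].max()), t))
    return calls


def _delta_prime(delta: np.ndarray, groups: list[tuple[np.ndarray, np.ndarray]]):
    """Per-probe signed max-|difference| of group means over bipartitions."""
    best = np.zeros(delta.shape[0])
    best_abs = np.zeros(delta.shape[0])
    for ia, ib in groups:
        d = delta[:, ia].mean(axis=1) - delta[:, ib].mean(axis=1)
        take = np.abs(d) > best_abs
        best[take] = d[take]
        best_abs[take] = np.abs(d[take])
    return best


def call_progressor_methylation(
    delta: pd.DataFrame,
    bipartitions: list[tuple[frozenset, frozenset]],
    case_id: str = "case",
    fdr_target: float = FDR_TARGET,
    n_perm: int = N_PERM,
    rng: np.random.Generator | None = None,
    theta_grid: np.ndarray = THETA_GRID,
) -> tuple[list[MethylationCall], float | None]:
    """Permutation-FDR-thresholded progressor calls.

    FDR(theta) = mean permuted count of |d'_beta| > theta divided by the
    observed count; the chosen threshold is the smallest grid value with
    FDR <= fdr_target. Returns (calls, threshold or None if no threshold
    attains the target)."""
    if rng is None:
        rng = np.random.default_rng()
    samples = list(delta.columns)
    idx = {s: i for i, s in enumerate(samples)}
    groups = [
        (np.array([idx[s] for s in a]), np.array([idx[s] for s in b]))
        for a, b in bipartitions
    ]
    if not groups:
        raise ValueError("need at least one bipartition")
    X = delta.to_numpy(float)
    obs = _delta_prime(X, groups)

    null_counts = np.zeros(len(theta_grid))
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        null = _delta_prime(X[:, perm], groups)
        null_counts += (np.abs(null)[:, None] > theta_grid[None, :]).sum(axis=0)
    null_mean = null_counts / n_perm
    obs_counts = (np.abs(obs)[:, None] > theta_grid[None, :]).sum(axis=0)

    chosen = None
    for t, nm, oc in zip(theta_grid, null_mean, obs_counts):
        if oc == 0:
            continue
        if nm / oc <= fdr_target:
            chosen = float(t)
            break
    if chosen is None:
        log.info("no threshold reaches FDR %.2f; no progressor calls", fdr_target)
        return [], None

    mean_delta = X.mean(axis=1)
    calls = []
    for i in np.flatnonzero(np.abs(obs) > chosen):
        calls.append(
            MethylationCall(
                probe_id=delta.index[i],
                case_id=case_id,
                category="progressor",
                direction="hyper" if mean_delta[i] > 0 else "hypo",
                statistic=float(obs[i]),
                threshold=chosen,
            )
        )
    return calls, chosen


def variance_decomposition(beta: pd.DataFrame, cases: pd.Series) -> pd.DataFrame:
    """Per-probe SS_T, SS_w (within-case, intratumor) and SS_b
    (between-case, intertumor); SS_T = SS_w + SS_b."""
    case_of = cases.reindex(beta.columns)
    if case_of.isna().any():
        raise ValueError("every sample column needs a case label")
    if case_of.nunique() < 2:
        raise ValueError("need >= 2 cases")
    X = beta.to_numpy(float)
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum(axis=1)
    ss_within = np.zeros(X.shape[0])
    ss_between = np.zeros(X.shape[0])
    for case in case_of.unique():
        cols = np.flatnonzero((case_of == case).to_numpy())
        sub = X[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        ss_within += ((sub - m) ** 2).sum(axis=1)
        ss_between += len(cols) * (m[:, 0] - grand[:, 0]) ** 2
    return pd.DataFrame(
        {"ss_total": ss_total, "ss_within": ss_within, "ss_between": ss_between},
        index=beta.index,
    )


def variance_enrichment(
    variances: pd.Series, categories: pd.Series, top_ns: list[int]
) -> pd.DataFrame:
    """Enrichment of each probe category among the top-N highest-variance
    probes: (category fraction in top N) / (category fraction overall)."""
    cats = categories.reindex(variances.index)
    if cats.isna().any():
        raise ValueError("categories must cover all probes")
    n_probes = len(variances)
    order = variances.sort_values(ascending=False).index
    overall = cats.value_counts(normalize=True)
    rows = {}
    for n in top_ns:
        if n > n_probes:
            raise ValueError(f"top_n={n} exceeds probe count {n_probes}")
        top = cats.loc[order[:n]].value_counts(normalize=True)
        rows[n] = {c: float(top.get(c, 0.0) / overall[c]) for c in overall.index}
    return pd.DataFrame(rows).T.fillna(0.0)
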