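"""Cancer cell fraction (CCF) posterior from read counts, purity and
allele-specific copy number.

For a mutation seen in m of n reads at a locus with allele-specific copy
numbers (q_a, q_b) in a sample of purity alpha, the expected allele
fraction of a mutation present in p copies in a fraction c of cancer cells
is f = alpha*c*p / (2(1-alpha) + alpha*(q_a+q_b)). The posterior over c is
P(c|n,m,alpha,q_a,q_b) propto Binom(m|n, f) * P(p|q_a,q_b) * P(c), with a
uniform prior on a regular grid of 100 c values in [0.01, 1] and an
equal-configuration prior over the mutation multiplicity p. The CCF is the
posterior median; CCF > 0.8 is called clonal. Samples with purity <= 0.6
are not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CCF_GRID = np.linspace(0.01, 1.0, 100)
CLONAL_CCF = 0.8
MIN_PURITY = 0.6


@dataclass(frozen=True)
class CCFInput:
    alt_reads: int
    total_depth: int
    purity: float
    cn_a: int
    cn_b: int

    def __post_init__(self):
        if not (0 <= self.alt_reads <= self.total_depth):
            raise ValueError("need 0 <= alt_reads <= total_depth")
        if self.total_depth <= 0:
            raise ValueError("total_depth must be positive")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.cn_a < 0 or self.cn_b < 0 or self.cn_a + self.cn_b < 1:
            raise ValueError("need cn_a, cn_b >= 0 and cn_a + cn_b >= 1")


@dataclass
class CCFPosterior:
    grid: np.ndarray
    probs: np.ndarray
    ccf: float
    clonal: bool
    multiplicity_prior: dict


def multiplicity_prior(cn_a: int, cn_b: int) -> dict[int, float]:
    """Equal-configuration prior over the mutation multiplicity p.

    A mutation may sit on 1..cn_a copies of allele a or 1..cn_b copies of
    allele b; every configuration is equally probable. E.g. q_a=q_b=1 gives
    P(p=1)=1; q_a=1, q_b=2 gives P(p=1)=2/3, P(p=2)=1/3.
    """
    if cn_a < 0 or cn_b < 0:
        raise ValueError("copy numbers must be non-negative")
    configs = [p for p in range(1, cn_a + 1)] + [p for p in range(1, cn_b + 1)]
    if not configs:
        raise ValueError("no allele to mutate: cn_a + cn_b must be >= 1")
    prior: dict[int, float] = {}
    w = 1.0 / len(configs)
    for p in configs:
        prior[p] = prior.get(p, 0.0) + w
    return dict(sorted(prior.items()))


def expected_vaf(c, p: int, purity: float, cn_a: int, cn_b: int):
    """f(c,p,alpha,q_a,q_b) = alpha*c*p / (2(1-alpha)+alpha*(q_a+q_b)),
    clipped to [0, 1]. Vectorized over c."""
    denom = 2.0 * (1.0 - purity) + purity * (cn_a + cn_b)
    return np.clip(purity * np.asarray(c, float) * p / denom, 0.0, 1.0)


def ccf_posterior(inp: CCFInput) -> CCFPosterior:
    """Discrete posterior over the CCF grid; CCF = posterior median
    (smallest grid point whose cumulative mass reaches 0.5)."""
    prior_p = multiplicity_prior(inp.cn_a, inp.cn_b)
    like = np.zeros_like(CCF_GRID)
    for p, w in prior_p.items():
        f = expected_vaf(CCF_GRID, p, inp.purity, inp.cn_a, inp.cn_b)
        like += w * stats.binom.pmf(inp.alt_reads, inp.total_depth, f)
    total = like.sum()
    if total <= 0:  # numerically impossible observation; fall back to uniform
        probs = np.full_like(CCF_GRID, 1.0 / len(CCF_GRID))
    else:
        probs = like / total
    cum = np.cumsum(probs)
    idx = min(int(np.searchsorted(cum, 0.5)), len(CCF_GRID) - 1)
    ccf = float(CCF_GRID[idx])
    return CCFPosterior(
        grid=CCF_GRID.copy(),
        probs=probs,
        ccf=ccf,
        clonal=ccf > CLONAL_CCF,
        multiplicity_prior=prior_p,
    )


def classify_clonality(posterior: CCFPosterior, purity: float) -> str:
    """'clonal' (CCF > 0.8), 'subclonal', or 'not_evaluated' (purity <= 0.6)."""
    if purity <= MIN_PURITY:
        return "not_evaluated"
    return "clonal" if posterior.ccf > CLONAL_CCF else "subclonal"
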