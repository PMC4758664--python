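"""Synthetic multiregional fixtures with planted tree structure.

These generators emulate the shapes of real multiregional data — VAF
matrices with founder/shared/unique structure consistent with a sample
tree, segmented copy-number tables with arm-level and focal events planted
on tree branches, and methylation beta matrices with case-level clustering
and planted founder/progressor events — so every analysis operator can be
tested against known truth without any external download. They are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mutations import MultiregionalMutationProfile, classify_mutations
from .methylation import BetaMatrix

BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Shared knobs of the fixture generators; per-generator fields are
    ignored by the generators that do not use them."""

    n_samples: int = 5
    topology: str | list = "caterpillar"   # or explicit clades (index tuples)
    n_founder: int = 30
    n_shared: int = 20
    n_unique: int = 10
    vaf_noise: float = 0.0
    depth: int = 100
    # copy number
    cn_noise: float = 0.01
    cn_events: list | None = None          # [(region_id, branch, magnitude)]
    # methylation
    n_probes: int = 500
    n_cases: int = 4
    samples_per_case: int = 8
    meth_effect: float = 0.4
    meth_noise: float = 0.02
    n_meth_founder: int = 20
    n_meth_progressor: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founder", "n_shared", "n_unique", "n_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.vaf_noise < 0.5):
            raise ValueError("vaf_noise out of range")


def sample_names(n: int) -> list[str]:
    return [f"s{i+1}" for i in range(n)]


def tree_clades(spec: FixtureSpec) -> list[tuple[int, ...]]:
    """Internal (proper, non-singleton) clades of the planted topology."""
    n = spec.n_samples
    if isinstance(spec.topology, list):
        return [tuple(c) for c in spec.topology]
    if spec.topology == "caterpillar":
        # ((..((s1,s2),s3)..,sn): clades {s1,s2}, {s1..s3}, ..., {s1..s_{n-1}}
        return [tuple(range(k)) for k in range(2, n)]
    if spec.topology == "balanced":
        half = n // 2
        return [tuple(range(half)), tuple(range(half, n))]
    raise ValueError(f"unknown topology {spec.topology!r}")


def _truncnorm(rng, loc, scale, lo, hi, size=None):
    if scale == 0:
        return np.full(size, loc) if size else loc
    x = rng.normal(loc, scale, size=size)
    return np.clip(x, lo, hi)


def gen_mutation_profile(spec: FixtureSpec):
    """Planted multiregional mutation profile.

    Founder variants are present in every sample, shared variants on the
    planted internal clades (round-robin), unique variants on single
    leaves. Base VAFs 0.3 / 0.2 / 0.1 for founder / shared / unique plus
    truncated-Gaussian noise kept above the 0.05 presence threshold.
    Returns (MultiregionalMutationProfile, truth DataFrame)."""
    rng = np.random.default_rng(spec.seed)
    samples = sample_names(spec.n_samples)
    clades = tree_clades(spec)
    rows, truth_rows = [], []
    base = {"founder": 0.3, "shared": 0.2, "unique": 0.1}

    def vaf_row(members, cat):
        v = np.zeros(spec.n_samples)
        for i in members:
            v[i] = _truncnorm(rng, base[cat], spec.vaf_noise, 0.06, 1.0)
        return v

    vid = 0
    for k in range(spec.n_founder):
        rows.append(vaf_row(range(spec.n_samples), "founder"))
        truth_rows.append(("founder", tuple(range(spec.n_samples))))
        vid += 1
    for k in range(spec.n_shared):
        clade = clades[k % len(clades)] if clades else tuple(range(spec.n_samples - 1))
        rows.append(vaf_row(clade, "shared"))
        truth_rows.append(("shared", clade))
    for k in range(spec.n_unique):
        leaf = k % spec.n_samples
        rows.append(vaf_row([leaf], "unique"))
        truth_rows.append(("unique", (leaf,)))

    n_var = len(rows)
    ids = [f"v{i:04d}" for i in range(n_var)]
    vaf = pd.DataFrame(np.array(rows), index=ids, columns=samples)
    depth = pd.DataFrame(spec.depth, index=ids, columns=samples)
    refs = rng.choice(list(BASES), size=n_var)
    alts = [rng.choice([b for b in BASES if b != r]) for r in refs]
    ctx = [
        rng.choice(list(BASES)) + r + rng.choice(list(BASES)) for r in refs
    ]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_var + 1) * 1000,
            "ref": refs,
            "alt": alts,
            "context": ctx,
        },
        index=ids,
    )
    prof = MultiregionalMutationProfile(
        case_id=f"fixture{spec.seed}", variants=variants, vaf=vaf, depth=depth
    )
    prof.category = classify_mutations(prof)
    truth = pd.DataFrame(
        {
            "category": [t[0] for t in truth_rows],
            "clade": [";".join(samples[i] for i in t[1]) for t in truth_rows],
        },
        index=ids,
    )
    return prof, truth


#: toy recurrent-region set (arm-level regions with contained focal peaks)
TOY_REGIONS = pd.DataFrame(
    {
        "chrom": ["7", "7", "13", "20", "8", "8"],
        "start": [1, 40_000_001, 1, 30_000_001, 1, 20_000_001],
        "end": [60_000_000, 41_000_000, 50_000_000, 62_000_000, 45_000_000, 21_000_000],
        "scale": ["arm", "focal", "arm", "arm", "arm", "focal"],
        "parent": [None, "7p", None, None, None, "8p"],
    },
    index=pd.Index(["7p", "7p_focal", "13q", "20q", "8p", "8p_focal"], name="region"),
)


def gen_cn_profile(spec: FixtureSpec, regions: pd.DataFrame | None = None):
    """Planted segmented-LRR tables.

    Events are (region_id, branch, magnitude) with branch 'trunk' (all
    samples, a founder event) or an index tuple naming a planted clade (a
    progressor event). Every region is emitted as one segment per sample,
    plus zero-LRR buffer segments so the per-sample median sits at 0.
    Returns (segment table, regions, truth DataFrame)."""
    rng = np.random.default_rng(spec.seed + 1)
    if regions is None:
        regions = TOY_REGIONS
    samples = sample_names(spec.n_samples)
    events = spec.cn_events
    if events is None:
        clades = tree_clades(spec)
        events = [
            ("7p", "trunk", 0.2),
            ("13q", "trunk", -0.18),
            ("20q", clades[0], 0.15),
            ("8p_focal", clades[-1], -0.2),
        ]
    effect = pd.DataFrame(0.0, index=regions.index, columns=samples)
    truth_rows = []
    for rid, branch, mag in events:
        members = samples if branch == "trunk" else [samples[i] for i in branch]
        effect.loc[rid, members] += mag
        truth_rows.append(
            {
                "region": rid,
                "category": "founder" if branch == "trunk" else "progressor",
                "direction": "gain" if mag > 0 else "loss",
                "group": ";".join(members),
                "magnitude": mag,
            }
        )
    seg_rows = []
    # buffer segments on otherwise-quiet chromosomes keep the median at 0
    quiet = [("1", 1, 100_000_000), ("2", 1, 100_000_000), ("3", 1, 100_000_000),
             ("4", 1, 100_000_000), ("5", 1, 100_000_000), ("6", 1, 100_000_000),
             ("9", 1, 100_000_000)]
    for s in samples:
        for rid, reg in regions.iterrows():
            seg_rows.append(
                {
                    "sample": s,
                    "chrom": reg["chrom"],
                    "start": reg["start"],
                    "end": reg["end"],
                    "lrr": effect.loc[rid, s] + rng.normal(0, spec.cn_noise),
                }
            )
        for chrom, start, end in quiet:
            seg_rows.append(
                {"sample": s, "chrom": chrom, "start": start, "end": end,
                 "lrr": rng.normal(0, spec.cn_noise)}
            )
    segments = pd.DataFrame(seg_rows)
    truth = pd.DataFrame(truth_rows)
    return segments, regions, truth


ISLAND_CATEGORIES = ("island", "shore", "open_sea")


def gen_beta_profile(spec: FixtureSpec):
    """Planted methylation beta matrix over several cases.

    Case-level baselines give intertumor clustering; the first case gets
    planted founder hyper/hypo probes (all samples shifted by the effect)
    and planted progressor probes (only a clade of samples shifted).
    Returns (BetaMatrix, truth DataFrame) where truth covers the first
    case's planted calls."""
    rng = np.random.default_rng(spec.seed + 2)
    cases = [f"case{j+1}" for j in range(spec.n_cases)]
    samples, case_of = [], {}
    for c in cases:
        for i in range(spec.samples_per_case):
            s = f"{c}_s{i+1}"
            samples.append(s)
            case_of[s] = c
    probes = [f"p{i:05d}" for i in range(spec.n_probes)]

    normal = pd.DataFrame(
        np.tile(rng.uniform(0.4, 0.6, size=(spec.n_probes, 1)), (1, len(cases))),
        index=probes, columns=cases,
    )
    # intertumor structure: per-case baseline offsets on a probe subset
    beta = pd.DataFrame(0.0, index=probes, columns=samples)
    case_offset = {
        c: rng.normal(0, 0.05, size=spec.n_probes) for c in cases
    }
    for s in samples:
        c = case_of[s]
        beta[s] = normal[c].to_numpy() + case_offset[c] + rng.normal(
            0, spec.meth_noise, size=spec.n_probes
        )

    target_case = cases[0]
    target_samples = [s for s in samples if case_of[s] == target_case]
    # progressor events sit on a balanced split so that the sample-label
    # permutation null is informative even for strong effects
    clade_samples = target_samples[: max(1, len(target_samples) // 2)]

    truth_rows = []
    nf, npg = spec.n_meth_founder, spec.n_meth_progressor
    founder_ids = probes[:nf]
    prog_ids = probes[nf : nf + npg]
    for j, pid in enumerate(founder_ids):
        direction = "hyper" if j % 2 == 0 else "hypo"
        eff = spec.meth_effect if direction == "hyper" else -spec.meth_effect
        beta.loc[pid, target_samples] = normal.loc[pid, target_case] + eff
        truth_rows.append({"probe": pid, "category": "founder", "direction": direction})
    for j, pid in enumerate(prog_ids):
        direction = "hyper" if j % 2 == 0 else "hypo"
        eff = spec.meth_effect if direction == "hyper" else -spec.meth_effect
        beta.loc[pid, clade_samples] = normal.loc[pid, target_case] + eff
        truth_rows.append(
            {"probe": pid, "category": "progressor", "direction": direction}
        )

    beta = beta.clip(0.0, 1.0)
    annot = pd.DataFrame(
        {
            "chrom": rng.choice([str(c) for c in range(1, 23)], size=spec.n_probes),
            "position": rng.integers(1, 10**8, size=spec.n_probes),
            "island": rng.choice(ISLAND_CATEGORIES, size=spec.n_probes),
            "promoter": rng.random(spec.n_probes) < 0.4,
        },
        index=probes,
    )
    bm = BetaMatrix(
        beta=beta,
        normal_beta=normal,
        cases=pd.Series(case_of).reindex(samples),
        probe_annot=annot,
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["case"] = target_case
    truth.attrs["clade_samples"] = clade_samples
    return bm, truth
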