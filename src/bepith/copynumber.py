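"""Founder/progressor copy-number calls from segmented log R ratios (LRR).

Segmented LRR (one table per case: sample, chrom, start, end, lrr;
coordinates 1-based inclusive) is median-centered per sample and averaged
over predefined recurrent chromosomal regions (arm-level and focal, with
focal-in-arm containment links). A region is a founder alteration when all
samples agree in sign, |LRR| > 0.06 in every sample and |LRR| > 0.12 in at
least one. Progressor alterations are regions whose maximal between-group
mean difference over the sample-tree bipartitions exceeds |dLRR| > 0.06.
A focal call contained in an arm-level call of the same category is
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

T_HIGH = 0.12
T_LOW = 0.06
T_DELTA = 0.06


@dataclass
class RegionLRRMatrix:
    regions: pd.DataFrame   # index=id; chrom, start, end, scale {arm, focal}, parent
    lrr: pd.DataFrame       # regions x samples, median-centered


@dataclass
class CNAlterationCall:
    region_id: str
    category: str           # founder / progressor
    direction: str          # gain / loss
    scale: str              # arm / focal
    statistic: float        # max |LRR| (founder) or dLRR (progressor), signed
    bipartition: tuple | None = None


def region_mean_lrr(segments: pd.DataFrame, regions: pd.DataFrame) -> RegionLRRMatrix:
    """Length-weighted mean segment LRR per region per sample, after
    per-sample median centering. Regions a sample's segments do not touch
    become NaN (excluded from calls, with a warning)."""
    req = {"sample", "chrom", "start", "end", "lrr"}
    if not req <= set(segments.columns):
        raise ValueError(f"segment table needs columns {sorted(req)}")
    samples = sorted(segments["sample"].unique())
    out = pd.DataFrame(np.nan, index=regions.index, columns=samples)
    for sample, seg in segments.groupby("sample"):
        lrr = seg["lrr"].to_numpy(float)
        centered = lrr - np.median(lrr)
        s0 = seg["start"].to_numpy(float)
        s1 = seg["end"].to_numpy(float) + 1.0  # to half-open
        chrom = seg["chrom"].to_numpy()
        for rid, reg in regions.iterrows():
            mask = chrom == reg["chrom"]
            if not mask.any():
                continue
            ov = np.minimum(s1[mask], float(reg["end"]) + 1.0) - np.maximum(
                s0[mask], float(reg["start"])
            )
            ov = np.clip(ov, 0.0, None)
            w = ov.sum()
            if w > 0:
                out.loc[rid, sample] = float((centered[mask] * ov).sum() / w)
    missing = out.isna().any(axis=1)
    for rid in out.index[missing]:
        log.warning("region %s lacks segment coverage in >=1 sample; excluded", rid)
    return RegionLRRMatrix(regions=regions, lrr=out)


def call_founder_cn(
    matrix: RegionLRRMatrix, t_high: float = T_HIGH, t_low: float = T_LOW
) -> list[CNAlterationCall]:
    """Founder call: one shared sign, |LRR| > t_low everywhere, and
    |LRR| > t_high in at least one sample."""
    calls = []
    for rid, row in matrix.lrr.iterrows():
        v = row.to_numpy(float)
        if np.isnan(v).any():
            continue
        if (np.abs(v) > t_low).all() and (np.abs(v) > t_high).any() and (
            (v > 0).all() or (v < 0).all()
        ):
            stat = v[np.argmax(np.abs(v))]
            calls.append(
                CNAlterationCall(
                    region_id=rid,
                    category="founder",
                    direction="gain" if stat > 0 else "loss",
                    scale=matrix.regions.loc[rid, "scale"],
                    statistic=float(stat),
                )
            )
    return calls


def call_progressor_cn(
    matrix: RegionLRRMatrix,
    bipartitions: list[tuple[frozenset, frozenset]],
    t_delta: float = T_DELTA,
    exclude: set | None = None,
) -> list[CNAlterationCall]:
    """Progressor call: max-|difference| of group-mean LRR over the tree
    bipartitions exceeds t_delta. Regions in ``exclude`` (typically those
    already called founder) are skipped. Direction comes from the sign of
    the altered group's mean (the side with the larger |mean|)."""
    exclude = exclude or set()
    if not bipartitions:
        raise ValueError("need at least one bipartition")
    calls = []
    for rid, row in matrix.lrr.iterrows():
        if rid in exclude:
            continue
        v = row
        if v.isna().any():
            continue
        best = None
        for a, b in bipartitions:
            ma = float(v[list(a)].mean())
            mb = float(v[list(b)].mean())
            d = ma - mb
            if best is None or abs(d) > abs(best[0]):
                altered, other = (a, b) if abs(ma) >= abs(mb) else (b, a)
                altered_mean = ma if altered is a else mb
                best = (d, (altered, other), altered_mean)
        d, bip, altered_mean = best
        if abs(d) > t_delta:
            calls.append(
                CNAlterationCall(
                    region_id=rid,
                    category="progressor",
                    direction="gain" if altered_mean > 0 else "loss",
                    scale=matrix.regions.loc[rid, "scale"],
                    statistic=float(d),
                    bipartition=bip,
                )
            )
    return calls


def resolve_focal_vs_arm(
    calls: list[CNAlterationCall], regions: pd.DataFrame
) -> list[CNAlterationCall]:
    """Drop a focal call whose containing arm region carries a call of the
    same category."""
    called = {(c.region_id, c.category) for c in calls}
    kept = []
    for c in calls:
        if c.scale == "focal":
            parent = regions.loc[c.region_id].get("parent")
            if parent and not pd.isna(parent) and (parent, c.category) in called:
                continue
        kept.append(c)
    return kept


def calls_to_frame(calls: list[CNAlterationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "region": c.region_id,
                "category": c.category,
                "direction": c.direction,
                "scale": c.scale,
                "statistic": c.statistic,
                "group": ";".join(sorted(map(str, c.bipartition[0]))) if c.bipartition else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["region", "category", "direction", "scale", "statistic", "group"]
    )
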