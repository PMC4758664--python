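"""Multiregional mutation profiles: rescue-and-filter construction,
founder/shared/unique classification, heat-map ordering, PCA color codes
and mutation-spectrum tabulation.

A variant called in any sample of a case is kept only if its read depth is
at least ``min_depth`` in every sample (so absence is trustworthy); it is
"present" in a sample when its VAF strictly exceeds ``vaf_threshold``.
Variants present in all samples are founder mutations; the rest are
progressor mutations, split into shared (>=2 samples) and unique (exactly
one sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

MIN_DEPTH = 10
VAF_THRESHOLD = 0.05

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class MultiregionalMutationProfile:
    case_id: str
    variants: pd.DataFrame        # index = variant ids; chrom, pos, ref, alt[, context]
    vaf: pd.DataFrame             # variants x samples
    depth: pd.DataFrame           # variants x samples
    category: pd.Series = None    # founder / shared / unique per variant

    @property
    def sample_ids(self) -> list:
        return list(self.vaf.columns)

    def presence(self) -> pd.DataFrame:
        return self.vaf > VAF_THRESHOLD


def build_profile(
    raw_calls: pd.DataFrame | None,
    vaf_all: pd.DataFrame,
    depth_all: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    vaf_threshold: float = VAF_THRESHOLD,
    case_id: str = "case",
    variants: pd.DataFrame | None = None,
) -> MultiregionalMutationProfile:
    """Rescue-and-filter a per-case variant set into a profile.

    ``raw_calls`` (optional) is a boolean variants x samples called-mask;
    variants called nowhere are dropped. Variants with depth < min_depth in
    any sample are dropped entirely; presence per sample is VAF strictly
    greater than ``vaf_threshold``; variants present nowhere are dropped.
    """
    if not vaf_all.index.equals(depth_all.index) or not vaf_all.columns.equals(
        depth_all.columns
    ):
        raise ValueError("vaf and depth matrices must share variant and sample ids")
    if vaf_all.isna().any().any() or depth_all.isna().any().any():
        raise ValueError("missing VAF/depth entries")

    keep = depth_all.min(axis=1) >= min_depth
    if raw_calls is not None:
        keep &= raw_calls.reindex(vaf_all.index).fillna(False).any(axis=1)
    vaf = vaf_all.loc[keep]
    present = vaf > vaf_threshold
    keep2 = present.any(axis=1)
    vaf = vaf.loc[keep2]
    depth = depth_all.loc[vaf.index]
    if variants is None:
        variants = pd.DataFrame(index=vaf.index)
    else:
        variants = variants.loc[vaf.index]
    prof = MultiregionalMutationProfile(
        case_id=case_id, variants=variants, vaf=vaf, depth=depth
    )
    prof.category = classify_mutations(prof)
    return prof


def classify_mutations(profile: MultiregionalMutationProfile) -> pd.Series:
    """founder = present in all samples; unique = exactly one; shared = rest."""
    present = profile.presence()
    n = present.shape[1]
    counts = present.sum(axis=1)
    cat = pd.Series("shared", index=present.index, dtype=object)
    cat[counts == n] = "founder"
    cat[counts == 1] = "unique"
    cat[counts == 0] = "absent"  # defensive; build_profile drops these
    return cat


def category_counts(profile: MultiregionalMutationProfile) -> dict:
    c = profile.category.value_counts()
    return {k: int(c.get(k, 0)) for k in ("founder", "shared", "unique")}


def heatmap_order(profile: MultiregionalMutationProfile) -> list:
    """Row order for heat maps: founder mutations by chromosomal position,
    shared mutations by hierarchical clustering of their VAF vectors,
    unique mutations by sample then VAF."""
    cat = profile.category
    vaf = profile.vaf
    order: list = []

    founder = cat[cat == "founder"].index
    if "chrom" in profile.variants.columns and "pos" in profile.variants.columns:
        fv = profile.variants.loc[founder]
        order += list(fv.sort_values(["chrom", "pos"]).index)
    else:
        order += sorted(founder)

    shared = list(cat[cat == "shared"].index)
    if len(shared) > 2:
        Z = linkage(vaf.loc[shared].to_numpy(), method="average")
        shared = [shared[i] for i in leaves_list(Z)]
    order += shared

    unique = cat[cat == "unique"].index
    if len(unique):
        present = profile.presence().loc[unique]
        which = present.to_numpy().argmax(axis=1)
        vmax = vaf.loc[unique].to_numpy().max(axis=1)
        idx = np.lexsort((-vmax, which))
        order += [unique[i] for i in idx]
    return order


def color_code_samples(profile: MultiregionalMutationProfile | pd.DataFrame) -> pd.DataFrame:
    """RGB color per sample from the first three principal components of
    the VAF profile, min-max scaled to [0, 255] per channel.

    Identical profiles get identical colors; a zero-variance profile gets
    a uniform neutral gray.
    """
    vaf = profile.vaf if isinstance(profile, MultiregionalMutationProfile) else profile
    X = vaf.to_numpy().T  # samples x variants
    samples = list(vaf.columns)
    n_comp = min(3, X.shape[0], X.shape[1])
    rgb = np.full((len(samples), 3), 128.0)
    if np.allclose(X.var(axis=0), 0):
        return pd.DataFrame(rgb.astype(int), index=samples, columns=["R", "G", "B"])
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(X)
    total_span = np.abs(scores).max()
    for j in range(scores.shape[1]):
        col = scores[:, j]
        span = col.max() - col.min()
        # a numerically-degenerate component carries no signal to scale
        if span <= 1e-9 * max(total_span, 1.0):
            rgb[:, j] = 128.0
        else:
            rgb[:, j] = (col - col.min()) / span * 255.0
    return pd.DataFrame(np.rint(rgb).astype(int), index=samples, columns=["R", "G", "B"])


def _pyrimidine_context(ref: str, alt: str, context: str | None):
    """Collapse a substitution (with optional trinucleotide context) onto
    the pyrimidine strand. Returns (class, cpg_flag, channel) or None for
    ambiguous bases."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    ctx = context.upper() if context else None
    if ctx is not None and (len(ctx) != 3 or any(b not in _COMPLEMENT for b in ctx)):
        return None
    if ref in ("G", "A"):  # purine: reverse-complement
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        if ctx is not None:
            ctx = "".join(_COMPLEMENT[b] for b in reversed(ctx))
    sub = f"{ref}>{alt}"
    cpg = None
    if ctx is not None:
        if ctx[1] != ref:
            return None
        cpg = ref == "C" and ctx[2] == "G"
        channel = f"{ctx[0]}[{sub}]{ctx[2]}"
    else:
        channel = None
    return sub, cpg, channel


def trinucleotide_channels() -> list[str]:
    bases = "ACGT"
    return [
        f"{five}[{sub}]{three}"
        for sub in PYRIMIDINE_CLASSES
        for five in bases
        for three in bases
    ]


def mutation_spectrum(variants: pd.DataFrame) -> dict:
    """Substitution-spectrum proportions of a mutation set.

    Returns {'six_class': Series over the 6 pyrimidine classes with C>*
    classes split by CpG context when contexts are available, 'channels':
    Series over the 96 trinucleotide channels (None without contexts)}.
    Variants with ambiguous bases are skipped with a warning.
    """
    has_ctx = "context" in variants.columns
    six: dict[str, int] = {}
    chan: dict[str, int] = {}
    n_used = 0
    for _, row in variants.iterrows():
        res = _pyrimidine_context(
            row["ref"], row["alt"], row["context"] if has_ctx else None
        )
        if res is None:
            log.warning("skipping variant with ambiguous bases: %s", dict(row))
            continue
        sub, cpg, channel = res
        n_used += 1
        if cpg is None:
            label = sub
        elif sub.startswith("C>"):
            label = f"{sub} at CpG" if cpg else sub
        else:
            label = sub
        six[label] = six.get(label, 0) + 1
        if channel is not None:
            chan[channel] = chan.get(channel, 0) + 1
    if n_used == 0:
        raise ValueError("no usable variants for spectrum")
    six_s = pd.Series(six, dtype=float) / n_used
    channels = None
    if has_ctx and chan:
        channels = pd.Series(
            {c: chan.get(c, 0) / n_used for c in trinucleotide_channels()}, dtype=float
        )
    return {"six_class": six_s, "channels": channels}
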