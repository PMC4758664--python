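"""Readers and writers for the TSV/SEG/Newick/config artifacts.

Conventions: all tables are tab-separated with a header; genomic
coordinates are 1-based inclusive (converted to half-open only internally);
all writers are deterministic. Readers validate required columns and reject
NaN or out-of-range values with actionable messages.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VARIANT_COLUMNS = ["case", "sample", "chrom", "pos", "ref", "alt", "alt_reads", "depth"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "lrr"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_variant_table(path) -> dict:
    """Long-format variant TSV -> per-case vaf/depth matrices.

    Required columns: case, sample, chrom, pos, ref, alt, alt_reads,
    depth; an optional precomputed `vaf` column wins over alt_reads/depth.
    Returns {case: {"vaf": DataFrame, "depth": DataFrame, "variants":
    DataFrame}} with variant ids "chrom:pos:ref>alt".
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, VARIANT_COLUMNS, path)
    if df[["alt_reads", "depth"]].isna().any().any():
        bad = df.index[df[["alt_reads", "depth"]].isna().any(axis=1)][0]
        raise ValueError(f"{path}: NaN read counts at data row {bad + 1}")
    if (df["depth"] <= 0).any():
        bad = df.index[df["depth"] <= 0][0]
        raise ValueError(f"{path}: depth must be positive (data row {bad + 1})")
    if (df["alt_reads"] > df["depth"]).any():
        bad = df.index[df["alt_reads"] > df["depth"]][0]
        raise ValueError(f"{path}: alt_reads > depth at data row {bad + 1}")
    if "vaf" not in df.columns:
        df["vaf"] = df["alt_reads"] / df["depth"]
    df["variant_id"] = (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref"]
        + ">"
        + df["alt"]
    )
    out = {}
    for case, sub in df.groupby("case"):
        vaf = sub.pivot_table(index="variant_id", columns="sample", values="vaf",
                              aggfunc="first")
        depth = sub.pivot_table(index="variant_id", columns="sample", values="depth",
                                aggfunc="first")
        variants = (
            sub.drop_duplicates("variant_id")
            .set_index("variant_id")[
                ["chrom", "pos", "ref", "alt"]
                + (["context"] if "context" in sub.columns else [])
            ]
            .loc[vaf.index]
        )
        out[str(case)] = {
            "vaf": vaf.fillna(0.0),
            "depth": depth.fillna(0).astype(int),
            "variants": variants,
        }
    return out


def write_variant_table(path, profile) -> None:
    """Inverse of read_variant_table for one profile (long format)."""
    rows = []
    for vid in profile.vaf.index:
        meta = profile.variants.loc[vid] if len(profile.variants.columns) else None
        for s in profile.vaf.columns:
            depth = int(profile.depth.loc[vid, s])
            rows.append(
                {
                    "case": profile.case_id,
                    "sample": s,
                    "chrom": meta["chrom"] if meta is not None else "NA",
                    "pos": meta["pos"] if meta is not None else 0,
                    "ref": meta["ref"] if meta is not None and "ref" in meta else "N",
                    "alt": meta["alt"] if meta is not None and "alt" in meta else "N",
                    "alt_reads": int(round(profile.vaf.loc[vid, s] * depth)),
                    "depth": depth,
                    "vaf": profile.vaf.loc[vid, s],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """SEG-style TSV (sample, chrom, start, end, lrr), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SEG_COLUMNS, path)
    if df["lrr"].isna().any():
        raise ValueError(f"{path}: NaN LRR values")
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: segment end < start")
    return df


def write_seg(path, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    """Region table: region, chrom, start, end, scale, parent."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "parent": str})
    _require_columns(df, ["region", "chrom", "start", "end", "scale"], path)
    bad = ~df["scale"].isin(["arm", "focal"])
    if bad.any():
        raise ValueError(f"{path}: scale must be 'arm' or 'focal'")
    if "parent" not in df.columns:
        df["parent"] = None
    return df.set_index("region")


def read_matrix(path) -> pd.DataFrame:
    """Generic probes/genes x samples TSV matrix with index in column 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains NaN")
    return df


def write_matrix(path, df: pd.DataFrame, index_label="id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path) -> pd.Series:
    """Sample sheet TSV (sample, case) -> Series sample -> case."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "case"], path)
    return df.set_index("sample")["case"]


def write_newick(path_or_none, tree) -> str:
    text = tree.newick()
    if path_or_none is not None:
        Path(path_or_none).write_text(text + "\n")
    return text


def write_calls(path, calls_frame: pd.DataFrame) -> None:
    calls_frame.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_run_metadata(out_dir, command: str, params: dict, seed=None) -> Path:
    """Every run echoes its resolved parameters for reproducibility."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "python": sys.version.split()[0],
    }
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (Path,)):
        return str(v)
    return v
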