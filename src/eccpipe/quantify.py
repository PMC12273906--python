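"""Normalized eccDNA abundance tables.

Two distinct denominators exist and are kept strictly apart:

* window profiles: counts per fixed-size chromosome window divided by the
  replicate's **total eccDNA reads**, times 100;
* TE/family/superfamily abundance: group counts divided by the sample's
  **total CCS reads**, times 100 (scales abundance to sequencing depth).

Outputs name their denominator explicitly so the two normalizations can
never be mixed silently.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["sample_id", "condition", "replicate",
                    "total_ccs_reads", "total_eccdna_reads"]


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if (manifest["total_eccdna_reads"] > manifest["total_ccs_reads"]).any():
        raise ValueError("total_eccdna_reads cannot exceed total_ccs_reads")
    dup = manifest.duplicated(subset=["condition", "replicate"])
    if dup.any():
        raise ValueError("replicate indices must be unique within a condition")
    return manifest


def window_profile(annotations: pd.DataFrame, manifest: pd.DataFrame,
                   window_size: int = 100_000,
                   chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-window normalized eccDNA profile, one row per window x sample.

    normalized = window count / total eccDNA reads of that replicate x 100.
    Zero-count windows are present with value 0 when ``chrom_lengths`` is
    given (every window of every chromosome is materialized).
    """
    validate_manifest(manifest)
    if (manifest["total_eccdna_reads"] <= 0).any():
        bad = manifest.loc[manifest["total_eccdna_reads"] <= 0, "sample_id"].tolist()
        raise ValueError(f"total_eccdna_reads is zero for sample(s): {bad}")
    required = {"sample_id", "window_chrom", "window_bin"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations missing columns: {sorted(required - set(annotations.columns))}")

    counts = (annotations.groupby(["sample_id", "window_chrom", "window_bin"])
              .size().rename("raw_count").reset_index())
    if chrom_lengths is not None:
        windows = [(c, b) for c, ln in chrom_lengths.items()
                   for b in range(math.ceil(ln / window_size))]
        grid = pd.MultiIndex.from_tuples(
            [(s, c, b) for s in manifest["sample_id"] for c, b in windows],
            names=["sample_id", "window_chrom", "window_bin"])
        counts = (counts.set_index(["sample_id", "window_chrom", "window_bin"])
                  .reindex(grid, fill_value=0).reset_index())
    out = counts.merge(manifest, on="sample_id", how="left")
    out["normalized"] = out["raw_count"] / out["total_eccdna_reads"] * 100.0
    out["denominator"] = "total_eccdna_reads"
    out["window_start"] = out["window_bin"] * window_size
    out["window_end"] = (out["window_bin"] + 1) * window_size
    if chrom_lengths is not None:
        out["window_end"] = [min(e, chrom_lengths[c]) for c, e in
                             zip(out["window_chrom"], out["window_end"])]
    return out[["window_chrom", "window_bin", "window_start", "window_end",
                "sample_id", "condition", "replicate", "raw_count",
                "normalized", "denominator"]]


def te_abundance(annotations: pd.DataFrame, manifest: pd.DataFrame,
                 axis: str = "superfamily",
                 family_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Normalized TE-derived eccDNA abundance per ``axis`` group x sample.

    normalized = TE-derived reads in group / total CCS reads x 100.
    ``axis`` is one of {"te", "family", "superfamily"}.
    """
    validate_manifest(manifest)
    if (manifest["total_ccs_reads"] <= 0).any():
        raise ValueError("manifest total_ccs_reads must be positive")
    col = {"te": "te_id", "family": "te_family", "superfamily": "te_superfamily"}.get(axis)
    if col is None:
        raise ValueError(f"axis must be te, family or superfamily, got {axis!r}")
    te_rows = annotations[annotations["origin_class"] == "TE"].copy()
    if axis == "superfamily" and family_map is not None:
        te_rows["te_superfamily"] = te_rows["te_family"].map(family_map).fillna("unclassified")
    counts = (te_rows.groupby(["sample_id", col]).size()
              .rename("raw_count").reset_index()
              .rename(columns={col: "group"}))
    groups = sorted(counts["group"].unique())
    grid = pd.MultiIndex.from_product([manifest["sample_id"], groups],
                                      names=["sample_id", "group"])
    counts = (counts.set_index(["sample_id", "group"])
              .reindex(grid, fill_value=0).reset_index())
    out = counts.merge(manifest, on="sample_id", how="left")
    out["normalized"] = out["raw_count"] / out["total_ccs_reads"] * 100.0
    out["axis"] = axis
    out["denominator"] = "total_ccs_reads"
    return out[["axis", "group", "sample_id", "condition", "replicate",
                "raw_count", "normalized", "denominator"]]


def fold_change(table_a: pd.DataFrame, table_b: pd.DataFrame,
                pseudo: float = 0.0) -> pd.DataFrame:
    """Per-group fold change of normalized values between two abundance
    tables sharing an axis (values are first averaged over samples within
    each table). ``pseudo`` = 0 yields explicit NA for zero denominators."""
    if "axis" in table_a.columns and "axis" in table_b.columns:
        if set(table_a["axis"]) != set(table_b["axis"]):
            raise ValueError("fold_change requires tables on the same axis")
    a = table_a.groupby("group")["normalized"].mean()
    b = table_b.groupby("group")["normalized"].mean()
    keys = sorted(set(a.index) | set(b.index))
    rows = []
    for key in keys:
        va = float(a.get(key, 0.0)) + pseudo
        vb = float(b.get(key, 0.0)) + pseudo
        if vb == 0.0:
            warnings.warn(f"zero denominator for group {key!r}; fold change is NA")
            fold = log2 = float("nan")
        else:
            fold = va / vb
            log2 = math.log2(fold) if fold > 0 else float("nan")
        rows.append({"group": key, "value_a": va, "value_b": vb,
                     "fold": fold, "log2_fold": log2})
    return pd.DataFrame(rows)


def replicate_summary(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean and standard deviation (n-1 denominator) of normalized values
    across replicates, for error bars."""
    if by is None:
        by = [c for c in ("group", "window_chrom", "window_bin", "condition")
              if c in table.columns]
    g = table.groupby(by)["normalized"]
    out = g.agg(mean="mean", sd=lambda x: np.std(x, ddof=1) if len(x) > 1 else 0.0,
                n="size").reset_index()
    return out
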