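"""Inferential layer: enrichment, group comparisons, correlations.

Implements the downstream statistics of the eccDNA profiling study:
TE-superfamily enrichment of eccDNA-derived reads against the genomic TE
composition (exact two-sided binomial tests, optional Benjamini-Hochberg
correction), condition comparisons (Welch t-test for two groups, one-way
ANOVA for three or more), per-window correlation with epigenetic tracks
or transcript fold changes (Pearson), long-inverted-repeat (LIR) overlap
counting, and the centromeric-vs-non-centromeric partition test.

The exact binomial p-value is computed by direct pmf summation (outcomes
whose pmf does not exceed the observed outcome's pmf), the definition the
package's calibration invariants are written against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simdata import TEFeature

ALPHA_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# Genomic composition
# ---------------------------------------------------------------------------

@dataclass
class GenomicComposition:
    """Per-group TE composition of the genome (counts and bp)."""

    table: pd.DataFrame  # columns: group, element_count, total_bp, fraction_by_count, fraction_by_bp
    level: str  # family | superfamily

    def fraction(self, group: str, basis: str = "count") -> float:
        col = "fraction_by_count" if basis == "count" else "fraction_by_bp"
        row = self.table.loc[self.table["group"] == group, col]
        return float(row.iloc[0]) if len(row) else 0.0


def genomic_composition(te_features: list[TEFeature], level: str = "superfamily"
                        ) -> GenomicComposition:
    """Element counts, bp totals, and both count- and bp-based fractions per
    TE family or superfamily."""
    if not te_features:
        raise ValueError("genomic_composition requires a non-empty TE annotation")
    key = (lambda t: t.superfamily) if level == "superfamily" else (lambda t: t.family)
    rows: dict[str, dict] = {}
    for t in te_features:
        g = key(t)
        r = rows.setdefault(g, {"group": g, "element_count": 0, "total_bp": 0})
        r["element_count"] += 1
        r["total_bp"] += t.length
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["group"]))
    df["fraction_by_count"] = df["element_count"] / df["element_count"].sum()
    df["fraction_by_bp"] = df["total_bp"] / df["total_bp"].sum()
    return GenomicComposition(table=df, level=level)


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------

def binomial_p_two_sided(observed: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value by pmf summation.

    Sums Binomial(n, p) pmf over all outcomes whose pmf is <= the observed
    outcome's pmf (with a 1e-12 relative slack for floating-point ties).
    """
    if not 0 <= observed <= n:
        raise ValueError("observed must lie in [0, n]")
    if p <= 0.0:
        return 1.0 if observed == 0 else np.nextafter(0.0, 1.0)
    if p >= 1.0:
        return 1.0 if observed == n else np.nextafter(0.0, 1.0)
    pmf = sps.binom.pmf(np.arange(n + 1), n, p)
    threshold = pmf[observed] * (1.0 + 1e-12)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


@dataclass
class EnrichmentResult:
    group: str
    observed: int
    n_total: int
    expected_fraction: float
    p_value: float
    adjusted_p: float
    direction: str  # over | under | none


def enrichment_test(observed: dict[str, int], n_total: int,
                    composition: GenomicComposition, basis: str = "count",
                    alpha: float = ALPHA_DEFAULT, correction: str = "bh"
                    ) -> list[EnrichmentResult]:
    """Per-group exact binomial enrichment of observed counts against the
    genomic composition.

    ``correction`` is "bh" (Benjamini-Hochberg) or "none" (bare p < alpha,
    matching analyses that report unadjusted p-values).
    """
    if sum(observed.values()) > n_total:
        raise ValueError("sum of observed counts exceeds n_total")
    groups = sorted(observed)
    pvals = []
    for g in groups:
        exp = composition.fraction(g, basis)
        if exp <= 0.0 and observed[g] > 0:
            import warnings
            warnings.warn(f"group {g!r} has zero expected fraction but nonzero observations")
        pvals.append(binomial_p_two_sided(observed[g], n_total, exp))
    if correction == "bh":
        adj = multipletests(pvals, method="fdr_bh")[1]
    elif correction == "none":
        adj = list(pvals)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    results = []
    for g, p, ap in zip(groups, pvals, adj):
        exp = composition.fraction(g, basis)
        frac = observed[g] / n_total if n_total else 0.0
        if ap < alpha and frac > exp:
            direction = "over"
        elif ap < alpha and frac < exp:
            direction = "under"
        else:
            direction = "none"
        results.append(EnrichmentResult(g, observed[g], n_total, exp, p, float(ap), direction))
    return results


# ---------------------------------------------------------------------------
# Group comparison (t-test / ANOVA)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str  # welch_t | anova
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    significant: bool


def compare_groups(groups: dict[str, list[float]], alpha: float = ALPHA_DEFAULT
                   ) -> GroupComparison:
    """Two groups -> Welch two-sample t-test; three or more -> one-way ANOVA."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("compare_groups requires at least two groups")
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs >=2 replicates")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) == 2:
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
        df = float(res.df)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # both groups constant and equal
            stat, p = 0.0, 1.0
        return GroupComparison("welch_t", stat, df, p, p < alpha)
    stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return GroupComparison("anova", float(stat), (k - 1, n - k), float(p), p < alpha)


# ---------------------------------------------------------------------------
# Window correlations
# ---------------------------------------------------------------------------

@dataclass
class TrackCorrelation:
    track: str
    n_windows: int
    pearson_r: float
    r_squared: float
    p_value: float
    n_excluded: int = 0


def correlate_windows(profile: pd.DataFrame, track: pd.DataFrame,
                      track_name: str = "track") -> TrackCorrelation:
    """Pearson correlation between a per-window eccDNA profile and a
    per-window track, inner-joined on (window_chrom, window_bin).

    ``profile`` needs columns window_chrom, window_bin, normalized;
    ``track`` needs window_chrom, window_bin, value. Windows missing from
    either side are excluded and counted. Zero variance on either side
    yields an explicit NA result.
    """
    keys = ["window_chrom", "window_bin"]
    p = profile.groupby(keys)["normalized"].mean().rename("x").reset_index()
    t = track.groupby(keys)["value"].mean().rename("y").reset_index()
    joined = p.merge(t, on=keys, how="inner")
    n_excluded = (len(p) - len(joined)) + (len(t) - len(joined))
    if len(joined) < 3:
        raise ValueError("correlate_windows requires >=3 shared windows")
    x = joined["x"].to_numpy()
    y = joined["y"].to_numpy()
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return TrackCorrelation(track_name, len(joined), float("nan"),
                                float("nan"), float("nan"), n_excluded)
    r, pval = sps.pearsonr(x, y)
    r = float(r)
    if 1.0 - abs(r) < 1e-12:  # exactly affine data: snap rounding residue
        r = math.copysign(1.0, r)
    return TrackCorrelation(track_name, len(joined), r, r ** 2,
                            float(pval), n_excluded)


# ---------------------------------------------------------------------------
# LIR overlap
# ---------------------------------------------------------------------------

def lir_overlap(annotations: pd.DataFrame, lir_intervals: pd.DataFrame,
                min_overlap: int = 1) -> pd.DataFrame:
    """Per-sample counts of LIR-derived eccDNAs and each sample's share of
    the total across samples.

    A monomer is LIR-derived iff its best locus overlaps any long-inverted-
    repeat interval by >= ``min_overlap`` bp. ``lir_intervals`` uses BED
    columns (chrom, start, end), 0-based half-open.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in lir_intervals.iterrows():
        by_chrom.setdefault(row["chrom"], []).append((int(row["start"]), int(row["end"])))
    for ivs in by_chrom.values():
        ivs.sort()

    def is_lir(chrom, start, end):
        for lo, hi in by_chrom.get(chrom, ()):
            if lo >= end:
                break
            if min(end, hi) - max(start, lo) >= min_overlap:
                return True
        return False

    ann = annotations.copy()
    ann["lir_derived"] = [is_lir(c, s, e) for c, s, e in
                          zip(ann["chrom"], ann["start"], ann["end"])]
    counts = (ann.groupby("sample_id")
              .agg(total=("monomer_id", "size"), lir_derived=("lir_derived", "sum"))
              .reset_index())
    grand = counts["lir_derived"].sum()
    counts["share_of_total_lir_pct"] = (
        counts["lir_derived"] / grand * 100.0 if grand else 0.0)
    return counts


# ---------------------------------------------------------------------------
# Centromeric partition
# ---------------------------------------------------------------------------

def _in_centromere(chrom, start, end, centromeres: dict[str, tuple[int, int]]) -> bool:
    iv = centromeres.get(chrom)
    if iv is None:
        return False
    mid = (start + end) // 2
    return iv[0] <= mid < iv[1]


def centromeric_partition(annotations: pd.DataFrame,
                          centromere_intervals: dict[str, tuple[int, int]],
                          te_features: list[TEFeature],
                          group_by: str = "family",
                          alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Per-family eccDNA counts from centromeric vs non-centromeric loci,
    with an exact binomial test of the centromeric share against the
    family's genomic centromeric copy fraction.

    A locus (or TE copy) counts as centromeric when its midpoint falls in
    the chromosome's centromere interval. Families with zero genomic copies
    are skipped with a warning.
    """
    col = "te_family" if group_by == "family" else "te_superfamily"
    te_key = (lambda t: t.family) if group_by == "family" else (lambda t: t.superfamily)

    genome_counts: dict[str, list[int]] = {}
    for t in te_features:
        cen = _in_centromere(t.chrom, t.start, t.end, centromere_intervals)
        g = genome_counts.setdefault(te_key(t), [0, 0])
        g[0 if cen else 1] += 1

    te_ann = annotations[annotations["origin_class"] == "TE"]
    rows = []
    for group, sub in te_ann.groupby(col):
        if group not in genome_counts:
            import warnings
            warnings.warn(f"{group_by} {group!r} has no genomic copies; skipped")
            continue
        cen_g, arm_g = genome_counts[group]
        genome_frac = cen_g / (cen_g + arm_g)
        cen_n = int(sum(_in_centromere(c, s, e, centromere_intervals)
                        for c, s, e in zip(sub["chrom"], sub["start"], sub["end"])))
        n = len(sub)
        p = binomial_p_two_sided(cen_n, n, genome_frac)
        frac = cen_n / n if n else 0.0
        if p < alpha and frac > genome_frac:
            direction = "over"
        elif p < alpha and frac < genome_frac:
            direction = "under"
        else:
            direction = "none"
        rows.append({"group": group, "eccdna_centromeric": cen_n,
                     "eccdna_non_centromeric": n - cen_n,
                     "eccdna_centromeric_fraction": frac,
                     "genome_centromeric_fraction": genome_frac,
                     "p_value": p, "direction": direction})
    return pd.DataFrame(rows, columns=["group", "eccdna_centromeric",
                                       "eccdna_non_centromeric",
                                       "eccdna_centromeric_fraction",
                                       "genome_centromeric_fraction",
                                       "p_value", "direction"])


def partition_by_chromosome(annotations: pd.DataFrame, group_by: str = "family"
                            ) -> pd.DataFrame:
    """Stacked per-chromosome eccDNA counts per TE family/superfamily."""
    col = "te_family" if group_by == "family" else "te_superfamily"
    te_ann = annotations[annotations["origin_class"] == "TE"]
    return (te_ann.groupby(["chrom", col]).size()
            .rename("eccdna_count").reset_index())
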