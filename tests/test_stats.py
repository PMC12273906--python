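"""Inferential layer: enrichment, comparisons, correlations, partitions."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eccpipe import stats as st
from eccpipe.simdata import TEFeature


def _te(family, superfamily, chrom="chr1", start=0, end=1000):
    return TEFeature(f"TE_{family}_{start}", family, superfamily, chrom, start, end, "+")


class TestGenomicComposition:
    def test_single_superfamily_fraction_one(self):
        comp = st.genomic_composition([_te("F", "RC/Helitron", start=i * 2000, end=i * 2000 + 500)
                                       for i in range(3)])
        assert comp.fraction("RC/Helitron", "count") == 1.0
        assert comp.fraction("RC/Helitron", "bp") == 1.0

    def test_fractions_sum_to_one(self):
        tes = ([_te("F", "RC/Helitron", start=i * 3000, end=i * 3000 + 700) for i in range(4)]
               + [_te("G", "LTR/Gypsy", start=50_000 + i * 3000, end=50_000 + i * 3000 + 2000)
                  for i in range(2)])
        comp = st.genomic_composition(tes)
        assert comp.table["fraction_by_count"].sum() == pytest.approx(1.0, abs=1e-9)
        assert comp.table["fraction_by_bp"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_bp_fractions_match_bruteforce_interval_sum(self):
        tes = [_te("F", "RC/Helitron", start=0, end=700),
               _te("G", "LTR/Gypsy", start=1000, end=4000),
               _te("G2", "LTR/Gypsy", start=5000, end=5600)]
        comp = st.genomic_composition(tes)
        total = sum(t.end - t.start for t in tes)
        gypsy = sum(t.end - t.start for t in tes if t.superfamily == "LTR/Gypsy")
        assert comp.fraction("LTR/Gypsy", "bp") == pytest.approx(gypsy / total, abs=1e-12)

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            st.genomic_composition([])


def _bruteforce_binom_p(k, n, p):
    """Exact rational two-sided binomial p: sum of pmf over outcomes whose
    pmf does not exceed pmf(k)."""
    pf = Fraction(p).limit_denominator(10**6)
    pmf = [Fraction(math.comb(n, i)) * pf**i * (1 - pf)**(n - i) for i in range(n + 1)]
    return float(sum(q for q in pmf if q <= pmf[k]))


class TestExactBinomial:
    @pytest.mark.parametrize("k,n,p", [
        (30, 100, 0.2), (0, 50, 0.1), (50, 50, 0.9), (7, 20, 0.35),
        (250, 500, 0.45), (10, 500, 0.05), (123, 321, 0.5),
    ])
    def test_matches_bruteforce_pmf_summation(self, k, n, p):
        assert st.binomial_p_two_sided(k, n, p) == pytest.approx(
            _bruteforce_binom_p(k, n, p), abs=1e-12)

    def test_matches_scipy_binomtest(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            ours = st.binomial_p_two_sided(k, n, p)
            scipy_p = sps.binomtest(k, n, p).pvalue
            assert ours == pytest.approx(scipy_p, rel=1e-6, abs=1e-12)

    def test_degenerate_expected_fractions(self):
        assert st.binomial_p_two_sided(0, 100, 0.0) == 1.0
        assert st.binomial_p_two_sided(5, 100, 0.0) > 0.0
        assert st.binomial_p_two_sided(100, 100, 1.0) == 1.0


class TestEnrichmentTest:
    def _comp(self):
        return st.genomic_composition(
            [_te("F", "RC/Helitron", start=i * 2000, end=i * 2000 + 500) for i in range(8)]
            + [_te("G", "LTR/Gypsy", start=100_000 + i * 4000, end=100_000 + i * 4000 + 500)
               for i in range(2)])

    def test_overrepresented_group_flagged(self):
        res = st.enrichment_test({"LTR/Gypsy": 60, "RC/Helitron": 40}, 100,
                                 self._comp(), correction="none")
        by = {r.group: r for r in res}
        assert by["LTR/Gypsy"].direction == "over"
        assert by["RC/Helitron"].direction == "under"
        assert all(r.adjusted_p == r.p_value for r in res)

    def test_null_consistent_observation_not_flagged(self):
        res = st.enrichment_test({"LTR/Gypsy": 20, "RC/Helitron": 80}, 100, self._comp())
        assert all(r.direction == "none" for r in res)
        assert all(r.p_value >= 0.05 for r in res)

    def test_bh_adjustment_is_monotone_and_larger(self):
        res = st.enrichment_test({"LTR/Gypsy": 35, "RC/Helitron": 65}, 100,
                                 self._comp(), correction="bh")
        for r in res:
            assert r.adjusted_p >= r.p_value

    def test_observed_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            st.enrichment_test({"LTR/Gypsy": 80, "RC/Helitron": 40}, 100, self._comp())


class TestCompareGroups:
    def test_identical_groups_t0_p1(self):
        res = st.compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.test == "welch_t"
        assert res.statistic == 0.0
        assert res.p_value == 1.0 and not res.significant

    def test_three_groups_run_anova(self):
        res = st.compare_groups({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.test == "anova"

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0, 1, 5)
            rejections += st.compare_groups({"a": a.tolist(), "b": b.tolist()}).significant
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_on_large_shift(self):
        """Three groups, one shifted by 3 SD at n = 3: ANOVA detects the
        shift in at least 80% of simulations."""
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = {"a": rng.normal(0, 1, 3).tolist(),
                      "b": rng.normal(0, 1, 3).tolist(),
                      "c": rng.normal(3, 1, 3).tolist()}
            hits += st.compare_groups(groups).significant
        assert hits / n_sim >= 0.80

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            st.compare_groups({"a": [1.0], "b": [1, 2]})


def _profile(values):
    return pd.DataFrame({"window_chrom": "chr1", "window_bin": range(len(values)),
                         "normalized": values})


def _track(values):
    return pd.DataFrame({"window_chrom": "chr1", "window_bin": range(len(values)),
                         "value": values})


class TestCorrelateWindows:
    def test_affine_track_gives_exact_unit_correlation(self):
        x = np.arange(10, dtype=float)
        res = st.correlate_windows(_profile(x), _track(2 * x + 1))
        assert res.pearson_r == 1.0
        assert res.r_squared == 1.0

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(3)
        small = 0
        n_seeds = 60
        for _ in range(n_seeds):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            small += abs(st.correlate_windows(_profile(x), _track(y)).pearson_r) < 0.1
        assert small / n_seeds >= 0.95

    def test_missing_windows_excluded_and_counted(self):
        x = np.arange(10, dtype=float)
        res = st.correlate_windows(_profile(x), _track(x).iloc[:6])
        assert res.n_windows == 6
        assert res.n_excluded == 4

    def test_zero_variance_is_explicit_na(self):
        res = st.correlate_windows(_profile([1.0] * 5), _track([1, 2, 3, 4, 5]))
        assert math.isnan(res.pearson_r)

    def test_estimator_unbiased_on_planted_correlation(self):
        """Mean estimate over 200 seeds within 0.02 of the planted rho."""
        rng = np.random.default_rng(4)
        rho = 0.25
        estimates = []
        for _ in range(200):
            x = rng.normal(size=1000)
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=1000)
            estimates.append(st.correlate_windows(_profile(x), _track(y)).pearson_r)
        assert abs(np.mean(estimates) - rho) <= 0.02


class TestLirOverlap:
    def _annotations(self):
        return pd.DataFrame([
            {"monomer_id": "m1", "sample_id": "s1", "chrom": "chr1", "start": 100, "end": 200},
            {"monomer_id": "m2", "sample_id": "s1", "chrom": "chr1", "start": 500, "end": 600},
            {"monomer_id": "m3", "sample_id": "s2", "chrom": "chr1", "start": 120, "end": 180},
        ])

    def test_one_bp_overlap_counts(self):
        lirs = pd.DataFrame([{"chrom": "chr1", "start": 150, "end": 160}])
        out = st.lir_overlap(self._annotations(), lirs)
        assert out.set_index("sample_id")["lir_derived"].to_dict() == {"s1": 1, "s2": 1}

    def test_disjoint_not_counted(self):
        lirs = pd.DataFrame([{"chrom": "chr1", "start": 900, "end": 950}])
        out = st.lir_overlap(self._annotations(), lirs)
        assert out["lir_derived"].sum() == 0

    def test_shares_sum_to_hundred(self):
        lirs = pd.DataFrame([{"chrom": "chr1", "start": 150, "end": 160},
                             {"chrom": "chr1", "start": 550, "end": 560}])
        out = st.lir_overlap(self._annotations(), lirs)
        assert out["share_of_total_lir_pct"].sum() == pytest.approx(100.0, abs=1e-9)


class TestCentromericPartition:
    def _setup(self):
        cen = {"chr1": (40_000, 60_000)}
        tes = ([_te("ATH", "LTR/Gypsy", start=41_000 + i * 2000, end=41_500 + i * 2000)
                for i in range(5)]
               + [_te("ATH", "LTR/Gypsy", start=2_000 + i * 2000, end=2_500 + i * 2000)
                  for i in range(5)])
        return cen, tes

    def test_all_centromeric_eccdna_significant(self):
        cen, tes = self._setup()
        ann = pd.DataFrame([{"monomer_id": f"m{i}", "origin_class": "TE",
                             "te_family": "ATH", "te_superfamily": "LTR/Gypsy",
                             "chrom": "chr1", "start": 41_000, "end": 41_500}
                            for i in range(20)])
        out = st.centromeric_partition(ann, cen, tes)
        row = out.iloc[0]
        assert row["eccdna_centromeric"] == 20
        assert row["p_value"] < 0.001
        assert row["direction"] == "over"

    def test_genome_proportional_share_not_flagged(self):
        cen, tes = self._setup()
        rows = ([{"monomer_id": f"c{i}", "origin_class": "TE", "te_family": "ATH",
                  "te_superfamily": "LTR/Gypsy", "chrom": "chr1", "start": 41_000,
                  "end": 41_500} for i in range(5)]
                + [{"monomer_id": f"a{i}", "origin_class": "TE", "te_family": "ATH",
                    "te_superfamily": "LTR/Gypsy", "chrom": "chr1", "start": 2_000,
                    "end": 2_500} for i in range(5)])
        out = st.centromeric_partition(pd.DataFrame(rows), cen, tes)
        assert out.iloc[0]["direction"] == "none"

    def test_partition_counts_match_bruteforce(self, genome, errorfree_annotations):
        """Pipeline partition counts equal direct interval arithmetic on the
        annotation table."""
        from eccpipe.annotate import annotations_frame
        annotations, _ = errorfree_annotations
        df = annotations_frame(annotations)
        out = st.centromeric_partition(df, genome.centromere_intervals,
                                       genome.te_features, group_by="family")
        te_df = df[df["origin_class"] == "TE"]
        for _, row in out.iterrows():
            sub = te_df[te_df["te_family"] == row["group"]]
            cen_n = 0
            for _, a in sub.iterrows():
                cs, ce = genome.centromere_intervals[a["chrom"]]
                mid = (a["start"] + a["end"]) // 2
                cen_n += cs <= mid < ce
            assert row["eccdna_centromeric"] == cen_n
            assert row["eccdna_non_centromeric"] == len(sub) - cen_n

    def test_family_without_genomic_copies_skipped(self):
        cen, tes = self._setup()
        ann = pd.DataFrame([{"monomer_id": "m", "origin_class": "TE",
                             "te_family": "GHOST", "te_superfamily": "LTR/Gypsy",
                             "chrom": "chr1", "start": 0, "end": 100}])
        with pytest.warns(UserWarning, match="GHOST"):
            out = st.centromeric_partition(ann, cen, tes)
        assert out.empty
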