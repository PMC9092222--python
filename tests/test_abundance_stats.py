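"""Normalization, aggregation, matching, and the rank-sum comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tirscan import abundance_stats as ab
from tirscan import synthetic_data


def small_table():
    return ab.OrfCountTable(
        samples=["s1", "s2"],
        orf_ids=["o1", "o2"],
        orf_lengths_nt=np.array([1500.0, 900.0]),
        counts=np.array([[10, 0], [20, 9]]),
        total_mapped=np.array([1e6, 2e6]),
    )


class TestNormalize:
    def test_rpkm_formula(self):
        norm = ab.normalize_counts(small_table())
        assert norm.loc["s1", "o1"] == pytest.approx(10 / 1.5 / 1.0)
        assert norm.loc["s1", "o2"] == 0.0

    def test_doubling_depth_halves_abundance(self):
        t = small_table()
        t2 = small_table()
        t2.total_mapped = t.total_mapped * 2
        n1, n2 = ab.normalize_counts(t), ab.normalize_counts(t2)
        assert np.allclose(n1.to_numpy(), 2 * n2.to_numpy())

    def test_zero_depth_with_counts_raises(self):
        t = small_table()
        t.total_mapped = np.array([0.0, 2e6])
        with pytest.raises(ValueError, match="zero mapped"):
            ab.normalize_counts(t)


class TestAggregate:
    def test_sums_within_class(self):
        norm = pd.DataFrame(
            {"o1": [2.0], "o2": [3.5], "o3": [1.0]}, index=["s1"]
        )
        out = ab.aggregate_by_class(norm, {"o1": "cADPR", "o2": "cADPR"})
        assert out.loc["s1", "cADPR"] == pytest.approx(5.5)
        assert out.loc["s1", "unclassified"] == pytest.approx(1.0)

    def test_absent_class_reads_as_zero_via_mass_conservation(self):
        norm = pd.DataFrame({"o1": [2.0]}, index=["s1"])
        out = ab.aggregate_by_class(norm, {"o1": "ADPR"})
        assert "v-cADPR-x" not in out.columns  # never detected -> no column
        assert out.loc["s1", ab.ALL_TIR_COLUMN] == pytest.approx(2.0)

    def test_all_tir_column_equals_row_sum_of_classes(self):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(
            rng.uniform(0, 5, size=(4, 6)),
            index=list("abcd"),
            columns=[f"o{i}" for i in range(6)],
        )
        labels = {"o0": "ADPR", "o1": "cADPR", "o2": "v-cADPR-x", "o3": "ADPR"}
        out = ab.aggregate_by_class(norm, labels)
        parts = out.drop(columns=[ab.ALL_TIR_COLUMN]).sum(axis=1)
        assert np.allclose(parts, out[ab.ALL_TIR_COLUMN])


class TestRichness:
    def test_counts_distinct_domain_ids(self):
        out = ab.tir_richness(
            {"s": ["a.TIR_2.1", "a.TIR_2.1", "b.TIR_2.1"], "t": []}
        )
        assert out == {"s": 2, "t": 0}

    def test_invariant_to_duplication(self):
        ids = ["a.TIR_2.1", "b.TIR_2.1", "c.TIR_3.1"]
        assert (
            ab.tir_richness({"s": ids})["s"]
            == ab.tir_richness({"s": ids + ids})["s"]
        )


def meta(pairs):
    return [
        ab.SampleMeta(sample_id=s, donor_id=f"d{s}", age_months=a, group=g)
        for s, a, g in pairs
    ]


class TestAgeMatching:
    def test_identical_age_lists_match_perfectly(self):
        m = meta(
            [(f"h{i}", 12.0 + i, "healthy") for i in range(5)]
            + [(f"m{i}", 12.0 + i, "malnourished") for i in range(5)]
        )
        report = ab.age_matched_subsample(m, rng=0)
        assert len(report.pairs) == 5 and not report.unmatched

    def test_only_samples_within_half_window_are_eligible(self):
        m = meta(
            [("h1", 11.0, "healthy"), ("h2", 18.0, "healthy"), ("m1", 12.0, "malnourished")]
        )
        report = ab.age_matched_subsample(m, window=3.0, rng=0)
        assert report.pairs == [("m1", "h1")]

    def test_empty_malnourished_returns_empty_subset(self):
        m = meta([("h1", 10.0, "healthy")])
        report = ab.age_matched_subsample(m, rng=0)
        assert report.pairs == [] and report.matched_healthy == []

    def test_unmatchable_sample_is_reported_and_skipped(self):
        m = meta(
            [("h1", 10.0, "healthy"), ("m1", 30.0, "malnourished"), ("m2", 10.5, "malnourished")]
        )
        report = ab.age_matched_subsample(m, rng=0)
        assert report.unmatched == ["m1"]
        assert report.pairs == [("m2", "h1")]


def enumeration_ranksum_p(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = min(u_stat(range(n1)), len(x) * len(y) - u_stat(range(n1)))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_stat(idx)
        if min(u, len(x) * len(y) - u) <= observed:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_5v5_matches_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [10, 20, 30, 40, 50]
        expected = enumeration_ranksum_p(x, y)
        assert expected == pytest.approx(2 / 252)
        assert ab.mannwhitney_p(np.array(x, float), np.array(y, float)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.007937, abs=1e-6)

    def test_partial_overlap_matches_enumeration(self):
        x, y = [1.0, 4.0, 6.0, 9.0], [3.0, 7.0, 8.0, 11.0]
        assert ab.mannwhitney_p(np.array(x), np.array(y)) == pytest.approx(
            enumeration_ranksum_p(x, y), abs=1e-12
        )

    def test_degenerate_identical_groups_report_p_one(self):
        x = np.array([2.0, 2.0, 2.0])
        assert ab.mannwhitney_p(x, x.copy()) == 1.0


class TestCompareGroups:
    @staticmethod
    def simulated(effect, seed=11):
        orf_labels = {f"o{i}": lab for i, lab in enumerate(
            ["v-cADPR-x"] * 5 + ["ADPR"] * 5 + ["cADPR"] * 5)}
        table, metas = synthetic_data.simulate_counts(
            orf_labels, n_per_group=20, effect_fold=effect,
            rng=np.random.default_rng(seed),
        )
        norm = ab.normalize_counts(table)
        return ab.aggregate_by_class(norm, orf_labels), metas

    def test_detects_planted_healthy_enrichment(self):
        class_ab, metas = self.simulated(effect=4.0)
        comp = ab.compare_groups(class_ab, metas, "v-cADPR-x", n_boot=200, rng=1)
        assert comp.point_p < 0.05
        assert comp.direction == "healthy_higher"
        assert comp.boot_consistency > 0.8

    def test_boot_replicate_count_is_honored(self):
        class_ab, metas = self.simulated(effect=1.0)
        comp = ab.compare_groups(class_ab, metas, "ADPR", n_boot=57, rng=2)
        assert comp.n_boot == 57
        assert 0.0 <= comp.boot_consistency <= 1.0

    def test_missing_class_column_raises(self):
        class_ab, metas = self.simulated(effect=1.0)
        with pytest.raises(KeyError):
            ab.compare_groups(class_ab, metas, "no-such-class", n_boot=0, rng=0)


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r1, _ = ab.abundance_metabolite_correlation(x, 2 * x + 1)
        r2, _ = ab.abundance_metabolite_correlation(x, -x)
        assert r1 == pytest.approx(1.0)
        assert r2 == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = ab.abundance_metabolite_correlation(x, y)
        direct = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ab.abundance_metabolite_correlation(np.ones(5), np.arange(5.0))
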