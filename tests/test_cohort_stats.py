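import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import fisher_p_oracle, make_call, spearman_oracle
from somase.cohort_stats import (
    RecurrenceSpectrum,
    contingency_2x2,
    kruskal_wallis,
    recurrence_spectrum,
    spearman_rho,
    stratified_summary,
)
from somase.allele_model import AnnotationRecord, SiteKey
from somase.exceptions import InsufficientDataError


def calls_matching_histogram(histogram):
    """Synthesize one call row per (sample, unique mutation) realizing a histogram."""
    calls = []
    site_index = 0
    for multiplicity, count in histogram.items():
        for _ in range(count):
            site_index += 1
            for sample in range(multiplicity):
                calls.append(
                    make_call(sample_id=f"S{sample:03d}", chrom="chr1", pos=site_index)
                )
    return calls


class TestRecurrenceSpectrum:
    def test_printed_cohort_arithmetic(self):
        # 1139 unique mutations; the recurrent ones: 44 pairs, 12 triples,
        # 4 quadruples, 2 quintuples, one each in 6 and 7 samples.
        recurrent = {2: 44, 3: 12, 4: 4, 5: 2, 6: 1, 7: 1}
        histogram = {1: 1139 - sum(recurrent.values()), **recurrent}
        spectrum = recurrence_spectrum(calls_matching_histogram(histogram))
        assert spectrum.unique_count == 1139
        assert spectrum.total_count == 1238
        assert round(100 * spectrum.singleton_fraction) == 94

    def test_single_sample_all_singletons(self):
        calls = [make_call(pos=i) for i in range(1, 8)]
        spectrum = recurrence_spectrum(calls)
        assert spectrum.multiplicity_histogram == {1: 7}
        assert spectrum.singleton_fraction == 1.0
        assert spectrum.total_count == spectrum.unique_count == 7

    def test_one_shared_site(self):
        calls = [
            make_call(sample_id="A", pos=1),
            make_call(sample_id="A", pos=2),
            make_call(sample_id="B", pos=2),
            make_call(sample_id="B", pos=3),
        ]
        spectrum = recurrence_spectrum(calls)
        assert spectrum.multiplicity_histogram == {1: 2, 2: 1}
        assert spectrum.total_count == 4

    def test_same_position_different_allele_is_distinct(self):
        calls = [
            make_call(sample_id="A", pos=5, ref="A", alt="G"),
            make_call(sample_id="B", pos=5, ref="A", alt="T"),
        ]
        assert recurrence_spectrum(calls).multiplicity_histogram == {1: 2}

    def test_conservation_invariant(self, small_cohort):
        from somase.ase_calling import call_expression_status
        from somase.site_filters import filter_cohort

        records, intervals, _, _ = small_cohort
        retained, _, _ = filter_cohort(records, intervals)
        calls = call_expression_status(retained)
        spectrum = recurrence_spectrum(calls)
        assert spectrum.total_count == len(calls)
        assert spectrum.unique_count == len({c.site for c in calls})

    def test_from_histogram_validation(self):
        with pytest.raises(ValueError):
            RecurrenceSpectrum.from_histogram({0: 3})


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_derived_example(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert spearman_oracle(x, y) == pytest.approx(0.6)
        assert spearman_rho(x, y) == pytest.approx(0.6, rel=1e-12)

    def test_absent_values_dropped_pairwise(self):
        x = [1.0, None, 2.0, 3.0, float("nan"), 4.0]
        y = [2.0, 5.0, 1.0, 4.0, 1.0, 3.0]
        assert spearman_rho(x, y) == pytest.approx(spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]))

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho([1.0, 2.0, None], [1.0, 2.0, 3.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50).tolist()
        y = rng.normal(size=50).tolist()
        base = spearman_rho(x, y)
        assert spearman_rho([math.exp(v) for v in x], y) == pytest.approx(base)
        assert spearman_rho(x, [v**3 for v in y]) == pytest.approx(base)


class TestKruskalWallis:
    def test_three_groups_hand_ranks(self):
        # rank sums (6, 15, 24): H = 12/(9*10) * sum(R^2)/3 - 3*10 = 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, rel=1e-12)

    def test_two_groups_hand_ranks(self):
        h, _ = kruskal_wallis([[1, 3], [2, 4]])
        assert h == pytest.approx(0.6, rel=1e-12)

    def test_group_order_invariant(self):
        groups = [[1.5, 2.5, 9.0], [4.0, 5.5], [7.0, 8.0, 0.5]]
        assert kruskal_wallis(groups) == pytest.approx(kruskal_wallis(groups[::-1]))

    def test_identical_values_degenerate(self):
        h, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert h == 0.0
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0, 3.0]])

    def test_permutation_mode_agrees_roughly(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 12).tolist(), rng.normal(1.2, 1, 12).tolist()]
        h, p_asym = kruskal_wallis(groups)
        h2, p_perm = kruskal_wallis(groups, permutation=2000, seed=5)
        assert h2 == h
        assert p_perm == pytest.approx(p_asym, abs=0.05)

    def test_permutation_seeded_deterministic(self):
        groups = [[1, 5, 3], [2, 8, 4, 9]]
        first = kruskal_wallis(groups, permutation=500, seed=11)
        second = kruskal_wallis(groups, permutation=500, seed=11)
        assert first == second


class TestContingency2x2:
    def test_no_association(self):
        assert contingency_2x2([[2, 2], [2, 2]], "fisher_exact") == pytest.approx(1.0)

    def test_perfect_association(self):
        # 2 * C(5,5) * C(5,0) / C(10,5) = 2/252
        p = contingency_2x2([[5, 0], [0, 5]], "fisher_exact")
        assert p == pytest.approx(0.0079365079, rel=1e-6)
        assert p == pytest.approx(fisher_p_oracle(5, 0, 0, 5), rel=1e-9)

    def test_fisher_matches_enumeration_small_margins(self):
        for a in range(9):
            for b in range(9 - a):
                for c in range(9 - a):
                    for d in range(9):
                        if a + b + c + d == 0 or b + d > 8 or c + d > 8:
                            continue
                        p = contingency_2x2([[a, b], [c, d]], "fisher_exact")
                        assert p == pytest.approx(fisher_p_oracle(a, b, c, d), rel=1e-8)

    def test_yates_triggered_by_small_cell(self):
        # hand oracle: chi2 with |ad - bc| reduced by n/2
        a, b, c, d = 3, 7, 6, 4
        n = a + b + c + d
        chi2 = (
            n * (abs(a * d - b * c) - n / 2) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        expected = float(sps.chi2.sf(chi2, 1))
        assert contingency_2x2([[a, b], [c, d]], "chi2_yates_auto") == pytest.approx(expected, rel=1e-12)

    def test_no_yates_for_large_cells(self):
        a, b, c, d = 30, 70, 60, 40
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        expected = float(sps.chi2.sf(chi2, 1))
        assert contingency_2x2([[a, b], [c, d]], "chi2_yates_auto") == pytest.approx(expected, rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2([[0, 0], [0, 0]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2([[1, -1], [2, 2]])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            contingency_2x2([[1, 2], [3, 4]], "barnard")


def annotate(sites_and_classes):
    annotations = {}
    for (pos, func_class, in_cgc) in sites_and_classes:
        annotations[SiteKey("chr1", pos, "A", "G")] = AnnotationRecord(
            gene=f"G{pos}", func_class=func_class, in_cancer_gene_list=in_cgc
        )
    return annotations


class TestStratifiedSummary:
    def test_single_stratum_no_tests(self):
        calls = [make_call(pos=i) for i in range(1, 6)]
        annotations = annotate((i, "missense", False) for i in range(1, 6))
        summary = stratified_summary(calls, annotations, "func_class")
        assert set(summary.v_rd_by_group) == {"missense"}
        assert summary.kruskal_h is None
        assert summary.pairwise_tests == ()

    def test_identical_v_rd_multisets_give_zero_h(self):
        calls = []
        specs = []
        for i, (func_class, trna) in enumerate(
            [("missense", 0.2), ("missense", 0.4), ("missense", 0.6),
             ("stop", 0.2), ("stop", 0.4), ("stop", 0.6)],
            start=1,
        ):
            calls.append(make_call(pos=i, vaf_trna=trna))
            specs.append((i, func_class, False))
        summary = stratified_summary(calls, annotate(specs), "func_class")
        assert summary.kruskal_h == pytest.approx(0.0, abs=1e-9)

    def test_dominant_stratum_detected(self):
        rng = np.random.default_rng(3)
        calls, specs = [], []
        pos = 0
        for _ in range(60):  # stratum A: stochastically larger V_R:D
            pos += 1
            calls.append(make_call(pos=pos, vaf_trna=float(rng.uniform(0.5, 0.95))))
            specs.append((pos, "missense", False))
        for _ in range(60):
            pos += 1
            calls.append(make_call(pos=pos, vaf_trna=float(rng.uniform(0.05, 0.5))))
            specs.append((pos, "non-coding", False))
        summary = stratified_summary(calls, annotate(specs), "func_class")
        assert summary.kruskal_h > 0
        assert summary.kruskal_p < 0.001
        medians = {g: np.median(v) for g, v in summary.v_rd_by_group.items()}
        assert medians["missense"] > medians["non-coding"]

    def test_group_sizes_sum_to_input(self, small_cohort):
        from somase.ase_calling import call_expression_status
        from somase.site_filters import filter_cohort

        records, intervals, annotations, _ = small_cohort
        retained, _, _ = filter_cohort(records, intervals)
        calls = call_expression_status(retained)
        summary = stratified_summary(calls, annotations, "func_class")
        assert sum(summary.group_sizes.values()) == len(calls)
        for group, counts in summary.call_counts_by_group.items():
            assert sum(counts.values()) == summary.group_sizes[group]
        for test in summary.pairwise_tests:
            assert 0.0 <= test.p_value <= 1.0
            assert test.q_value >= test.p_value - 1e-12

    def test_cgc_stratification_labels(self):
        calls = [make_call(pos=1), make_call(pos=2)]
        annotations = annotate([(1, "missense", True), (2, "missense", False)])
        summary = stratified_summary(calls, annotations, "in_cancer_gene_list")
        assert set(summary.v_rd_by_group) == {"CGC", "non-CGC"}

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="grouping key"):
            stratified_summary([], {}, "chromosome")

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            stratified_summary([make_call(pos=1)], {}, "func_class")
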