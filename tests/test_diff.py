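"""Aggregation, CV cascade, classification and the one-sample t-test."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from phosphodelta import diff
from phosphodelta import simulate
from tests.conftest import make_measurement


def t_two_tailed_oracle(t_stat: float, df: int) -> float:
    """Numeric integration of the Student t density (independent of scipy.stats)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t_stat), math.inf)
    return 2 * tail


def summary_from_hl(hls, peptide_id="p"):
    methods = ["SIMAC", "TiO2", "TiSH"][: len(hls)]
    per_method = dict(zip(methods, hls))
    return diff.PeptideRatioSummary(
        peptide_id=peptide_id,
        sequence="AKSPTLR",
        protein_acc="P00001",
        sites="S3",
        per_method_hl=per_method,
        mean_hl=sum(hls) / len(hls),
        mean_log2=sum(math.log2(v) for v in hls) / len(hls),
        cv=(statistics.stdev(hls) / (sum(hls) / len(hls))) if len(hls) > 1 else None,
        n_methods=len(hls),
    )


class TestAggregateScans:
    @pytest.mark.parametrize(
        "scans,expected",
        [
            ([(-1.0, 3.0), (0.0, 1.0)], -0.75),
            ([(0.2, 1.0), (0.4, 1.0), (0.6, 1.0)], 0.4),
            ([(1.234, 7.0)], 1.234),
        ],
    )
    def test_weighted_mean(self, scans, expected):
        assert diff.aggregate_scans(scans) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diff.aggregate_scans([])


class TestMedianNormalize:
    def test_already_centred_unchanged(self):
        records = [make_measurement(hl_ratio=2.0**x) for x in (-1.0, 0.0, 1.0)]
        out = diff.median_normalize(records)
        assert [m.log2_ratio for m in out] == pytest.approx([-1.0, 0.0, 1.0])

    def test_shift_by_median(self):
        records = [make_measurement(hl_ratio=2.0**x) for x in (0.6, 1.0, 1.4)]
        out = diff.median_normalize(records)
        assert [m.log2_ratio for m in out] == pytest.approx([-0.4, 0.0, 0.4])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=25),
        st.lists(st.floats(-5, 5), min_size=1, max_size=25),
    )
    def test_post_median_zero_per_method(self, xs, ys):
        records = [make_measurement(hl_ratio=2.0**x, method="TiSH") for x in xs]
        records += [make_measurement(hl_ratio=2.0**y, method="TiO2") for y in ys]
        out = diff.median_normalize(records)
        for method, values in (("TiSH", xs), ("TiO2", ys)):
            log2s = sorted(m.log2_ratio for m in out if m.method == method)
            # sort-based median oracle
            n = len(log2s)
            oracle = log2s[n // 2] if n % 2 else (log2s[n // 2 - 1] + log2s[n // 2]) / 2
            assert abs(oracle) < 1e-9
        for m in out:
            assert abs(m.log2_ratio - math.log2(m.hl_ratio)) < 1e-9


class TestSummarize:
    def test_three_method_mean_and_cv(self):
        records = [
            make_measurement(hl_ratio=hl, method=m)
            for hl, m in [(0.5, "SIMAC"), (0.6, "TiO2"), (0.55, "TiSH")]
        ]
        (s,) = diff.summarize_across_methods(records).values()
        assert s.mean_hl == pytest.approx(0.55)
        # hand formula: sd of {0.5, 0.6, 0.55} = 0.05, cv = 0.05 / 0.55
        assert s.cv == pytest.approx(0.05 / 0.55, abs=1e-4)
        assert s.n_methods == 3

    def test_single_method_has_no_cv(self):
        (s,) = diff.summarize_across_methods([make_measurement(hl_ratio=0.6)]).values()
        assert s.mean_hl == pytest.approx(0.6)
        assert s.cv is None and s.n_methods == 1

    def test_identical_values_give_zero_cv(self):
        records = [
            make_measurement(hl_ratio=0.7, method=m) for m in ("SIMAC", "TiO2")
        ]
        (s,) = diff.summarize_across_methods(records).values()
        assert s.cv == 0.0

    def test_within_method_duplicates_averaged_on_log2(self):
        records = [
            make_measurement(hl_ratio=0.25, method="TiSH"),
            make_measurement(hl_ratio=1.0, method="TiSH"),
        ]
        (s,) = diff.summarize_across_methods(records).values()
        # log2 average of {-2, 0} is -1 -> H/L 0.5
        assert s.per_method_hl["TiSH"] == pytest.approx(0.5)
        assert s.n_methods == 1


class TestCascade:
    def test_low_cv_kept(self):
        s = summary_from_hl([0.5, 0.6, 0.55])
        assert diff.cascade_filter([s]) == [s]
        assert s.cascade_branch == diff.BRANCH_LOW_CV

    def test_high_cv_with_high_ratio_rejected(self):
        s = summary_from_hl([0.5, 1.2])  # cv ~ 58%, 1.2 >= 0.75
        assert diff.cascade_filter([s]) == []
        assert s.cascade_branch == diff.BRANCH_REJECTED

    def test_high_cv_all_low_kept(self):
        s = summary_from_hl([0.3, 0.7])  # cv ~ 56.6%, all < 0.75
        assert diff.cascade_filter([s]) == [s]
        assert s.cascade_branch == diff.BRANCH_HIGH_CV_ALL_LOW

    def test_single_method_kept_without_cv(self):
        s = summary_from_hl([0.9])
        assert diff.cascade_filter([s]) == [s]
        assert s.cascade_branch == diff.BRANCH_SINGLE

    @given(
        st.lists(
            st.lists(st.floats(0.05, 4.0), min_size=1, max_size=3),
            min_size=1,
            max_size=40,
        ),
        st.floats(0.05, 1.0),
        st.floats(0.05, 1.0),
    )
    def test_kept_subset_and_cv_monotonicity(self, groups, cv_a, cv_b):
        lo, hi = sorted((cv_a, cv_b))
        summaries = [summary_from_hl(hls, peptide_id=str(i)) for i, hls in enumerate(groups)]
        strict = {s.peptide_id for s in diff.cascade_filter(summaries, cv_max=lo)}
        loose = {s.peptide_id for s in diff.cascade_filter(summaries, cv_max=hi)}
        assert strict <= loose <= {s.peptide_id for s in summaries}
        # branches partition the kept set
        kept = diff.cascade_filter(summaries)
        for s in kept:
            assert s.cascade_branch in (
                diff.BRANCH_LOW_CV, diff.BRANCH_SINGLE, diff.BRANCH_HIGH_CV_ALL_LOW
            )


class TestClassify:
    @pytest.mark.parametrize(
        "mean_hl,expected",
        [
            (0.5, diff.HYPER),
            (1.0, diff.UNCHANGED),
            (0.75, diff.UNCHANGED),   # boundaries are exclusive
            (1.3, diff.UNCHANGED),
            (1.31, diff.HYPO),
        ],
    )
    def test_thresholds(self, mean_hl, expected):
        s = summary_from_hl([mean_hl])
        assert diff.classify(s) == expected


class TestSignificance:
    def test_documented_example(self):
        s = summary_from_hl([2.0**-1.1, 2.0**-0.9, 2.0**-1.0])
        diff.significance_test([s])
        t_stat = -1.0 / (statistics.stdev([-1.1, -0.9, -1.0]) / math.sqrt(3))
        assert t_stat == pytest.approx(-17.3205, abs=1e-3)
        assert s.p_value == pytest.approx(0.00332, abs=5e-5)

    @pytest.mark.parametrize(
        "log2s",
        [
            [-1.1, -0.9, -1.0],
            [0.3, -0.2, 0.6],
            [2.0, 0.1],
            [-0.05, -0.10],
            [1.0, 1.5, 0.7],
        ],
    )
    def test_matches_numeric_t_cdf_oracle(self, log2s):
        s = summary_from_hl([2.0**x for x in log2s])
        diff.significance_test([s])
        n = len(log2s)
        t_stat = (sum(log2s) / n) / (statistics.stdev(log2s) / math.sqrt(n))
        assert s.p_value == pytest.approx(t_two_tailed_oracle(t_stat, n - 1), abs=1e-6)

    def test_zero_variance_degenerate_rules(self):
        flat = summary_from_hl([1.0, 1.0, 1.0])     # log2 all exactly 0
        shifted = summary_from_hl([0.5, 0.5, 0.5])  # log2 all exactly -1
        diff.significance_test([flat, shifted])
        assert flat.p_value == 1.0 and flat.degenerate_p
        assert shifted.p_value == 0.0 and shifted.degenerate_p

    def test_single_method_excluded(self):
        s = summary_from_hl([0.5])
        significant = diff.significance_test([s])
        assert s.p_value is None and significant == []


class TestAbundance:
    def test_status_assignment(self):
        summaries = [
            summary_from_hl([0.5], peptide_id="a"),
            summary_from_hl([0.5], peptide_id="b"),
            summary_from_hl([0.5], peptide_id="c"),
        ]
        summaries[0].protein_acc = "UNCH"
        summaries[1].protein_acc = "RED"
        summaries[2].protein_acc = "MISSING"
        table = [
            simulate.AbundanceMeasurement("x1", "UNCH", 0.85),
            simulate.AbundanceMeasurement("x2", "RED", 0.7),
        ]
        flags = diff.abundance_correct(summaries, table)
        assert flags["a"].status == "unchanged"
        assert flags["b"].status == "reduced"
        assert flags["c"].status == "unknown" and flags["c"].protein_hl is None

    def test_protein_level_is_median_of_peptides(self):
        s = summary_from_hl([0.5], peptide_id="a")
        s.protein_acc = "PX"
        table = [
            simulate.AbundanceMeasurement(f"x{i}", "PX", hl) for i, hl in enumerate([0.5, 0.9, 1.0])
        ]
        flags = diff.abundance_correct([s], table)
        assert flags["a"].protein_hl == pytest.approx(0.9)
        assert flags["a"].status == "unchanged"


class TestVolcano:
    def test_counts_and_empty(self):
        hyper = summary_from_hl([0.4, 0.45, 0.42], peptide_id="h")
        null = summary_from_hl([1.0, 1.02, 0.98], peptide_id="n")
        for s in (hyper, null):
            diff.classify(s)
        diff.significance_test([hyper, null])
        table = diff.volcano_table([hyper, null])
        assert len(table) == 2
        assert diff.volcano_counts(table) == (1, 0)
        assert diff.volcano_table([]).empty

    def test_noiseless_simulation_recovers_planted_classes(self):
        config = simulate.SimulationConfig(
            seed=11, n_phosphopeptides=200, noise_log2_sd=0.0
        )
        exp = simulate.gen_phospho_experiment(config)
        summaries = diff.summarize_across_methods(diff.median_normalize(exp.records))
        kept = diff.cascade_filter(summaries)
        called = {s.peptide_id for s in kept if diff.classify(s) == diff.HYPER}
        assert called == exp.truth_hyper_ids
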