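"""Cohort scan orchestration, reports, subset power and contamination QC."""

import numpy as np
import pandas as pd
import pytest

from snptrace import (
    GenotypeCall,
    MatchStatus,
    PairVerdict,
    PlantedTruth,
    SimConfig,
    Swap,
    check_expected_pairs,
    compare_pair,
    contamination_score,
    correlation_matrix,
    derive_expected_pairs,
    render_heatmap,
    scan_cohort,
    simulate_cohort,
    subset_sensitivity,
    validation_cohort_config,
    write_expected_csv,
    write_pairwise_csv,
)
from snptrace.cohort import evaluate_scan_against_truth
from snptrace.synthetic import sample_name
from conftest import make_profile

HET = GenotypeCall.HET
HOM_REF = GenotypeCall.HOM_REF


@pytest.fixture(scope="module")
def small_cohort():
    """20 patients x 2 timepoints, no planted errors."""
    from snptrace import default_panel

    return simulate_cohort(SimConfig(panel=default_panel(), n_patients=20, seed=101))


@pytest.fixture(scope="module")
def swapped_cohort():
    """Same structure with one TP2 swap planted between patients 0 and 1."""
    from snptrace import default_panel

    config = SimConfig(
        panel=default_panel(), n_patients=20, seed=101,
        planted_errors=(Swap(sample_name(0, 1), sample_name(1, 1)),),
    )
    return simulate_cohort(config)


class TestScanCohort:
    def test_pair_count_is_n_choose_2(self, panel28):
        profiles = [make_profile(panel28, [HET] * 28, f"P{i}") for i in range(4)]
        result = scan_cohort(profiles)
        assert len(result.comparisons) == 6
        assert len({c.sample_pair for c in result.comparisons}) == 6

    def test_duplicate_sample_id_rejected(self, panel28):
        profiles = [make_profile(panel28, [HET] * 28, "same") for _ in range(2)]
        with pytest.raises(ValueError, match="duplicate"):
            scan_cohort(profiles)

    def test_clean_cohort_matches_exactly_the_timepoint_pairs(self, small_cohort):
        result = scan_cohort(small_cohort.profiles)
        assert len(result.comparisons) == 40 * 39 // 2
        match_pairs = result.match_pairs
        expected_pairs = {
            frozenset((sample_name(i, 0), sample_name(i, 1))) for i in range(20)
        }
        assert match_pairs == expected_pairs
        assert result.unexpected_matches == ()
        assert all(e.verdict is PairVerdict.CONCORDANT for e in result.expected)

    def test_planted_swap_bookkeeping(self, swapped_cohort):
        truth = swapped_cohort.truth
        assert len(truth.unexpected_pairs) == 2
        assert len(truth.discordant_expected_pairs) == 2
        result = scan_cohort(swapped_cohort.profiles)
        assert {c.sample_pair for c in result.unexpected_matches} == set(
            truth.unexpected_pairs
        )
        discordant = {
            frozenset((e.x_id, e.y_id))
            for e in result.expected
            if e.verdict is PairVerdict.DISCORDANT
        }
        assert discordant == set(truth.discordant_expected_pairs)

    def test_scan_agrees_with_compare_pair(self, small_cohort):
        profiles = list(small_cohort.profiles)[:12]
        result = scan_cohort(profiles)
        by_pair = {c.sample_pair: c for c in result.comparisons}
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                ref = compare_pair(profiles[i], profiles[j])
                got = by_pair[frozenset((profiles[i].sample_id, profiles[j].sample_id))]
                assert (got.n_evaluable, got.n_concordant, got.status) == (
                    ref.n_evaluable, ref.n_concordant, ref.status,
                )
                assert got.discordant_positions == ref.discordant_positions
                assert got.correlation == pytest.approx(ref.correlation, abs=1e-9)


class TestExpectedPairs:
    def test_patient_id_is_first_digit_run(self):
        ids = ["CLL-68035557-02S65286-TP1", "CLL-68035557-67S38544-TP2"]
        pairs = derive_expected_pairs(ids)
        assert pairs == [(ids[0], ids[1], "68035557")]

    def test_three_samples_of_one_patient_give_three_pairs(self):
        ids = [f"CLL-123-0{i}-TP{i}" for i in range(3)]
        assert len(derive_expected_pairs(ids)) == 3

    def test_all_distinct_patients_give_no_pairs(self):
        assert derive_expected_pairs(["CLL-1-a", "CLL-2-b", "CLL-3-c"]) == []

    def test_pattern_without_group_rejected(self):
        with pytest.raises(ValueError, match="capturing group"):
            derive_expected_pairs(["s1"], id_pattern=r"\d+")

    def test_unmatched_sample_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pairs = derive_expected_pairs(["no-digits-here", "CLL-5-a", "CLL-5-b"])
        assert len(pairs) == 1
        assert "no-digits-here" in caplog.text

    @pytest.mark.parametrize(
        "n_concordant,correlation,status,verdict",
        [
            (9, 0.241, MatchStatus.NO_MATCH, PairVerdict.DISCORDANT),
            (28, 1.0, MatchStatus.MATCH, PairVerdict.CONCORDANT),
            (21, 0.97, MatchStatus.BORDERLINE_MATCH, PairVerdict.REVIEW),
            (5, 0.1, MatchStatus.UNEVALUABLE, PairVerdict.DISCORDANT),
        ],
    )
    def test_verdicts(self, n_concordant, correlation, status, verdict):
        from snptrace import CohortScanResult, MatchThresholds, PairComparison

        obs = PairComparison(
            x_id="CLL-7-TP1", y_id="CLL-7-TP2",
            n_evaluable=28 if status is not MatchStatus.UNEVALUABLE else 5,
            n_concordant=n_concordant, correlation=correlation,
            status=status, discordant_positions=(),
        )
        scan = CohortScanResult(
            comparisons=(obs,), matches=(), expected=(), unexpected_matches=(),
            sample_ids=("CLL-7-TP1", "CLL-7-TP2"), thresholds=MatchThresholds(),
        )
        got = check_expected_pairs([("CLL-7-TP1", "CLL-7-TP2", "7")], scan)[0]
        assert got.verdict is verdict
        assert got.patient_id == "7"

    def test_unscanned_expected_pair_is_an_error(self, panel28):
        x = make_profile(panel28, [HET] * 28, "CLL-1-a")
        y = make_profile(panel28, [HET] * 28, "CLL-1-b")
        scan = scan_cohort([x, y])
        with pytest.raises(ValueError, match="unscanned"):
            check_expected_pairs([("CLL-1-a", "ghost", "1")], scan)


class TestReports:
    def test_pairwise_csv_matches_first_then_descending_correlation(
        self, swapped_cohort, tmp_path
    ):
        result = scan_cohort(swapped_cohort.profiles)
        path = write_pairwise_csv(result, "t", "20250101-000000", tmp_path)
        assert path.name == "Pairwise_concordance_t_20250101-000000.csv"
        df = pd.read_csv(path)
        n_match = len(result.matches)
        head = df.head(n_match)
        assert set(head["status"]) <= {"MATCH", "BORDERLINE_MATCH"}
        tail_corr = df["correlation"].iloc[n_match:].dropna().to_numpy()
        assert (np.diff(tail_corr) <= 1e-12).all()

    def test_pairwise_csv_deterministic_rerun(self, small_cohort, tmp_path):
        result = scan_cohort(small_cohort.profiles)
        p1 = write_pairwise_csv(result, "a", "20250101-000000", tmp_path / "r1")
        p2 = write_pairwise_csv(result, "a", "20250101-000000", tmp_path / "r2")
        assert p1.read_bytes() == p2.read_bytes()

    def test_expected_csv_sorted_and_round_trips(self, swapped_cohort, tmp_path):
        result = scan_cohort(swapped_cohort.profiles)
        path = write_expected_csv(result.expected, "t", "20250101-000000", tmp_path)
        assert path.name == "Expected_concordant_pairs_t_20250101-000000.csv"
        df = pd.read_csv(path)
        assert len(df) == len(result.expected)
        corr = df["correlation"].to_numpy()
        assert (np.diff(corr) <= 1e-12).all()
        # broken pairs sink to the bottom of the table
        assert set(df.tail(2)["verdict"]) == {"DISCORDANT"}
        assert set(df["verdict"]) <= {"CONCORDANT", "REVIEW", "DISCORDANT"}

    def test_empty_expected_list_writes_header_only(self, tmp_path):
        path = write_expected_csv([], "e", "20250101-000000", tmp_path)
        assert len(path.read_text().splitlines()) == 1

    def test_heatmap_matrix_symmetric_unit_diagonal(self, small_cohort, tmp_path):
        result = scan_cohort(list(small_cohort.profiles)[:10])
        ids, m = correlation_matrix(result)
        assert m.shape == (10, 10)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)
        path = render_heatmap(result, "h", "20250101-000000", tmp_path)
        assert path.name == "Pairwise_concordance_h_20250101-000000.png"
        assert path.stat().st_size > 0


class TestSubsetSensitivity:
    def test_full_size_subset_equals_full_scan(self, swapped_cohort):
        truth = swapped_cohort.truth
        full = scan_cohort(swapped_cohort.profiles)
        du, dd, fp = evaluate_scan_against_truth(full, truth)
        res = subset_sensitivity(
            swapped_cohort.profiles, truth, [28], iterations=1, seed=9
        )[0]
        assert (res.detected_unexpected, res.detected_discordant, res.false_positives) == (du, dd, fp)

    def test_oversized_subset_rejected(self, swapped_cohort):
        with pytest.raises(ValueError, match="exceeds panel size"):
            subset_sensitivity(swapped_cohort.profiles, swapped_cohort.truth,
                               [29], iterations=1, seed=0)

    def test_same_seed_reproduces_results(self, swapped_cohort):
        truth = swapped_cohort.truth
        a = subset_sensitivity(swapped_cohort.profiles, truth, [20, 16],
                               iterations=3, seed=5)
        b = subset_sensitivity(swapped_cohort.profiles, truth, [20, 16],
                               iterations=3, seed=5)
        assert a == b

    def test_false_positive_means_monotone_in_panel_size(self):
        # specificity falls as the panel shrinks: mean false positives over
        # iterations must not increase with subset size
        cohort = simulate_cohort(validation_cohort_config(seed=17, n_patients=60))
        truth = cohort.truth
        sizes = [16, 18, 20, 22, 24, 26]
        results = subset_sensitivity(cohort.profiles, truth, sizes,
                                     iterations=10, seed=17)
        means = {
            s: np.mean([r.false_positives for r in results if r.subset_size == s])
            for s in sizes
        }
        for smaller, larger in zip(sizes, sizes[1:]):
            assert means[smaller] >= means[larger]


class TestContamination:
    def test_pure_profile_scores_zero(self, panel28):
        prof = make_profile(panel28, ([HOM_REF, HET, GenotypeCall.HOM_ALT] * 10)[:28])
        report = contamination_score(prof)
        assert report.score == 0.0
        assert not report.flagged
        assert report.deviant_loci == ()

    def test_single_locus_deviation_arithmetic(self, tiny_panel):
        from snptrace import SampleProfile

        prof = SampleProfile.from_counts("s", tiny_panel,
                                         [75, 100, 100, 100], [25, 0, 0, 0])
        report = contamination_score(prof.subset([0]))
        assert report.score == pytest.approx(0.25)
        assert report.flagged
        assert len(report.deviant_loci) == 1

    def test_no_evaluable_locus_is_undefined(self, tiny_panel):
        from snptrace import SampleProfile

        prof = SampleProfile.from_counts("s", tiny_panel, [0] * 4, [0] * 4)
        report = contamination_score(prof)
        assert np.isnan(report.score)
        assert not report.flagged

    def test_cross_contamination_shifts_score_at_depth_500(self, panel28):
        # 10% admixture moves VAFs off the anchors by ~f/2 at the loci where
        # the two individuals differ; the mean-deviation score rises well
        # above the clean baseline, and doubling the admixture trips the
        # default flag
        from snptrace import Contaminate
        from snptrace.synthetic import sample_name

        def cohort_with(fraction):
            planted = (
                (Contaminate(sample_name(0, 0), sample_name(1, 0), fraction),)
                if fraction else ()
            )
            return simulate_cohort(
                SimConfig(panel=panel28, n_patients=2, timepoints=1,
                          mean_depth=500.0, seed=23, planted_errors=planted)
            )

        clean_report = contamination_score(cohort_with(0.0).profiles[0])
        ten_pct = contamination_score(cohort_with(0.10).profiles[0])
        twenty_pct = contamination_score(cohort_with(0.20).profiles[0])
        assert not clean_report.flagged
        assert ten_pct.score > 3 * clean_report.score
        assert len(ten_pct.deviant_loci) >= 1
        assert twenty_pct.flagged
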