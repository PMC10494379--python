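import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from multibdwi.diagnostics_stats import (
    bland_altman,
    build_report,
    delong_compare,
    icc_two_reader,
    independent_t_test,
    ks_normality,
    roc_analysis,
    summary_t_test,
    youden_from_rates,
)
from multibdwi.model_fitting import MAP_NAMES


def brute_force_auc(values, labels):
    """Exhaustive concordant-pair counting with 1/2 credit for ties."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pos = v[y == 1]
    neg = v[y == 0]
    total = 0.0
    for x in pos:
        for z in neg:
            total += 1.0 if x > z else (0.5 if x == z else 0.0)
    return total / (len(pos) * len(neg))


class TestKsNormality:
    def test_constant_sample_degenerate(self):
        d, p, degenerate = ks_normality([1, 1, 1, 1])
        assert degenerate

    def test_rejects_clearly_non_normal(self):
        rng = np.random.default_rng(0)
        _, p, _ = ks_normality(rng.uniform(0, 1, 1000))
        assert p < 0.01

    def test_null_calibration_at_5_percent(self):
        """Normal samples keep p > 0.05 about 95% of the time."""
        rng = np.random.default_rng(0)
        kept = sum(
            ks_normality(rng.standard_normal(1000))[1] > 0.05
            for _ in range(100)
        )
        assert kept >= 94


class TestTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = independent_t_test(g, g)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_summary_equals_raw_on_matching_samples(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 15)
        raw = independent_t_test(g1, g2)
        summ = summary_t_test(
            20, g1.mean(), g1.std(ddof=1), 15, g2.mean(), g2.std(ddof=1)
        )
        assert raw.t == pytest.approx(summ.t, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)
        assert raw.df == 33

    def test_constant_equal_groups_flagged(self):
        res = summary_t_test(5, 1.0, 0.0, 5, 1.0, 0.0)
        assert res.degenerate

    def test_published_group_summaries_reproduce_printed_t(self):
        res = summary_t_test(22, 1.315, 0.175, 18, 1.956, 0.306)
        assert abs(res.t) == pytest.approx(8.309, rel=5e-3)
        res = summary_t_test(22, 1.084, 0.126, 18, 1.741, 0.213)
        assert abs(res.t) == pytest.approx(12.118, rel=5e-3)


class TestIcc:
    def test_identical_readers_give_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = icc_two_reader(x, x)
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0
        assert res.band == "excellent"

    def test_overwhelming_reader_noise_gives_poor_agreement(self):
        rng = np.random.default_rng(4)
        r1 = rng.normal(0, 1, 40)
        r2 = r1 + rng.normal(0, 20, 40)  # noise SD >> between-subject SD
        res = icc_two_reader(r1, r2)
        assert res.icc < 0.2
        assert res.band == "poor"

    def test_matches_independent_anova_implementation(self):
        data = np.array(
            [[9, 2], [1, 1], [8, 4], [2, 3], [10, 8], [8, 9]], dtype=float
        )
        res = icc_two_reader(data[:, 0], data[:, 1])
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(6), 2),
                "rater": np.tile([0, 1], 6),
                "y": data.ravel(),
            }
        )
        oracle = pg.intraclass_corr(long, targets="subj", raters="rater",
                                    ratings="y")
        icc_a1 = oracle.loc[oracle["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc_a1, abs=1e-6)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_band_cutpoints(self):
        from multibdwi.diagnostics_stats import _agreement_band

        assert _agreement_band(0.15) == "poor"
        assert _agreement_band(0.35) == "fair"
        assert _agreement_band(0.55) == "moderate"
        assert _agreement_band(0.75) == "good"
        assert _agreement_band(0.95) == "excellent"

    def test_listwise_deletion(self):
        r1 = [1.0, 2, 3, 4, 5, np.nan, 7]
        r2 = [1.1, 2, 3, 4, 5, 6, 7.2]
        res = icc_two_reader(r1, r2)
        assert res.n_subjects == 6
        assert res.n_dropped == 1


class TestBlandAltman:
    def test_identical_readers(self):
        x = [1.0, 2.0, 3.0]
        res = bland_altman(x, x)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_symmetric_differences(self):
        res = bland_altman([0.0, 1.0], [1.0, 0.0])  # diffs -1, +1
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2))

    def test_constant_offset(self):
        res = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(1.0)
        assert res.loa_low == res.loa_high == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 2 < res.cutoff < 3

    def test_single_discordant_pair(self):
        assert roc_analysis([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_full_ties_give_chance(self):
        assert roc_analysis([1, 1, 2, 2], [0, 1, 0, 1]).auc == 0.5

    def test_orientation_auto_inverts_lower_is_positive(self):
        # progression-like marker: lower values in the positive class
        res = roc_analysis([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert not res.higher_is_positive

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(4, 13)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            values = rng.integers(0, 5, n).astype(float)  # force ties
            res = roc_analysis(values, labels)
            oriented = values if res.higher_is_positive else -values
            assert res.auc == pytest.approx(
                brute_force_auc(oriented, labels), abs=1e-12
            )

    def test_youden_identity_on_roc_output(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=30)
        labels = (rng.random(30) > 0.5).astype(int)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        res = roc_analysis(values, labels)
        assert res.youden_j == res.sensitivity + res.specificity - 1.0


class TestYouden:
    def test_published_f_row(self):
        assert youden_from_rates(0.8636, 0.6111) == pytest.approx(0.47, abs=5e-3)

    @pytest.mark.parametrize(
        "sens,spec,j", [(1, 1, 1), (0.5, 0.5, 0.0)]
    )
    def test_limits(self, sens, spec, j):
        assert youden_from_rates(sens, spec) == pytest.approx(j)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden_from_rates(1.2, 0.5)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=40)
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        auc_a, auc_b, p = delong_compare(v, v, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_power_against_separated_aucs(self):
        """Binormal AUCs 0.95 vs 0.75, n=200/200: rejection rate > 80%."""
        rng = np.random.default_rng(10)
        rejections = 0
        n = 200
        mu_a = np.sqrt(2) * 1.645  # binormal AUC 0.95
        mu_b = np.sqrt(2) * 0.674  # binormal AUC 0.75
        y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
        for _ in range(500):
            shared = rng.normal(size=2 * n)
            a = shared + np.r_[np.full(n, mu_a), np.zeros(n)] + rng.normal(size=2 * n)
            b = shared + np.r_[np.full(n, mu_b), np.zeros(n)] + rng.normal(size=2 * n)
            if delong_compare(a, b, y)[2] < 0.05:
                rejections += 1
        assert rejections / 500 > 0.80

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(12)
        widths = []
        for n in (50, 200, 800):
            v = np.r_[rng.normal(1.0, 1, n), rng.normal(0, 1, n)]
            y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
            res = roc_analysis(v, y)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): quadrupling n about halves the width
        assert widths[2] < 0.65 * widths[1]

    def test_subject_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 2, 3], [1, 2], [1, 0, 1])


class TestBuildReport:
    def test_full_report_structure(self, study):
        rep = study.report
        assert set(rep.t_tests) == set(MAP_NAMES)
        assert set(rep.roc) == set(MAP_NAMES)
        assert len(rep.delong_pairs) == 15
        assert rep.icc is not None and set(rep.icc) == set(MAP_NAMES)

    def test_single_reader_table_omits_agreement(self, study):
        table = study.lesion_table
        single = table[table.reader == "reader1"]
        rep = build_report(single)
        assert rep.icc is None
        assert rep.bland_altman is None

    def test_permuted_labels_destroy_separation(self, study):
        """Group labels shuffled at random: AUCs collapse toward chance."""
        table = study.lesion_table.copy()
        rng = np.random.default_rng(0)
        subjects = table["subject"].unique()
        groups = (
            table.drop_duplicates("subject").set_index("subject")["group"]
        )
        permuted = pd.Series(
            rng.permutation(groups.to_numpy()), index=groups.index
        )
        table["group"] = table["subject"].map(permuted)
        rep = build_report(table)
        for name, roc in rep.roc.items():
            assert 0.3 < roc.auc < 0.7, name

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            build_report(pd.DataFrame({"subject": [], "group": []}))
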