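import itertools

import numpy as np
import pytest
from scipy import stats as sps

import dtialps as d
from dtialps import StatsError


def pooled_t_oracle(a, b):
    """Hand-evaluated Student pooled-variance t and p (independent of the
    implementation under test)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTests:
    def test_identical_groups(self):
        res = d.t_test_raw([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("a, b", [
        ((1, 2, 3), (4, 5, 6)),
        ((0.2, 1.4, 2.2, 0.9), (1.1, 1.8, 2.9, 3.3, 2.2)),
    ])
    def test_raw_matches_hand_formula(self, a, b):
        res = d.t_test_raw(a, b)
        t, p = pooled_t_oracle(a, b)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        assert res.df == len(a) + len(b) - 2

    def test_raw_equals_summary_on_sufficient_statistics(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.4, 0.3, 42)
        b = rng.normal(1.7, 0.25, 50)
        raw = d.t_test_raw(a, b)
        summ = d.t_test_summary(a.mean(), a.std(ddof=1), a.size,
                                b.mean(), b.std(ddof=1), b.size)
        assert raw.t == pytest.approx(summ.t, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)
        assert raw.df == summ.df

    def test_summary_equal_means(self):
        res = d.t_test_summary(1.0, 0.5, 10, 1.0, 0.7, 12)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            d.t_test_raw([1.0], [2.0, 3.0])
        with pytest.raises(StatsError):
            d.t_test_raw([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(StatsError):
            d.t_test_summary(1.0, -0.1, 10, 2.0, 0.5, 10)

    def test_type_one_error_calibration(self):
        """Under the null (equal distributions) the pooled t test flags at
        alpha = 0.05 with frequency in (0.03, 0.07) over 1000 replicates."""
        rng = np.random.default_rng(7)
        a = rng.normal(1.5, 0.3, size=(25, 1000))
        b = rng.normal(1.5, 0.3, size=(25, 1000))
        _, p = sps.ttest_ind(b, a, axis=0, equal_var=True)
        rate = np.mean(p < 0.05)
        assert 0.03 < rate < 0.07
        # spot-check the vectorised oracle against t_test_raw on one column
        res = d.t_test_raw(a[:, 0], b[:, 0])
        assert res.p == pytest.approx(p[0], rel=1e-12)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = d.pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p <= 1e-300
        res = d.pearson(x, -2 * x + 3)
        assert res.r == pytest.approx(-1.0)

    def test_t_statistic_relation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = d.pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r ** 2))
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)

    @pytest.mark.parametrize("x, y, tol", [
        ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5), 0.05),
        ((1, 2, 3, 4, 5, 6, 7), (2, 1, 4, 3, 5, 7, 6), 0.03),
    ])
    def test_p_agrees_with_exact_permutation(self, x, y, tol):
        """The t-distribution p approximates the exact permutation p over
        all n! orderings (n <= 7)."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        res = d.pearson(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-12)
        count = total = 0
        for perm in itertools.permutations(y):
            r_perm = np.corrcoef(x, perm)[0, 1]
            total += 1
            count += abs(r_perm) >= abs(res.r) - 1e-12
        assert res.p == pytest.approx(count / total, abs=tol)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = d.pearson(x, y).r
        assert d.pearson(3 * x + 1, y).r == pytest.approx(base, rel=1e-12)
        assert d.pearson(-2 * x, y).r == pytest.approx(-base, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            d.pearson([1, 2], [3, 4])
        with pytest.raises(StatsError):
            d.pearson([1, 1, 1], [1, 2, 3])


class TestChiSquare:
    def test_flat_table(self):
        res = d.chi_square_2x2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0
        assert res.p == 1.0
        assert res.df == 1

    def test_hand_evaluated_expected_counts(self):
        """Direct sum((O - E)^2 / E) oracle on the cohort's gender table."""
        table = np.array([[20, 22], [22, 28]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_oracle = float(((table - expected) ** 2 / expected).sum())
        res = d.chi_square_2x2(table.astype(int))
        assert res.chi2 == pytest.approx(chi2_oracle, rel=1e-12)
        assert res.chi2 == pytest.approx(0.1205, abs=5e-4)

    def test_equals_squared_two_proportion_z(self):
        n1, n2, k1, k2 = 42, 50, 20, 22
        p1, p2 = k1 / n1, k2 / n2
        pbar = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        res = d.chi_square_2x2([[k1, n1 - k1], [k2, n2 - k2]])
        assert res.chi2 == pytest.approx(z ** 2, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(StatsError):
            d.chi_square_2x2([[0, 0], [5, 7]])


class TestAnalyzeCohort:
    def _cohort(self, r_age=0.766, r_dur=-0.48, seed=5, n_cae=42, n_hc=50):
        base = d.default_cohort_config()
        cae = d.GroupConfig(n=n_cae, alps=base.cae.alps, age=base.cae.age,
                            duration=base.cae.duration,
                            frequency=base.cae.frequency,
                            r_alps_age=r_age, r_alps_duration=r_dur)
        hc = d.GroupConfig(n=n_hc, alps=base.hc.alps, age=base.hc.age,
                           r_alps_age=base.hc.r_alps_age)
        return d.sample_cohort(d.CohortConfig(cae=cae, hc=hc), seed=seed)

    def test_null_cohort_correlations_small(self):
        subjects = self._cohort(r_age=0.0, r_dur=0.0, n_cae=2000, n_hc=50)
        report = d.analyze_cohort(subjects, use="alps_true")
        assert abs(report.correlations["ALPS vs age (CAE)"].r) < 0.05
        assert abs(report.correlations["ALPS vs duration (CAE)"].r) < 0.05

    def test_recovers_generator_targets_on_truth_values(self):
        subjects = self._cohort(n_cae=2000, n_hc=2000, seed=6)
        report = d.analyze_cohort(subjects, use="alps_true")
        assert report.correlations["ALPS vs age (CAE)"].r == pytest.approx(
            0.766, abs=0.04)
        assert report.correlations["ALPS vs duration (CAE)"].r == pytest.approx(
            -0.48, abs=0.04)
        assert report.correlations["ALPS vs age (HC)"].r == pytest.approx(
            0.651, abs=0.04)
        g = report.group_test
        assert g.mean_a == pytest.approx(1.45, abs=0.03)   # CAE
        assert g.mean_b == pytest.approx(1.66, abs=0.03)   # HC
        assert g.p < 1e-10

    def test_missing_covariate_skipped_with_warning(self, caplog):
        subjects = self._cohort()
        for s in subjects:
            if s.group == "CAE":
                s.frequency = None
        with caplog.at_level("WARNING", logger="dtialps.stats"):
            report = d.analyze_cohort(subjects, use="alps_true")
        assert "ALPS vs frequency (CAE)" not in report.correlations
        assert any("frequency" in r.message for r in caplog.records)
        assert "ALPS vs age (CAE)" in report.correlations

    def test_report_table_and_summary(self):
        subjects = self._cohort()
        report = d.analyze_cohort(subjects, use="alps_true")
        df = report.to_dataframe()
        assert df.shape[0] == 1 + len(report.correlations)
        assert {"analysis", "estimate", "statistic", "p"} <= set(df.columns)
        assert "CAE" in report.summary()

    def test_group_type_one_calibration(self):
        """With identical group ALPS distributions, the group-difference p
        is approximately uniform: its false-positive rate at alpha = 0.05
        stays in (0.03, 0.07) over 500 seeded replicates."""
        rng = np.random.default_rng(11)
        a = rng.normal(1.55, 0.33, size=(42, 500))
        b = rng.normal(1.55, 0.33, size=(50, 500))
        _, p = sps.ttest_ind(b, a, axis=0, equal_var=True)
        assert 0.03 < np.mean(p < 0.05) < 0.07
        assert sps.kstest(p, "uniform").pvalue > 0.01
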