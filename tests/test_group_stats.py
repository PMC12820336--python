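import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from alpsfw.core_io import CohortTable, ValidationError
from alpsfw.group_stats import (
    ancova,
    bh_fdr,
    build_report,
    levene,
    mann_whitney,
    paired_t,
    partial_eta_sq,
    shapiro_wilk,
    spearman,
    two_sample_t,
    two_sample_t_from_summary,
)


def step_up_oracle(pvals, alpha=0.05):
    """Brute-force BH: largest i with p_(i) <= i*alpha/m, reject all below."""
    p = np.asarray(pvals, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestShapiro:
    def test_calibrated_on_normal_samples(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=50)
            hits += shapiro_wilk(x)[1] > 0.05
        assert hits >= 90

    def test_detects_lognormal(self):
        hits = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).normal(size=50))
            hits += shapiro_wilk(x)[1] < 0.05
        assert hits >= 90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.ones(10))

    def test_sample_size_bounds(self):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestLevene:
    def test_location_shift_preserves_spread(self, rng):
        x = rng.normal(size=60)
        y = np.r_[x + 5.0]
        f, p = levene(np.r_[x, y], np.r_[["a"] * 60, ["b"] * 60])
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_detects_unequal_spread(self):
        rng = np.random.default_rng(3)
        x = rng.normal(scale=1.0, size=100)
        y = rng.normal(scale=3.0, size=100)
        _, p = levene(np.r_[x, y], np.r_[["a"] * 100, ["b"] * 100])
        assert p < 0.05

    def test_two_groups_equals_squared_t_on_absolute_deviations(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(scale=2.0, size=25)
        f, _ = levene(np.r_[x, y], np.r_[["a"] * 30, ["b"] * 25], center="mean")
        dx = np.abs(x - x.mean())
        dy = np.abs(y - y.mean())
        t, _, _ = two_sample_t(dx, dy, variant="pooled")
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            levene(np.arange(4.0), np.array(["a", "a", "a", "b"]))


class TestTwoSampleT:
    def test_hama_summary_reproduces_published_t(self):
        """Pooled t from the printed HAMA group summaries: 4.469."""
        t, df, p = two_sample_t_from_summary(6.42, 3.89, 48, 3.60, 0.95, 40)
        assert t == pytest.approx(4.469, rel=0.01)
        assert df == 86
        assert p < 0.001

    def test_age_summary_reproduces_published_t(self):
        t, _, p = two_sample_t_from_summary(46.04, 7.18, 48, 47.10, 8.05, 40)
        assert t == pytest.approx(-0.652, rel=0.01)
        assert p > 0.5

    def test_identical_groups_null(self, rng):
        x = rng.normal(size=30)
        t, df, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, rel=1e-12)

    def test_welch_df_below_pooled_when_unbalanced(self, rng):
        x = rng.normal(scale=1, size=10)
        y = rng.normal(scale=5, size=50)
        _, df_w, _ = two_sample_t(x, y, variant="welch")
        _, df_p, _ = two_sample_t(x, y, variant="pooled")
        assert df_w < df_p


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        """x={1,2}, y={3,4}: U=0, one-sided p = 1/6 by enumeration."""
        u, p = mann_whitney([1, 2], [3, 4], alternative="less")
        assert u == 0
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_identical_multisets_give_half_maximal_u(self):
        x = [1.0, 2.0, 3.0, 5.0]
        u, _ = mann_whitney(x, x)
        assert u == pytest.approx(len(x) * len(x) / 2)

    def test_detects_stochastic_dominance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1, 60)
        y = rng.normal(0.0, 1, 60)
        _, p = mann_whitney(x, y)
        assert p < 0.05


class TestPairedT:
    def test_null_calibration(self):
        pvals = [
            paired_t(
                np.random.default_rng(seed).normal(size=48),
                np.random.default_rng(seed + 10_000).normal(size=48),
            )[2]
            for seed in range(200)
        ]
        assert 0.4 < np.mean(pvals) < 0.6

    def test_unit_shift_detected(self, rng):
        a = rng.normal(size=30)
        b = a + 1.0 + rng.normal(scale=1e-3, size=30)
        t, df, p = paired_t(a, b)
        assert p < 1e-6 and abs(t) > 100 and df == 29

    def test_zero_difference_variance_rejected(self, rng):
        a = rng.normal(size=10)
        with pytest.raises(ValidationError):
            paired_t(a, a)


class TestAncova:
    def _simulate(self, seed, beta_group=0.0, n1=48, n2=40):
        rng = np.random.default_rng(seed)
        group = np.r_[["NIHL"] * n1, ["HC"] * n2]
        age = rng.normal(46, 7, n1 + n2)
        edu = rng.normal(12, 2.5, n1 + n2)
        y = 1.4 + beta_group * (group == "NIHL") - 0.001 * age + 0.002 * edu
        y = y + rng.normal(0, 0.13, n1 + n2)
        return y, group, np.column_stack([age, edu])

    def test_f_equals_t_squared(self):
        y, g, cov = self._simulate(1, beta_group=-0.07)
        res = ancova(y, g, cov)
        assert res.F == pytest.approx(res.t**2, rel=1e-10)

    def test_internal_consistency_and_eta(self):
        y, g, cov = self._simulate(2, beta_group=-0.07)
        res = ancova(y, g, cov)
        assert res.beta == pytest.approx(
            res.adjusted_means["NIHL"][0] - res.adjusted_means["HC"][0], abs=1e-12
        )
        assert res.eta_p2 == pytest.approx(partial_eta_sq(res.F, 1, res.df_resid), rel=1e-12)
        assert res.ci_low < res.beta < res.ci_high
        assert res.df_resid == 88 - 4

    def test_orthogonal_covariates_reduce_to_raw_difference(self):
        """When both groups share identical covariate values, the adjusted
        difference equals the raw mean difference."""
        rng = np.random.default_rng(4)
        n = 30
        group = np.r_[["NIHL"] * n, ["HC"] * n]
        ages = np.linspace(40, 52, n)
        cov = np.tile(np.column_stack([ages, 9 + 0.02 * (ages - 46) ** 2]), (2, 1))
        y = rng.normal(size=2 * n) + 0.3 * (group == "NIHL")
        res = ancova(y, group, cov)
        raw = y[:n].mean() - y[n:].mean()
        assert res.beta == pytest.approx(raw, abs=1e-10)

    def test_matches_pingouin_reference(self):
        """Independent cross-check against an established ANCOVA routine."""
        pingouin = pytest.importorskip("pingouin")
        y, g, cov = self._simulate(7, beta_group=-0.08)
        df = pd.DataFrame({"y": y, "group": g, "age": cov[:, 0], "edu": cov[:, 1]})
        ref = pingouin.ancova(data=df, dv="y", between="group", covar=["age", "edu"])
        row = ref[ref.Source == "group"].iloc[0]
        res = ancova(y, g, cov)
        assert res.F == pytest.approx(row.F, rel=1e-9)
        assert res.p == pytest.approx(row["p_unc"], rel=1e-9)
        assert res.eta_p2 == pytest.approx(row.np2, rel=1e-6)

    def test_collinear_design_rejected(self):
        y, g, cov = self._simulate(5)
        cov = np.column_stack([cov[:, 0], cov[:, 0]])
        with pytest.raises(ValidationError, match="collinear"):
            ancova(y, g, cov)


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F,expected",
        [(7.407, 0.081), (7.852, 0.085), (5.172, 0.058), (5.681, 0.063)],
    )
    def test_published_f_values_reproduce_effect_sizes(self, F, expected):
        assert partial_eta_sq(F, 1, 84) == pytest.approx(expected, abs=5e-4)

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 1, 84) == 0.0


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 25, 100])
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_rank_case(self):
        """d^2 sum = 4 over n=5: r = 1 - 6*4/(5*24) = 0.8."""
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.r == pytest.approx(0.8, rel=1e-12)

    def test_null_calibration(self):
        inside = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            r = spearman(rng.normal(size=48), rng.normal(size=48)).r
            inside += abs(r) < 0.285
        assert 0.92 <= inside / 500 <= 0.98

    def test_equals_pearson_on_midranks_with_ties(self, rng):
        x = rng.integers(0, 8, 60).astype(float)
        y = rng.integers(0, 8, 60).astype(float)
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert res.r == pytest.approx(sps.pearsonr(rx, ry).statistic, rel=1e-12)


class TestBHFDR:
    TABLE4_P = [0.031, 0.004, 0.0005, 0.042, 0.0005, 0.001, 0.048, 0.033,
                0.0005, 0.604, 0.952, 0.652, 0.277, 0.444, 0.473]

    def test_fifteen_correlation_family_survival_pattern(self):
        """Exactly 5 rejections: the three FW correlations plus mean- and
        left-ALPS vs HAMA (the censored '<0.001' entries may take any
        stand-in value below 0.001)."""
        reject, _ = bh_fdr(self.TABLE4_P)
        assert int(reject.sum()) == 5
        assert set(np.where(reject)[0]) == {1, 2, 4, 5, 8}

    def test_pattern_robust_to_censored_standins(self):
        for standin in (1e-6, 5e-4, 9.9e-4):
            p = list(self.TABLE4_P)
            for i in (2, 4, 8):
                p[i] = standin
            reject, _ = bh_fdr(p)
            assert set(np.where(reject)[0]) == {1, 2, 4, 5, 8}

    def test_four_ancova_family_all_survive(self):
        reject, _ = bh_fdr([0.008, 0.006, 0.026, 0.019])
        assert reject.all()

    def test_all_ones_reject_nothing(self):
        reject, adj = bh_fdr(np.ones(10))
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_families_are_independent(self):
        p = [0.01, 0.02, 0.9, 0.01, 0.5]
        rej_joint, _ = bh_fdr(p, families=[[0, 1, 2], [3, 4]])
        rej_a, _ = bh_fdr([0.01, 0.02, 0.9])
        rej_b, _ = bh_fdr([0.01, 0.5])
        assert np.array_equal(rej_joint, np.r_[rej_a, rej_b])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_equals_brute_force_step_up(self, pvals):
        reject, _ = bh_fdr(pvals)
        assert np.array_equal(reject, step_up_oracle(pvals))

    def test_empty_family_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 0.2], families=[[0, 1], []])


def _null_cohort(seed, n1=48, n2=40):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    frame = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": np.r_[["NIHL"] * n1, ["HC"] * n2],
            "age": rng.normal(46, 7, n).round(1),
            "education": rng.normal(12, 2.5, n).round(1),
            "hama": np.abs(rng.normal(5, 3, n)).round(),
            "mtwv": np.r_[rng.uniform(26, 70, n1).round(1), [np.nan] * n2],
        }
    )
    measures = pd.DataFrame(
        {
            "id": frame.id,
            "alps_mean": rng.normal(1.4, 0.13, n),
            "alps_left": rng.normal(1.4, 0.13, n),
            "alps_right": rng.normal(1.4, 0.13, n),
            "fw": rng.uniform(0.05, 0.2, n),
        }
    )
    return measures, CohortTable(frame=frame)


class TestBuildReport:
    def test_imposed_effects_force_table2_signs(self):
        """Ledger-level measures with an imposed NIHL deficit must give
        negative ALPS betas and a positive FW beta."""
        from alpsfw.synthetic_data import CohortSpec, PhantomSpec, simulate_cohort

        cohort = simulate_cohort(
            CohortSpec(phantom=PhantomSpec(grid_shape=(24, 24, 10)), seed=12)
        )
        led = cohort.ledger
        measures = pd.DataFrame(
            {
                "id": led.id,
                "alps_mean": led.alps_mean,
                "alps_left": led.alps_left,
                "alps_right": led.alps_right,
                "fw": led.fw_true,
            }
        )
        report = build_report(measures, cohort.cohort)
        betas = report.table2.set_index("outcome").beta
        assert betas.alps_mean < 0 and betas.alps_left < 0 and betas.alps_right < 0
        assert betas.fw > 0
        # left deficit exceeds the right deficit within NIHL
        t3 = report.table3.set_index("group")
        assert t3.loc["NIHL"].left_mean < t3.loc["NIHL"].right_mean

    def test_null_generator_false_positive_rate(self):
        hits, total = 0, 0
        for seed in range(200):
            measures, cohort = _null_cohort(seed)
            report = build_report(measures, cohort)
            p = np.r_[report.table2.p.to_numpy(), report.table4.p.to_numpy()]
            hits += int((p < 0.05).sum())
            total += len(p)
        assert 0.035 <= hits / total <= 0.065

    def test_structure_and_fdr_consistency(self):
        measures, cohort = _null_cohort(99)
        report = build_report(measures, cohort)
        assert len(report.table1) == 4
        assert len(report.table2) == 4
        assert len(report.table3) == 2
        assert len(report.table4) == 15
        for tbl in (report.table2, report.table4):
            rej, adj = bh_fdr(tbl.p.to_numpy())
            assert np.array_equal(tbl.significant_fdr.to_numpy(), rej)
            assert np.allclose(tbl.p_fdr.to_numpy(), adj)

    def test_missing_measurements_excluded_and_logged(self):
        measures, cohort = _null_cohort(5)
        measures.loc[3, "fw"] = np.nan
        report = build_report(measures, cohort)
        assert report.excluded == [cohort.frame.id.iloc[3]]
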