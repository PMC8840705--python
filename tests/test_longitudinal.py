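import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import friedmanchisquare

from mgslong import longitudinal as lg
from mgslong._nonparametric import benjamini_hochberg, friedman_test, ld_f1_anova_type
from mgslong.io_model import MgsAbundanceTable
from mgslong.synthetic_data import SimulationConfig, simulate_abundances, simulate_bss

from conftest import make_metadata

BEFORE = lg.Period(("D-30", "D-14", "D-1"), "before")
DURING = lg.Period(("D-1", "D8", "D35"), "during")


class TestPrevalenceFilter:
    def test_strictly_more_than_threshold(self):
        # 17/170 = exactly 10% -> dropped; 18/170 -> kept
        n = 170
        col_a = np.zeros(n)
        col_a[:17] = 1.0
        col_b = np.zeros(n)
        col_b[:18] = 1.0
        t = MgsAbundanceTable(
            pd.DataFrame(
                {"a": col_a, "b": col_b}, index=[f"s{i}" for i in range(n)]
            )
        )
        kept = lg.prevalence_filter(t, 0.10)
        assert kept.mgs_ids == ["b"]

    def test_generator_known_prevalences(self):
        rng = np.random.default_rng(0)
        pres = {"f1": 0.05, "f2": 0.3, "f3": 0.8}
        n = 200
        data = {k: (rng.random(n) < v).astype(float) for k, v in pres.items()}
        t = MgsAbundanceTable(pd.DataFrame(data, index=[f"s{i}" for i in range(n)]))
        expected = [k for k in pres if (t.abundance[k] > 0).mean() > 0.10]
        assert lg.prevalence_filter(t, 0.10).mgs_ids == expected


class TestTrajectory:
    def test_constant_abundance_all_zero(self):
        v = lg.log_fold_trajectory([0.3, 0.3, 0.3], pseudo=1e-6)
        assert np.allclose(v, 0.0)

    def test_tenfold_rise(self):
        v = lg.log_fold_trajectory([0.1, 1.0, 1.0], pseudo=1e-9)
        assert v[0] == 0.0
        assert np.allclose(v[1:], 1.0, atol=1e-6)

    def test_zero_baseline_finite(self):
        v = lg.log_fold_trajectory([0.0, 1.0], pseudo=1e-4)
        assert np.isfinite(v).all() and v[1] > 3


class TestAucStatistic:
    def test_constant_trajectory_exactly_zero(self):
        for days in ([-30, -14, -1], [-1, 8, 35], [-30, -14, -1, 8, 35]):
            assert lg.auc_statistic(np.zeros(len(days)), days) == 0.0

    def test_simple_triangle(self):
        # v=(0,1) over days (-1,35): area 18, span 36 -> 0.5 normalized
        assert lg.auc_statistic([0, 1], [-1, 35]) == pytest.approx(0.5)
        assert lg.auc_statistic([0, 1], [-1, 35], normalize=False) == pytest.approx(18)

    def test_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        days = np.array([-30.0, -14.0, -1.0, 8.0, 35.0])
        for _ in range(100):
            v = rng.normal(size=5)
            v[0] = 0.0
            grid = np.linspace(days[0], days[-1], 200001)
            fine = np.trapezoid(np.interp(grid, days, v), grid)
            assert lg.auc_statistic(v, days, normalize=False) == pytest.approx(
                fine, abs=1e-8
            )

    @given(
        st.lists(st.floats(-5, 5), min_size=5, max_size=5),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    def test_linearity_and_time_shift_invariance(self, vals, shift, scale):
        days = np.array([-30.0, -14.0, -1.0, 8.0, 35.0])
        v = np.asarray(vals)
        a = lg.auc_statistic(v, days)
        # linear in the trajectory
        assert lg.auc_statistic(scale * v, days) == pytest.approx(scale * a, abs=1e-9)
        # invariant to adding a constant to all day offsets
        assert lg.auc_statistic(v, days + shift) == pytest.approx(a, abs=1e-9)

    def test_sign_follows_monotone_cases(self):
        days = [-1, 8, 35]
        assert lg.auc_statistic([0, 0.5, 1.0], days) > 0
        assert lg.auc_statistic([0, -0.5, -1.0], days) < 0

    def test_under_two_points_undefined(self):
        assert np.isnan(lg.auc_statistic([0.0], [1.0]))


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        m = np.tile(np.arange(6)[:, None], (1, 3)).astype(float)
        chi2, p, pairwise = lg.friedman_with_nemenyi(m)
        assert chi2 == 0.0 and p == 1.0
        assert (pairwise >= 0.99).all()

    def test_hand_rank_oracle_six_by_three(self):
        # ranks per subject computed by hand for a fixed 6x3 matrix
        m = np.array(
            [[1, 2, 3], [1, 3, 2], [2, 1, 3], [1, 2, 3], [3, 1, 2], [1, 2, 3]],
            dtype=float,
        )
        # column rank sums: [9, 11, 16]; chi2 = 12/(6*3*4)*Sum(Rj^2)-3*6*4
        expect = 12 / (6 * 3 * 4) * (81 + 121 + 256) - 72
        chi2, p = friedman_test(m)
        assert chi2 == pytest.approx(expect)
        scipy_res = friedmanchisquare(*m.T)
        assert chi2 == pytest.approx(scipy_res.statistic)
        assert p == pytest.approx(scipy_res.pvalue)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = rng.integers(0, 4, size=(9, 4)).astype(float)
            chi2, p = friedman_test(m)
            res = friedmanchisquare(*m.T)
            assert chi2 == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue)

    def test_strict_ordering_minimal_p(self):
        rng = np.random.default_rng(3)
        n, k = 10, 4
        increasing = np.cumsum(rng.random((n, k)) + 0.1, axis=1)
        chi2_max = 12 / (n * k * (k + 1)) * np.sum(
            (n * np.arange(1, k + 1)) ** 2.0
        ) - 3 * n * (k + 1)
        chi2, p = friedman_test(increasing)
        assert chi2 == pytest.approx(chi2_max)
        shuffled = increasing.copy()
        rng.shuffle(shuffled.T)
        assert friedman_test(shuffled)[0] <= chi2 + 1e-9

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.zeros((5, 1)))


class TestBenjaminiHochberg:
    def test_equals_brute_force_step_up(self):
        rng = np.random.default_rng(4)

        def brute(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q

        for _ in range(50):
            p = rng.random(rng.integers(1, 25))
            assert np.allclose(benjamini_hochberg(p), brute(p))

    def test_monotone_in_p_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestCompareEvolution:
    def test_constant_feature_untested_and_unflagged(self):
        meta = make_metadata(8)
        t = MgsAbundanceTable(
            pd.DataFrame(
                {"flat": 0.5, "also_flat": 0.1},
                index=meta.sample_ids,
            )
        )
        res = lg.compare_evolution(t, meta, BEFORE, DURING)
        assert res["p_auc"].isna().all()
        assert not res["changed_before"].any()
        assert not res["changed_during"].any()

    def test_on_treatment_shift_detected_and_localized(self):
        from mgslong.synthetic_data import TreatmentEffect

        cfg = SimulationConfig(
            n_subjects=25,
            n_mgs=40,
            richness_mean=30,
            treatment_effects=(TreatmentEffect("MGS0001", 4.0, "D8"),),
        )
        latent, _ = simulate_abundances(cfg, 11)
        meta, _ = simulate_bss(cfg, 12)
        res = lg.compare_evolution(latent, meta, BEFORE, DURING)
        assert res.loc["MGS0001", "p_auc"] <= 0.05
        assert res.loc["MGS0001", "changed_during"]
        assert not res.loc["MGS0001", "changed_before"]

    def test_pre_treatment_shift_flagged_before_not_during(self):
        from mgslong.synthetic_data import TreatmentEffect

        cfg = SimulationConfig(
            n_subjects=25,
            n_mgs=40,
            richness_mean=30,
            treatment_effects=(TreatmentEffect("MGS0002", 4.0, "D-14"),),
        )
        latent, _ = simulate_abundances(cfg, 13)
        meta, _ = simulate_bss(cfg, 14)
        res = lg.compare_evolution(latent, meta, BEFORE, DURING)
        assert res.loc["MGS0002", "p_auc"] <= 0.05
        assert res.loc["MGS0002", "changed_before"]
        assert not res.loc["MGS0002", "changed_during"]

    def test_min_paired_subjects_enforced(self):
        meta = make_metadata(4)
        rng = np.random.default_rng(5)
        t = MgsAbundanceTable(
            pd.DataFrame(
                rng.random((len(meta.sample_ids), 3)),
                index=meta.sample_ids,
                columns=list("abc"),
            )
        )
        res = lg.compare_evolution(t, meta, BEFORE, DURING, min_paired=5)
        assert res["p_auc"].isna().all()

    def test_subject_missing_initial_visit_excluded(self):
        meta = make_metadata(8, drop={(0, "D-30")})
        rng = np.random.default_rng(6)
        t = MgsAbundanceTable(
            pd.DataFrame(
                rng.random((len(meta.sample_ids), 2)),
                index=meta.sample_ids,
                columns=list("ab"),
            )
        )
        aucs = lg.period_aucs(t, meta, BEFORE)
        assert np.isnan(aucs.loc["S01"]).all()
        assert np.isfinite(aucs.loc["S02"]).all()


class TestCorrelateBss:
    def test_richness_equal_to_bss_gives_rho_one(self, schedule):
        meta = make_metadata(10)
        df = meta.table.copy()
        df["bss"] = (df.index % 6) + 1
        from mgslong.io_model import SampleMetadata

        meta = SampleMetadata(df, schedule)
        values = meta.table.set_index("sample_id")["bss"].astype(float).rename("rich")
        res = lg.correlate_bss(values, meta)
        valid = res.dropna(subset=["rho"])
        assert (valid["rho"] > 0.999).all()

    def test_planted_bss_linked_feature_recovered(self, schedule):
        rng = np.random.default_rng(7)
        meta_df = make_metadata(30).table.copy()
        meta_df["bss"] = rng.integers(1, 8, size=len(meta_df))
        from mgslong.io_model import SampleMetadata

        meta = SampleMetadata(meta_df, schedule)
        bss = meta.table.set_index("sample_id")["bss"].astype(float)
        linked = bss * 0.01 + rng.normal(0, 0.001, len(bss))
        noise = pd.Series(rng.random(len(bss)), index=bss.index)
        t = pd.DataFrame({"linked": linked, "noise": noise})
        res = lg.correlate_bss(t, meta)
        link = res[res["feature"] == "linked"]
        assert (link["p"] <= 0.05).all()
        assert (link["rho"] > 0).all()
        summary = lg.bss_consistency_summary(res)
        assert summary.loc["linked", "n_visits_significant"] == 5
        assert summary.loc["linked", "sign_consistent"]

    def test_independent_feature_sign_consistency_rate(self):
        # for a feature independent of BSS, the probability that three
        # independent correlation signs agree is 2/2^3 = 25%
        rng = np.random.default_rng(8)
        agree = 0
        reps = 400
        for _ in range(reps):
            signs = np.sign(rng.normal(size=3))
            agree += int(np.all(signs == signs[0]))
        rate = agree / reps
        assert abs(rate - 0.25) < 3 * np.sqrt(0.25 * 0.75 / reps)

    def test_constant_bss_reported_undefined(self):
        meta = make_metadata(10, bss_value=4)
        rng = np.random.default_rng(9)
        values = pd.Series(
            rng.random(len(meta.sample_ids)), index=meta.sample_ids, name="rich"
        )
        res = lg.correlate_bss(values, meta)
        assert res["rho"].isna().all()


class TestLdF1:
    def test_all_tied_gives_p_one(self):
        stat, df, p = ld_f1_anova_type(np.ones((6, 4)))
        assert stat == 0.0 and p == 1.0

    def test_strong_time_trend_significant(self):
        rng = np.random.default_rng(10)
        m = np.cumsum(np.abs(rng.normal(size=(12, 4))) + 0.5, axis=1)
        _, _, p = ld_f1_anova_type(m)
        assert p < 1e-6

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        ps = np.array(
            [ld_f1_anova_type(rng.normal(size=(15, 4)))[2] for _ in range(400)]
        )
        rate = float((ps <= 0.05).mean())
        assert 0.02 <= rate <= 0.09
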