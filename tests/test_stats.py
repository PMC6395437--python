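import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptw.cohort import CohortSpec, REFERENCE_DEMOGRAPHICS, simulate_cohort
from aptw.io import CohortTable
from aptw.stats import (
    TIME_BINS,
    anova_lsd,
    assign_time_bin,
    build_tables,
    pearson,
    ttest_ind,
)


class TestTimeBins:
    @pytest.mark.parametrize(
        "hours,label",
        [
            (12, "<=96h"),
            (95.99, "<=96h"),
            (96.0, "4-7d"),  # a recorded "4 days" belongs to the 4-7 day bin
            (4 * 24, "4-7d"),
            (168.0, "4-7d"),
            (168.01, "8-21d"),
            (21 * 24, "8-21d"),
            (504.01, ">=22d"),
            (34 * 24, ">=22d"),
        ],
    )
    def test_edge_rule(self, hours, label):
        assert assign_time_bin(hours).label == label

    @given(st.floats(min_value=1e-3, max_value=5000.0, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_partition_is_total_and_unique(self, h):
        hits = [b.label for b in TIME_BINS if h in b]
        assert len(hits) == 1

    @pytest.mark.parametrize("h", [0.0, -5.0])
    def test_nonpositive_time_rejected(self, h):
        with pytest.raises(ValueError):
            assign_time_bin(h)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(6.0)
        assert pearson(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1.0, 2.5, 3.1, 4.9, 5.2, 7.8])
        y = np.array([2.1, 1.7, 3.9, 4.4, 3.1, 6.0])
        # brute-force product-moment formula
        xm, ym = x - x.mean(), y - y.mean()
        r_oracle = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert pearson(x, y).statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson(np.ones(5), np.arange(5.0))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestTTest:
    def test_identical_samples_give_t0_p1(self):
        a = np.array([1.0, 1.0, 1.0])
        res = ttest_ind(a, a)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_pooled_formula_oracle(self):
        a = np.array([1.2, 2.3, 1.8, 2.9])
        b = np.array([2.0, 3.1, 2.7, 3.9])
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert ttest_ind(a, b).statistic == pytest.approx(t_oracle, abs=1e-12)

    def test_swapping_samples_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 8)
        r1, r2 = ttest_ind(a, b), ttest_ind(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest_ind(np.ones(3), np.full(3, 2.0))

    def test_welch_option(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 5), rng.normal(0, 5, 20)
        assert ttest_ind(a, b, equal_var=False).df != len(a) + len(b) - 2


class TestAnovaLsd:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 7), rng.normal(0.8, 1, 9)
        res_f = anova_lsd([a, b])
        res_t = ttest_ind(a, b)
        assert res_f.statistic == pytest.approx(res_t.statistic**2, abs=1e-10)

    def test_matches_sum_of_squares_oracle(self):
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([2.5, 3.5, 4.0, 4.5]),
            np.array([5.0, 6.0]),
        ]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_oracle = (ssb / 2) / (ssw / (len(allv) - 3))
        assert anova_lsd(groups).statistic == pytest.approx(F_oracle, abs=1e-10)

    def test_equal_group_means_give_zero_f(self):
        res = anova_lsd([np.array([-1.0, 1.0]), np.array([-2.0, 2.0]), np.array([0.5, -0.5])])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            anova_lsd([np.ones(3), np.ones(4)])

    def test_undersized_groups_reported_but_excluded(self):
        res = anova_lsd({"a": np.array([1.0, 2.0]), "b": np.array([2.0, 3.0]), "c": np.array([5.0])})
        assert res.group_ns == (2, 2, 1)
        labels = set(res.pairwise["group_a"]) | set(res.pairwise["group_b"])
        assert "c" not in labels

    def test_lsd_pairwise_uses_pooled_mse_without_correction(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.5, 2.0)]
        res = anova_lsd(groups)
        # hand-compute the (0, 2) pair
        allv = np.concatenate(groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        mse = ssw / (len(allv) - 3)
        t = (groups[0].mean() - groups[2].mean()) / np.sqrt(mse * (1 / 6 + 1 / 6))
        row = res.pairwise[(res.pairwise["group_a"] == "0") & (res.pairwise["group_b"] == "2")]
        assert row["t"].iloc[0] == pytest.approx(t, abs=1e-12)


class TestCohortSimulation:
    def test_zero_spread_collapses_to_group_mean(self):
        spec = CohortSpec(lesion_sd_pct=0.0, cnawm_sd_pct=0.0, nihss_sd=0.0, include_followups=False)
        t = simulate_cohort(spec, seed=0)
        assert np.allclose(t.df["lesion_aptw_pct"], spec.lesion_mean_pct)
        assert np.allclose(t.df["cnawm_aptw_pct"], spec.cnawm_mean_pct)

    def test_perfect_linkage_gives_sample_r_of_one(self):
        # NIHSS centered mid-scale so no draw hits the clip bounds
        spec = CohortSpec(
            nihss_lesion_r=-1.0, nihss_mean=21.0, integer_nihss=False, include_followups=False
        )
        t = simulate_cohort(spec, seed=1)
        r = pearson(t.df["lesion_aptw_pct"], t.df["nihss"]).statistic
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CohortSpec(nihss_lesion_r=1.2)

    def test_determinism(self):
        a = simulate_cohort(seed=9).df
        b = simulate_cohort(seed=9).df
        pd.testing.assert_frame_equal(a, b)

    def test_reference_structure(self):
        t = simulate_cohort(seed=0)
        assert len(t.pre_treatment) == 43
        assert t.post_treatment["patient_id"].nunique() == 26
        assert sum(len(p.followups_days) for p in REFERENCE_DEMOGRAPHICS) == 44


class TestBuildTables:
    def test_template_onset_bins(self):
        t = simulate_cohort(seed=0)
        rep = build_tables(t)
        lesion = rep.by_onset_time[rep.by_onset_time["measure"] == "lesion"]
        ns = dict(zip(lesion["onset_bin"], lesion["n_pre"]))
        assert ns == {"<=96h": 30, "4-7d": 13, "8-21d": 0, ">=22d": 0}

    def test_post_groups_exclude_ineffective_cases(self):
        t = simulate_cohort(seed=0)
        rep = build_tables(t)
        lesion = rep.by_treatment_time[rep.by_treatment_time["measure"] == "lesion"]
        n_post = lesion[lesion["group"] != "pre"]["n"].sum()
        assert n_post == 42  # 44 follow-ups minus the two ineffective cases

    def test_identical_pre_and_post_rows_give_p_near_one(self):
        pre = simulate_cohort(CohortSpec(include_followups=False), seed=2).df
        pre["effective"] = True  # no exclusions: post must mirror pre exactly
        post = pre.copy()
        post["scan_id"] = post["scan_id"].str.replace("-0", "-1")
        post["post_treatment_time_h"] = 48.0
        post["treated"] = True
        df = pd.concat([pre, post], ignore_index=True)
        rep = build_tables(CohortTable(df=df))
        lesion = rep.by_treatment_time[rep.by_treatment_time["measure"] == "lesion"]
        p = lesion[lesion["group"] == "<=96h"]["p_vs_pre"].iloc[0]
        assert p > 0.99

    def test_group_means_track_generator_truth(self):
        reps = [build_tables(simulate_cohort(seed=s)) for s in range(20)]
        vals = []
        for rep in reps:
            lesion = rep.by_treatment_time[rep.by_treatment_time["measure"] == "lesion"]
            vals.append(float(lesion[lesion["group"] == "pre"]["mean"].iloc[0]))
        # MC error of the mean of 20 cohort means: 0.91/sqrt(20*43) ~ 0.031
        assert np.mean(vals) == pytest.approx(-1.01, abs=0.1)
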