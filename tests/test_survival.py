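"""Marker-validation statistics: standardization, the Bonferroni panel
gate, Cox fits, dichotomization, exact association tests, correlations,
subgroup analysis and the multivariate model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiomorph.survival import (
    association_test,
    bonferroni_gate,
    dichotomize_median,
    evaluate_panel,
    fast_cox_single,
    fit_continuous_cox,
    km_logrank,
    marker_correlations,
    multivariate_cox,
    split_pilot_validation,
    standardize,
    subgroup_survival,
)
from angiomorph.synthetic import CohortSpec, generate_cohort, simulate_endpoint


def _null_cohort(n=300, seed=0):
    return generate_cohort(CohortSpec(
        n_patients=n, seed=seed,
        true_log_hr_per_sd={m: (0.0, 0.0) for m in CohortSpec().true_log_hr_per_sd},
    ))


class TestStandardize:
    def test_three_values(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([5, 5, 5])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=60, unique=True))
    def test_output_mean_zero_sd_one(self, values):
        z = standardize(values)
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestBonferroniGate:
    def test_panel_of_seven(self):
        threshold, _ = bonferroni_gate([0.01] * 7, alpha=0.05, m=7)
        assert round(threshold, 4) == 0.0071

    def test_single_test_threshold_is_alpha(self):
        threshold, _ = bonferroni_gate([0.04], alpha=0.05, m=1)
        assert threshold == 0.05

    def test_exact_threshold_passes(self):
        threshold, decisions = bonferroni_gate([0.05 / 7], alpha=0.05, m=7)
        assert decisions[0]


class TestContinuousCox:
    def test_fast_solver_matches_lifelines(self):
        df = _null_cohort(n=400, seed=3)
        df["z"] = standardize(df["mvp_mean_um"])
        res = fit_continuous_cox(df, "mvp_mean_um", "ddfs")
        beta, se, p = fast_cox_single(df.ddfs_months.to_numpy(),
                                      df.ddfs_event.to_numpy().astype(bool),
                                      df.z.to_numpy())
        assert math.exp(beta) == pytest.approx(res.hr, rel=1e-5)
        assert p == pytest.approx(res.p, rel=1e-3, abs=1e-8)

    def test_negating_the_marker_inverts_the_hr(self):
        df = _null_cohort(n=300, seed=4)
        df["neg"] = -df["mvp_mean_um"]
        a = fit_continuous_cox(df, "mvp_mean_um", "bcss")
        b = fit_continuous_cox(df, "neg", "bcss")
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-6)
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_no_events_is_flagged(self):
        df = _null_cohort(n=50, seed=5)
        df["ddfs_event"] = 0
        res = fit_continuous_cox(df, "mvp_mean_um", "ddfs")
        assert not res.converged and math.isnan(res.hr)

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            fit_continuous_cox(_null_cohort(50), "mvp_mean_um", "os")


class TestDichotomize:
    def test_even_split(self):
        labels = dichotomize_median([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = dichotomize_median([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_odd_n_gives_uneven_split(self):
        rng = np.random.default_rng(0)
        labels = dichotomize_median(rng.normal(size=293))
        low, high = (labels == "low").sum(), (labels == "high").sum()
        assert (low, high) == (147, 146)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_median([2, 2, 2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=80, unique=True))
    def test_low_group_never_smaller(self, values):
        labels = dichotomize_median(values)
        assert (labels == "low").sum() >= (labels == "high").sum()


class TestKmLogrank:
    def test_null_groups_hr_near_one(self):
        df = _null_cohort(n=800, seed=6)
        groups = dichotomize_median(df["icd_um"])
        res = km_logrank(df, groups, "ddfs")
        assert 0.6 < res.hr < 1.6
        assert res.logrank_p > 0.001
        assert set(res.curves) == {"low", "high"}

    def test_doubled_hazard_recovered(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = np.repeat([0.0, 1.0], n // 2)
        time, event = simulate_endpoint(np.log(2.0) * x, rng, event_fraction=0.5)
        df = pd.DataFrame({"ddfs_months": time, "ddfs_event": event.astype(int)})
        res = km_logrank(df, np.where(x > 0, "high", "low"), "ddfs")
        assert 1.7 <= res.hr <= 2.35
        assert res.logrank_p < 1e-6

    def test_all_censored_is_an_error(self):
        df = _null_cohort(n=60, seed=8)
        df["ddfs_event"] = 0
        with pytest.raises(ValueError, match="no events"):
            km_logrank(df, dichotomize_median(df["icd_um"]), "ddfs")

    def test_single_group_is_an_error(self):
        df = _null_cohort(n=60, seed=9)
        with pytest.raises(ValueError):
            km_logrank(df, np.repeat("low", len(df)), "ddfs")


class TestAssociationTest:
    def test_published_style_2x2_table(self):
        """Monte-Carlo exact Pearson p on a strongly associated 2x2 table
        ([[5, 22], [142, 124]]) lands near 0.001."""
        labels = ["low"] * 147 + ["high"] * 146
        covariate = (["presence"] * 5 + ["absence"] * 142
                     + ["presence"] * 22 + ["absence"] * 124)
        p = association_test(labels, covariate, seed=1)
        assert 1e-4 <= p <= 3e-3

    def test_identical_rows_give_p_one(self):
        labels = ["a"] * 40 + ["b"] * 40
        covariate = (["x"] * 20 + ["y"] * 20) * 2
        assert association_test(labels, covariate, seed=2) == pytest.approx(1.0)

    def test_independent_labels_not_significant(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["a", "b"], size=400)
        covariate = rng.choice(["x", "y", "z"], size=400)
        assert association_test(labels, covariate, seed=4) > 0.01

    def test_ordered_trend_detects_monotone_association(self):
        labels, covariate = [], []
        for grade, (n_low, n_high) in enumerate([(40, 22), (83, 60), (24, 64)], 1):
            labels += ["low"] * n_low + ["high"] * n_high
            covariate += [grade] * (n_low + n_high)
        p_trend = association_test(labels, covariate, ordered=True, seed=5)
        assert p_trend < 0.001

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            association_test(["a"] * 10, ["x"] * 5 + ["y"] * 5)


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(20.0)
        r2, tau2 = marker_correlations(x, 3 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert tau2 == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 3, 50)
        r2, tau2 = marker_correlations(x, np.exp(3 * x))
        assert tau2 == pytest.approx(1.0)
        assert r2 < 1.0

    def test_categorized_uses_median_split(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        y = x + rng.normal(scale=1.0, size=500)
        r2, tau2 = marker_correlations(x, y, categorized=True)
        assert 0 < tau2 < r2  # dichotomization loses association strength

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            marker_correlations([1, 1, 1, 1], [1, 2, 3, 4])


class TestSubgroup:
    @staticmethod
    def _interaction_cohort(seed, hr_in_a=4.0, n=600):
        """Binary factor prognostic (HR hr_in_a) in stratum A only."""
        rng = np.random.default_rng(seed)
        stratum = np.repeat(["A", "B"], n // 2)
        factor = (rng.random(n) < 0.4).astype(int)
        eta = np.where(stratum == "A", np.log(hr_in_a) * factor, 0.0)
        time, event = simulate_endpoint(eta, rng, event_fraction=0.35)
        return pd.DataFrame({
            "stratum": stratum, "factor": factor,
            "ddfs_months": time, "ddfs_event": event.astype(int),
        })

    def test_stratum_specific_effect_detected(self):
        df = self._interaction_cohort(seed=21)
        res = subgroup_survival(df, df["stratum"], "factor", "ddfs")
        assert res["strata"]["A"].km.logrank_p < 0.05
        assert res["strata"]["B"].km.logrank_p >= 0.05
        assert res["hr_outside_other_ci"]["A"]

    def test_swapping_strata_swaps_results(self):
        df = self._interaction_cohort(seed=22)
        res = subgroup_survival(df, df["stratum"], "factor", "ddfs")
        swapped = subgroup_survival(
            df, df["stratum"].map({"A": "B", "B": "A"}), "factor", "ddfs")
        assert res["strata"]["A"].km.hr == pytest.approx(swapped["strata"]["B"].km.hr)

    def test_eventless_stratum_is_flagged(self):
        df = self._interaction_cohort(seed=23)
        df.loc[df.stratum == "B", "ddfs_event"] = 0
        res = subgroup_survival(df, df["stratum"], "factor", "ddfs")
        assert res["strata"]["B"].km is None
        assert res["strata"]["B"].flagged


class TestMultivariate:
    def test_single_covariate_reduces_to_univariate(self):
        df = _null_cohort(n=300, seed=31)
        df["z"] = standardize(df["mvp_mean_um"])
        uni = fit_continuous_cox(df, "mvp_mean_um", "ddfs")
        multi = multivariate_cox(df, ["z"], "ddfs")
        assert multi.hr.iloc[0] == pytest.approx(uni.hr, abs=1e-8)
        assert multi.p.iloc[0] == pytest.approx(uni.p, abs=1e-8)

    def test_two_independent_effects_recovered(self):
        rng = np.random.default_rng(32)
        n = 800
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        time, event = simulate_endpoint(0.5 * x1 - 0.4 * x2, rng, event_fraction=0.5)
        df = pd.DataFrame({"x1": x1, "x2": x2, "ddfs_months": time,
                           "ddfs_event": event.astype(int)})
        res = multivariate_cox(df, ["x1", "x2"], "ddfs").set_index("covariate")
        assert res.loc["x1", "ci_low"] <= math.exp(0.5) <= res.loc["x1", "ci_high"]
        assert res.loc["x2", "ci_low"] <= math.exp(-0.4) <= res.loc["x2", "ci_high"]

    def test_low_events_per_variable_warns(self):
        df = _null_cohort(n=80, seed=33)
        df["z1"] = standardize(df["mvp_mean_um"])
        df["z2"] = standardize(df["icd_um"])
        df["z3"] = standardize(df["mva_cv"])
        with pytest.warns(UserWarning, match="events per variable"):
            multivariate_cox(df, ["z1", "z2", "z3"], "bcss")


class TestPanel:
    MARKERS = list(CohortSpec().true_log_hr_per_sd)

    def test_dual_endpoint_rule_is_conservative(self):
        df = generate_cohort(CohortSpec(n_patients=400, seed=41))
        panel = evaluate_panel(df, self.MARKERS)
        t = panel.table
        for marker, flag in panel.prognostic.items():
            per_endpoint = t[t.marker == marker]["passes"]
            assert flag == bool(per_endpoint.all())
            if flag:
                assert per_endpoint.any()

    def test_threshold_is_alpha_over_panel_size(self):
        df = generate_cohort(CohortSpec(n_patients=200, seed=42))
        panel = evaluate_panel(df, self.MARKERS, alpha=0.05)
        assert panel.threshold == pytest.approx(0.05 / 7)

    def test_strong_effect_is_flagged(self):
        spec = CohortSpec(
            n_patients=500, seed=43,
            true_log_hr_per_sd={"mvp_mean_um": (np.log(1.8), np.log(1.8))},
            censoring_fraction_ddfs=0.6, censoring_fraction_bcss=0.6,
        )
        df = generate_cohort(spec)
        panel = evaluate_panel(df, self.MARKERS)
        assert panel.prognostic["mvp_mean_um"]


class TestSplit:
    def test_sizes_and_disjointness(self):
        df = _null_cohort(n=394, seed=51)
        pilot, validation = split_pilot_validation(df, pilot_fraction=0.25, seed=1)
        assert len(pilot) == round(0.25 * 394)
        assert len(pilot) + len(validation) == 394
        assert set(pilot.patient_id).isdisjoint(validation.patient_id)

    def test_seeded_reproducibility(self):
        df = _null_cohort(n=100, seed=52)
        a, _ = split_pilot_validation(df, seed=9)
        b, _ = split_pilot_validation(df, seed=9)
        assert a.equals(b)
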