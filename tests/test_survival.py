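import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alfnet.survival import (
    brier_score,
    compare_groups,
    composite_score,
    cox_fit,
    idi_nri,
    km_logrank,
    roc_analysis,
    run_full_analysis,
    z_transform,
)
from _oracles import auc_pair_counting, breslow_neg_log_pl


class TestCompareGroups:
    def test_identical_groups_not_rejected(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"g": ["a"] * 100 + ["b"] * 100, "v": np.r_[x, x]})
        _, p, _ = compare_groups(df, "v", group_col="g")
        assert p > 0.9

    def test_chi_squared_hand_oracle(self):
        # 2x2 table (20,10 / 10,20): chi2 = sum (O-E)^2/E = 6.667 uncorrected
        df = pd.DataFrame(
            {
                "g": ["a"] * 30 + ["b"] * 30,
                "v": [0] * 20 + [1] * 10 + [0] * 10 + [1] * 20,
            }
        )
        stat, p, test = compare_groups(df, "v", group_col="g")
        assert test == "chi-squared"
        assert stat == pytest.approx(20 / 3, abs=1e-10)

    def test_shift_alternative_power(self):
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "g": ["a"] * 200 + ["b"] * 200,
                    "v": np.r_[
                        rng.standard_normal(200), rng.standard_normal(200) + 1.0
                    ],
                }
            )
            _, p, _ = compare_groups(df, "v", group_col="g")
            rejections += p < 0.05
        assert rejections == 10  # >99% power regime

    def test_skewed_data_uses_mann_whitney(self, rng):
        df = pd.DataFrame(
            {
                "g": ["a"] * 150 + ["b"] * 150,
                "v": rng.lognormal(0, 1.5, 300),
            }
        )
        _, _, test = compare_groups(df, "v", group_col="g")
        assert test == "mann-whitney"


class TestZTransform:
    def test_three_point_example(self):
        np.testing.assert_allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self, rng):
        z = z_transform(rng.lognormal(0, 1, 500))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_allclose(z_transform(z_transform(x)), z_transform(x), atol=1e-12)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="standard deviation"):
            z_transform([2.0, 2.0, 2.0])

    def test_missing_values_ignored(self):
        z = z_transform([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and z[0] == -z[2]


class TestCox:
    def test_six_subject_brute_force_grid(self):
        # tied event times force genuine Breslow handling
        df = pd.DataFrame(
            {
                "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
                "time": [2.0, 4.0, 4.0, 6.0, 8.0, 8.0],
                "event": [1, 1, 1, 0, 1, 1],
            }
        )
        fit = cox_fit(df, ["x"], tie_method="breslow")
        grid = np.linspace(-3, 3, 60001)
        x, t, e = df["x"].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy()
        lls = [breslow_neg_log_pl(b, x, t, e) for b in grid]
        b_star = grid[int(np.argmin(lls))]
        assert fit.terms[0].beta == pytest.approx(b_star, abs=1e-4)

    def test_agrees_with_lifelines_efron(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        T = rng.exponential(1 / (0.1 * np.exp(0.4 * x1 - 0.3 * x2)))
        df = pd.DataFrame(
            {
                "x1": x1,
                "x2": x2,
                "time": np.minimum(T, 15.0),
                "event": (T < 15.0).astype(int),
            }
        )
        fit = cox_fit(df, ["x1", "x2"], tie_method="efron")
        cph = CoxPHFitter().fit(df, "time", "event")
        for term in fit.terms:
            assert term.beta == pytest.approx(cph.params_[term.name], abs=1e-5)
            assert term.se == pytest.approx(
                cph.standard_errors_[term.name], abs=1e-5
            )

    def test_hazard_ratio_and_ci_consistency(self, rng):
        n = 200
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.2 * np.exp(0.5 * x)))
        df = pd.DataFrame(
            {"x": x, "time": np.minimum(T, 10), "event": (T < 10).astype(int)}
        )
        t = cox_fit(df, ["x"]).terms[0]
        assert t.hazard_ratio == pytest.approx(math.exp(t.beta))
        assert t.ci_low == pytest.approx(math.exp(t.beta - 1.96 * t.se))
        assert t.ci_high == pytest.approx(math.exp(t.beta + 1.96 * t.se))

    def test_null_covariate_hazard_ratio_near_one(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            x = rng.standard_normal(n)
            T = rng.exponential(5.0, n)
            df = pd.DataFrame(
                {"x": x, "time": np.minimum(T, 28), "event": (T < 28).astype(int)}
            )
            hr = cox_fit(df, ["x"]).terms[0].hazard_ratio
            hits += 0.8 < hr < 1.25
        assert hits >= 18

    def test_planted_binary_hazard_ratio_two(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        T = rng.exponential(1 / (0.05 * 2.0**x))
        df = pd.DataFrame(
            {"x": x, "time": np.minimum(T, 28), "event": (T < 28).astype(int)}
        )
        t = cox_fit(df, ["x"]).terms[0]
        assert abs(t.beta - math.log(2.0)) <= 2 * t.se

    def test_separation_raises(self):
        df = pd.DataFrame(
            {
                "x": [0, 0, 0, 1, 1, 1],
                "time": [1, 2, 3, 10, 11, 12],
                "event": [1, 1, 1, 1, 1, 1],
            }
        )
        with pytest.raises(RuntimeError):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "time": [5.0, 6.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, ["x"])

    def test_predicted_risk_monotone_in_linear_predictor(self, rng):
        n = 400
        x = rng.standard_normal(n)
        T = rng.exponential(1 / (0.1 * np.exp(0.8 * x)))
        df = pd.DataFrame(
            {"x": x, "time": np.minimum(T, 28), "event": (T < 28).astype(int)}
        )
        fit = cox_fit(df, ["x"])
        risk = fit.predict_risk(df, 28.0)
        assert ((risk >= 0) & (risk <= 1)).all()
        order = np.argsort(x)
        assert (np.diff(risk[order]) >= 0).all()


class TestCompositeAndRoc:
    def test_zero_delta_weight_preserves_sofa_ranking(self, rng):
        sofa = rng.integers(0, 20, 50).astype(float)
        delta = rng.standard_normal(50)
        comp = composite_score(sofa, delta, 0.053, 0.0)
        assert (np.argsort(comp) == np.argsort(0.053 * sofa)).all()

    def test_published_coefficient_arithmetic(self):
        # beta1=0.053 (SOFA), beta2=0.275 (deviation) from the acid-base axis
        assert composite_score(10.0, 2.0, 0.053, 0.275) == pytest.approx(1.08)

    def test_auc_invariant_under_positive_rescaling(self, rng):
        scores = rng.standard_normal(80)
        events = (rng.random(80) < 0.4).astype(int)
        a1 = roc_analysis(scores, events).auc
        a2 = roc_analysis(3.5 * scores + 11, events).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3 < r.cutoff < 10
        assert r.ppv == 1.0 and r.npv == 1.0

    def test_all_tied_scores(self):
        r = roc_analysis([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_pair_counting_examples(self):
        assert roc_analysis([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_analysis([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_exhaustive_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 60).astype(float)  # heavy ties
        events = (rng.random(60) < 0.5).astype(int)
        if events.min() == events.max():
            events[0] = 1 - events[0]
        r = roc_analysis(scores, events)
        assert r.auc == pytest.approx(auc_pair_counting(scores, events), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_trapezoidal_roc_integration(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        scores = np.round(rng.standard_normal(80), 1)
        events = (rng.random(80) < 0.4).astype(int)
        if events.min() == events.max():
            events[0] = 1 - events[0]
        assert roc_analysis(scores, events).auc == pytest.approx(
            roc_auc_score(events, scores), abs=1e-12
        )

    def test_ppv_npv_consistent_with_prevalence(self, rng):
        scores = rng.standard_normal(200)
        events = (rng.random(200) < 0.3).astype(int)
        r = roc_analysis(scores, events)
        n1, n0 = events.sum(), (1 - events).sum()
        tp = r.sensitivity * n1
        fp = (1 - r.specificity) * n0
        assert r.ppv == pytest.approx(tp / (tp + fp))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=4, max_size=25),
        st.data(),
    )
    def test_auc_matches_pair_counting_property(self, raw_scores, data):
        """Rank-statistic AUC equals exhaustive pair counting on arbitrary
        tied integer scores."""
        n = len(raw_scores)
        events = np.array(
            data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        )
        if events.min() == events.max():
            events[0] = 1 - events[0]
        scores = np.array(raw_scores, dtype=float)
        assert roc_analysis(scores, events).auc == pytest.approx(
            auc_pair_counting(scores, events), abs=1e-12
        )


class TestBrier:
    def test_perfect_predictions(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half(self):
        assert brier_score([0.5] * 10, [0, 1] * 5) == 0.25

    def test_hand_arithmetic(self):
        assert brier_score([0.9, 0.1], [1, 0]) == pytest.approx(0.01)

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(ValueError):
            brier_score([1.2], [1])


class TestIdiNri:
    def test_no_change_gives_zero(self, rng):
        risk = rng.random(40)
        events = (rng.random(40) < 0.5).astype(int)
        s = idi_nri(risk, risk, events)
        assert s.idi == 0.0 and s.nri == 0.0

    def test_hand_computation(self):
        old = np.r_[np.full(10, 0.2), np.full(10, 0.2)]
        new = np.r_[np.full(10, 0.4), np.full(10, 0.1)]
        events = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = idi_nri(old, new, events)
        assert s.idi == pytest.approx(0.3, abs=1e-12)
        assert s.nri == pytest.approx(2.0, abs=1e-12)

    def test_idi_antisymmetric(self, rng):
        old = rng.random(60)
        new = rng.random(60)
        events = (rng.random(60) < 0.4).astype(int)
        assert idi_nri(old, new, events).idi == pytest.approx(
            -idi_nri(new, old, events).idi, abs=1e-12
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            idi_nri([0.1, 0.2], [0.2, 0.3], [1, 1])


class TestKmLogrank:
    def test_identical_groups_chi2_near_zero(self):
        t = np.r_[np.arange(1.0, 21.0), np.arange(1.0, 21.0)]
        e = np.ones(40, int)
        g = np.r_[np.zeros(20, int), np.ones(20, int)]
        _, chi2, p = km_logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p > 0.99

    def test_three_fold_hazard_separation_detected(self, rng):
        n = 50
        t1 = rng.exponential(1 / 0.3, n)
        t2 = rng.exponential(1 / 0.1, n)
        t = np.r_[t1, t2]
        e = np.ones(2 * n, int)
        g = np.r_[np.zeros(n, int), np.ones(n, int)]
        _, chi2, p = km_logrank(t, e, g)
        assert p < 0.01

    def test_km_curve_properties(self, rng):
        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = (rng.random(60) < 0.5).astype(int)
        curves, _, _ = km_logrank(t, e, g)
        for df in curves.values():
            s = df["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 0], [0, 0, 0])


class TestFullAnalysis:
    def test_report_deterministic(self, small_cohort):
        cfg, cohort = small_cohort
        variables = ("ph", "bicarbonate", "chloride", "lactate", "glucose", "gcs")
        r1 = run_full_analysis(cohort, variables)
        r2 = run_full_analysis(cohort, variables)
        assert json.dumps(r1.to_json_dict(), sort_keys=True, default=float) == json.dumps(
            r2.to_json_dict(), sort_keys=True, default=float
        )

    def test_planted_cohort_end_to_end(self, small_cohort):
        cfg, cohort = small_cohort
        variables = ("ph", "bicarbonate", "chloride", "lactate", "glucose", "spo2", "resp_rate")
        rep = run_full_analysis(cohort, variables)
        assert rep.metadata["n_events"] == cfg.n_nonsurvivors
        sofa_auc = rep.roc.set_index("index").loc["SOFA", "auc"]
        comp = rep.roc[rep.roc["index"] != "SOFA"]
        assert (comp["auc"] > sofa_auc).mean() > 0.5

    def test_null_pipeline_fwer_controlled(self):
        """With Bonferroni correction, a null cohort should essentially
        never flag an axis as predictive."""
        from alfnet import null_config, generate_cohort
        from alfnet.parenclitic import deviation_matrix, fit_reference_models

        flagged_reps = 0
        n_reps = 10
        variables = ["ph", "bicarbonate", "chloride", "lactate", "glucose", "gcs"]
        for seed in range(n_reps):
            cfg = null_config(seed=300 + seed, n_survivors=200, n_nonsurvivors=120)
            cohort = generate_cohort(cfg)
            models = fit_reference_models(cohort[cohort.event == 0], variables)
            dm = deviation_matrix(models, cohort).reset_index(drop=True)
            if dm.shape[1] == 0:
                continue
            pvals = []
            for col in dm.columns:
                work = cohort.copy()
                work["_z"] = z_transform(dm[col].to_numpy())
                pvals.append(cox_fit(work, ["_z"]).terms[0].p)
            if min(pvals) < 0.05 / len(pvals):
                flagged_reps += 1
        assert flagged_reps <= 2
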