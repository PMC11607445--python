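"""Option enumeration, AKI and contraindication rules, optimal selection."""

import numpy as np
import pandas as pd
import pytest

from optab.preprocess import preprocess_cohort
from optab.selector import (
    ContraindicationRuleSet,
    ModelBundle,
    check_contraindications,
    detect_aki_stage1,
    enumerate_options,
    forecast_under_option,
    plan_iterations,
    select_optimal,
)
from optab.synthetic import ANTIBIOTICS, SimConfig, simulate_cohort
from optab.tecde import ModelConfig, TECDEModel

RULES = ContraindicationRuleSet()


class TestEnumeration:
    def test_three_antibiotics_give_six_options(self):
        opts = enumerate_options(ANTIBIOTICS)
        assert len(opts) == 6
        assert sum(len(o) == 1 for o in opts) == 3
        assert sum(len(o) == 2 for o in opts) == 3

    def test_resistance_excludes_antibiotic(self):
        opts = enumerate_options(ANTIBIOTICS, resistant=["Vancomycin"])
        assert len(opts) == 3
        assert all("Vancomycin" not in o for o in opts)

    def test_single_antibiotic_gives_its_singleton(self):
        assert enumerate_options(["Ceftriaxone"]) == [("Ceftriaxone",)]

    def test_all_resistant_raises_referral(self):
        with pytest.raises(ValueError, match="physician"):
            enumerate_options(ANTIBIOTICS, resistant=list(ANTIBIOTICS))

    def test_order_is_deterministic(self):
        assert enumerate_options(ANTIBIOTICS) == enumerate_options(reversed(ANTIBIOTICS))


def brute_force_aki(creat_t, creat_v, rules=RULES):
    """Exhaustive scan over all (evaluation time, lookback sample) pairs."""
    for j in range(len(creat_t)):
        for i in range(len(creat_t)):
            if 0 <= creat_t[j] - creat_t[i] <= rules.aki_delta_window:
                if creat_v[j] - creat_v[i] >= rules.aki_creatinine_delta:
                    return True
            if 0 <= creat_t[j] - creat_t[i] <= rules.aki_baseline_window:
                pass
        window = [v for t, v in zip(creat_t, creat_v)
                  if 0 <= creat_t[j] - t <= rules.aki_baseline_window]
        if window and min(window) > 0 and creat_v[j] >= rules.aki_baseline_ratio * min(window):
            return True
    return False


class TestAki:
    def test_delta_criterion(self):
        flag, reasons = detect_aki_stage1(([0.0, 24.0], [1.0, 1.3]))
        assert flag and "creatinine_delta" in reasons

    def test_ratio_criterion_over_five_days(self):
        flag, reasons = detect_aki_stage1(([0.0, 60.0, 120.0], [1.0, 1.1, 1.5]))
        assert flag and "creatinine_ratio" in reasons

    def test_urine_criterion_sustained_8h(self):
        flag, reasons = detect_aki_stage1(
            ([0.0], [1.0]), urine_rate=(np.arange(0.0, 9.0), np.full(9, 0.4)))
        assert flag and "urine_output" in reasons

    def test_flat_series_not_flagged(self):
        flag, reasons = detect_aki_stage1(
            ([0.0, 48.0, 96.0], [1.0, 1.0, 1.0]),
            urine_rate=([0.0, 6.0, 12.0], [1.0, 1.0, 1.0]))
        assert not flag and reasons == []

    def test_short_low_urine_span_not_flagged(self):
        flag, _ = detect_aki_stage1(
            ([0.0], [1.0]), urine_rate=([0.0, 2.0, 4.0], [0.4, 0.4, 1.0]))
        assert not flag

    def test_long_low_urine_span_still_flags(self):
        # spans longer than 12 h also trigger stage >= 1
        flag, _ = detect_aki_stage1(
            ([0.0], [1.0]), urine_rate=(np.arange(0.0, 20.0), np.full(20, 0.3)))
        assert flag

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            detect_aki_stage1(([0.0], [-1.0]))

    def test_random_series_match_exhaustive_scan(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            n = rng.integers(1, 12)
            t = np.sort(rng.uniform(0, 200, n))
            v = rng.uniform(0.5, 2.2, n)
            flag, _ = detect_aki_stage1((t, v))
            assert flag == brute_force_aki(t, v)


class TestContraindications:
    def test_male_bilirubin_over_24_warns_ceftriaxone(self):
        w = check_contraindications(
            ("Ceftriaxone",), {"bilirubin_total": 2.5, "alt": 100, "creatinine": 1.0},
            "male", False)
        assert any("bilirubin" in x for x in w)

    def test_female_threshold_is_22(self):
        labs = {"bilirubin_total": 2.3, "alt": 100, "creatinine": 1.0}
        assert check_contraindications(("Ceftriaxone",), labs, "female", False)
        assert not check_contraindications(("Ceftriaxone",), labs, "male", False)

    def test_piperacillin_alone_never_warned(self):
        w = check_contraindications(
            ("Piperacillin/Tazobactam",),
            {"bilirubin_total": 9.9, "alt": 999, "creatinine": 9.9}, "male", True)
        assert w == []

    def test_creatinine_over_two_warns_all_vancomycin_options(self):
        labs = {"creatinine": 2.1, "alt": 0.0, "bilirubin_total": 0.0}
        for opt in [("Vancomycin",), ("Ceftriaxone", "Vancomycin"),
                    ("Piperacillin/Tazobactam", "Vancomycin")]:
            assert any("creatinine" in x for x in
                       check_contraindications(opt, labs, "male", False))

    def test_aki_flag_warns_vancomycin(self):
        w = check_contraindications(
            ("Vancomycin",), {"creatinine": 1.0, "alt": 0, "bilirubin_total": 0},
            "female", True)
        assert any("kidney" in x.lower() for x in w)

    def test_alt_280_boundary(self):
        labs = {"alt": 280.0, "bilirubin_total": 0.0, "creatinine": 1.0}
        assert not check_contraindications(("Ceftriaxone",), labs, "male", False)
        labs["alt"] = 280.1
        assert check_contraindications(("Ceftriaxone",), labs, "male", False)

    def test_unknown_sex_code_rejected(self):
        with pytest.raises(ValueError):
            check_contraindications(("Vancomycin",), {}, "unknown", False)

    def test_rules_must_be_positive(self):
        with pytest.raises(ValueError):
            ContraindicationRuleSet(vanc_creatinine_max=0.0)


@pytest.fixture(scope="module")
def tiny_bundle():
    """A small untrained-but-functional model over a simulated cohort."""
    cohort, truth = simulate_cohort(SimConfig(n_patients=12, horizon=96.0, seed=61))
    res = preprocess_cohort(cohort)
    model = TECDEModel(
        len(res.variables), 3, res.grids[0].d.size, res.grids[0].outcome_idx.size,
        ModelConfig(latent_dim=4, hidden=(8, 8)), seed=61)
    bundle = ModelBundle(model, res.variables, res.grids[0].antibiotics,
                         res.stats, res.static_stats)
    return bundle, cohort, res.grids


class TestForecastUnderOption:
    def test_deterministic(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        a = forecast_under_option(bundle, grids[0], ("Vancomycin",), 24, 48.0)
        b = forecast_under_option(bundle, grids[0], ("Vancomycin",), 24, 48.0)
        pd.testing.assert_frame_equal(a, b)

    def test_cached_prefix_equals_full_encode(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        from optab.preprocess import build_rectilinear_path
        cache = {"path": build_rectilinear_path(grids[1])}
        first = forecast_under_option(bundle, grids[1], ("Ceftriaxone",), 24, 48.0,
                                      _cache=cache)
        second = forecast_under_option(bundle, grids[1], ("Vancomycin",), 24, 48.0,
                                       _cache=cache)
        fresh = forecast_under_option(bundle, grids[1], ("Vancomycin",), 24, 48.0)
        pd.testing.assert_frame_equal(second, fresh)

    def test_output_in_physical_units(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        fc = forecast_under_option(bundle, grids[0], ("Vancomycin",), 0, 48.0)
        assert list(fc.columns) == bundle.outcome_variables
        assert fc.index[0] == 1.0 and fc.index[-1] == 48.0

    def test_zeroed_treatment_channels_make_options_identical(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        model = bundle.model
        # zero the treatment columns of the CDE field input and g_eta weights
        V = model.V
        w0 = model.F_theta.weights  # treatment effect flows via bmv contraction
        # instead: zero the columns of g_eta's first layer that read a0, and
        # verify that with treatment-insensitive dynamics the forecasts tie
        g0 = model.g_eta.weights[0]
        saved = g0.data.copy()
        g0.data[V : V + model.M, :] = 0.0
        # also make the field blind to the treatment channels
        # (the contraction weights are the last M control columns per latent)
        fw = model.F_theta.weights[-1]
        saved_f = fw.data.copy()
        mask = np.ones(model.C, dtype=bool)
        mask[1 + 2 * V :] = False
        fw.data = fw.data.reshape(-1, model.P, model.C) * mask
        fw.data = fw.data.reshape(saved_f.shape)
        try:
            a = forecast_under_option(bundle, grids[2], ("Vancomycin",), 0, 24.0)
            b = forecast_under_option(bundle, grids[2], ("Ceftriaxone",), 0, 24.0)
            np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)
        finally:
            g0.data = saved
            fw.data = saved_f


class TestSelectOptimal:
    def test_selected_equals_brute_force_minimum(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        for i in (0, 3, 5):
            dec = select_optimal(bundle, cohort[i], grids[i], 0, 48.0,
                                 mode="unconstrained")
            scores = {o: dec.sofa_at_horizon[o] for o in dec.candidates}
            best = sorted(scores, key=lambda o: (scores[o], len(o), o))[0]
            assert dec.selected == best

    def test_constrained_skips_warned_best(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        # absurdly low creatinine threshold: every Vancomycin option is warned
        rules = ContraindicationRuleSet(vanc_creatinine_max=1e-6)
        dec = select_optimal(bundle, cohort[0], grids[0], 0, 48.0, rules=rules,
                             mode="constrained")
        assert "Vancomycin" not in dec.selected
        warned = [o for o in dec.candidates if "Vancomycin" in o]
        assert all(dec.warnings[o] for o in warned)

    def test_all_warned_falls_back_with_notification(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        rules = ContraindicationRuleSet(
            vanc_creatinine_max=1e-6, ceft_alt_max=1e-6,
            ceft_bili_max_male=1e-6, ceft_bili_max_female=1e-6)
        # restrict candidates to warned antibiotics only
        cands = [("Ceftriaxone",), ("Vancomycin",), ("Ceftriaxone", "Vancomycin")]
        dec = select_optimal(bundle, cohort[0], grids[0], 0, 48.0, rules=rules,
                             mode="constrained", candidates=cands)
        assert dec.selected in cands
        assert dec.notifications  # fallback is announced

    def test_unconstrained_ignores_warnings(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        rules = ContraindicationRuleSet(
            vanc_creatinine_max=1e-6, ceft_alt_max=1e-6,
            ceft_bili_max_male=1e-6, ceft_bili_max_female=1e-6)
        unc = select_optimal(bundle, cohort[0], grids[0], 0, 48.0, rules=rules,
                             mode="unconstrained")
        scores = unc.sofa_at_horizon
        best = sorted(unc.candidates, key=lambda o: (scores[o], len(o), o))[0]
        assert unc.selected == best


class TestPlanIterations:
    def test_96h_record_decides_at_0_48_72_96(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        plan = plan_iterations(bundle, cohort[0], grids[0])
        times = [d.time for d in plan.decisions]
        assert times == [0.0, 48.0, 72.0, 96.0]
        assert plan.decisions[0].horizon == 48.0
        assert plan.decisions[1].horizon == 24.0

    def test_decreasing_sofa_emits_deescalation(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        p = cohort[0]
        obs = p.observations[p.observations["variable"] != "sofa"]
        fake = pd.DataFrame({
            "time_h": [0.0, 12.0, 24.0, 36.0, 48.0],
            "variable": "sofa",
            "value": [10.0, 8.0, 7.0, 5.0, 4.0],
        })
        from dataclasses import replace
        p2 = replace(p, observations=pd.concat([obs, fake], ignore_index=True))
        plan = plan_iterations(bundle, p2, grids[0])
        dec48 = [d for d in plan.decisions if d.time == 48.0][0]
        assert any("de-escalation" in n for n in dec48.notifications)

    def test_fungal_culture_notifies_without_changing_schedule(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        from dataclasses import replace
        p = cohort[1]
        micro = pd.DataFrame([{
            "sample_time_h": 0.0, "result_time_h": 30.0,
            "organism_class": "fungal", "resistant_to": ""}])
        p2 = replace(p, micro=micro)
        plan = plan_iterations(bundle, p2, grids[1])
        assert [d.time for d in plan.decisions] == [0.0, 48.0, 72.0, 96.0]
        assert any(k == "pathogen" and t == 30.0 for t, k, _ in plan.notifications)

    def test_resistance_result_triggers_middecision(self, tiny_bundle):
        bundle, cohort, grids = tiny_bundle
        from dataclasses import replace
        p = cohort[2]
        micro = pd.DataFrame([{
            "sample_time_h": 0.0, "result_time_h": 30.0,
            "organism_class": "gram_pos", "resistant_to": "Vancomycin"}])
        p2 = replace(p, micro=micro)
        plan = plan_iterations(bundle, p2, grids[2])
        times = [d.time for d in plan.decisions]
        assert 30.0 in times
        after = [d for d in plan.decisions if d.time >= 30.0]
        assert all("Vancomycin" not in o for d in after for o in d.candidates)
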