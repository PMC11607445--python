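"""Variable selection, normalization, gridding and control-path causality."""

import numpy as np
import pandas as pd
import pytest

from optab.preprocess import (
    GridRecord,
    PreprocessConfig,
    build_rectilinear_path,
    cumulative_masks,
    filter_by_coverage,
    fit_apply_normalization,
    knn_impute_initial,
    preprocess_cohort,
    round_to_hours,
    select_by_spearman,
)
from optab.records import PatientRecord
from optab.synthetic import SimConfig, simulate_cohort


def make_patient(pid, rows, treatments=None, statics=None):
    obs = pd.DataFrame(rows, columns=["time_h", "variable", "value"])
    tre = pd.DataFrame(treatments or [], columns=["start_h", "end_h", "antibiotic"])
    return PatientRecord(
        patient_id=pid,
        observations=obs,
        treatments=tre,
        micro=pd.DataFrame(columns=["sample_time_h", "result_time_h",
                                    "organism_class", "resistant_to"]),
        statics=statics or {"sex": 1.0, "age": 60.0, "height": 170.0, "weight": 75.0},
    )


class TestCoverage:
    def _cohort(self, frac, n=100):
        cohort = []
        k = int(round(frac * n))
        for i in range(n):
            rows = [(0.0, "always", 1.0)]
            if i < k:
                rows.append((1.0, "partial", 2.0))
            cohort.append(make_patient(i, rows))
        return cohort

    def test_49_percent_excluded(self):
        kept = filter_by_coverage(self._cohort(0.49), 0.5)
        assert "partial" not in kept and "always" in kept

    def test_exactly_50_percent_kept(self):
        kept = filter_by_coverage(self._cohort(0.50), 0.5)
        assert "partial" in kept

    def test_fully_observed_kept(self):
        assert "always" in filter_by_coverage(self._cohort(1.0), 0.5)


class TestSpearman:
    def _cohort_with(self, transform, n=60, seed=0):
        rng = np.random.default_rng(seed)
        cohort = []
        for i in range(n):
            sofa = rng.uniform(2, 20)
            rows = [(5.0, "sofa", sofa), (6.0, "derived", transform(sofa)),
                    (7.0, "noise", rng.normal())]
            cohort.append(make_patient(i, rows))
        return cohort

    def test_identity_and_monotone_transform_selected(self):
        for f in (lambda s: s, lambda s: np.exp(0.3 * s)):
            keep, _ = select_by_spearman(self._cohort_with(f))
            assert "derived" in keep

    def test_independent_noise_excluded(self):
        keep, report = select_by_spearman(self._cohort_with(lambda s: s, n=500))
        assert "noise" not in keep
        assert report[report["variable"] == "noise"]["spearman"].abs().max() < 0.3

    def test_raw_mode_also_selects_monotone(self):
        keep, _ = select_by_spearman(self._cohort_with(lambda s: -(s**2)), mode="raw")
        assert "derived" in keep

    def test_outcome_labs_always_retained(self):
        cohort = self._cohort_with(lambda s: s)
        for p in cohort:
            p.observations.loc[len(p.observations)] = (8.0, "creatinine", 1.0)
        keep, _ = select_by_spearman(cohort)
        assert "creatinine" in keep


class TestNormalization:
    def test_hand_computed_three_patient_cohort(self):
        cohort = [
            make_patient(0, [(0.0, "x", 1.0), (1.0, "x", 2.0)]),
            make_patient(1, [(0.0, "x", 3.0)]),
            make_patient(2, [(0.0, "x", 6.0)]),
        ]
        normalized, stats = fit_apply_normalization(cohort)
        mean, sd = stats["x"]
        vals = np.array([1.0, 2.0, 3.0, 6.0])
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=0))
        pooled = np.concatenate([p.observations["value"].to_numpy() for p in normalized])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-12)
        assert pooled.std(ddof=0) == pytest.approx(1.0)

    def test_refitting_standardized_data_is_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=50)
        vals = (vals - vals.mean()) / vals.std(ddof=0)
        cohort = [make_patient(i, [(0.0, "x", v)]) for i, v in enumerate(vals)]
        normalized, _ = fit_apply_normalization(cohort)
        out = np.array([p.observations["value"].iloc[0] for p in normalized])
        np.testing.assert_allclose(out, vals, atol=1e-12)

    def test_fitted_stats_reapplied_unchanged(self):
        train = [make_patient(i, [(0.0, "x", float(i))]) for i in range(10)]
        other = [make_patient(99, [(0.0, "x", 100.0)])]
        _, stats = fit_apply_normalization(train)
        out, stats2 = fit_apply_normalization(other, stats=stats)
        assert stats2 == stats
        mean, sd = stats["x"]
        assert out[0].observations["value"].iloc[0] == pytest.approx((100.0 - mean) / sd)

    def test_zero_variance_variable_raises_with_name(self):
        cohort = [make_patient(i, [(0.0, "flat", 7.0)]) for i in range(5)]
        with pytest.raises(ValueError, match="flat"):
            fit_apply_normalization(cohort)


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(knn_impute_initial(X.copy(), k=2), X)

    def test_k1_exact_duplicate_donor(self):
        X = np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 9.0], [50.0, 60.0, 70.0]])
        out = knn_impute_initial(X, k=1)
        assert out[0, 2] == pytest.approx(9.0)

    def test_k_equals_all_donors_gives_donor_mean(self):
        X = np.array([[np.nan, 5.0], [1.0, 5.0], [3.0, 5.0], [5.0, 5.0]])
        out = knn_impute_initial(X, k=3)
        assert out[0, 0] == pytest.approx(3.0)

    def test_all_missing_vector_rejected(self):
        X = np.array([[np.nan, np.nan], [1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            knn_impute_initial(X, k=1)


class TestRoundToHours:
    def test_nearest_hour(self):
        p = make_patient(0, [(3.4, "x", 1.0)])
        out = round_to_hours(p)
        assert out.observations["time_h"].iloc[0] == 3.0

    def test_collision_keeps_latest_raw_observation(self):
        p = make_patient(0, [(5.2, "creatinine", 1.1), (5.4, "creatinine", 1.7)])
        out = round_to_hours(p)
        assert len(out.observations) == 1
        assert out.observations["value"].iloc[0] == 1.7

    def test_collision_mean_mode(self):
        p = make_patient(0, [(5.2, "creatinine", 1.0), (5.4, "creatinine", 2.0)])
        out = round_to_hours(p, collision="mean")
        assert out.observations["value"].iloc[0] == pytest.approx(1.5)

    def test_integer_times_unchanged(self):
        p = make_patient(0, [(3.0, "x", 1.0), (7.0, "x", 2.0)])
        out = round_to_hours(p)
        np.testing.assert_array_equal(out.observations["time_h"], [3.0, 7.0])


class TestMasks:
    def test_never_observed_all_zero(self):
        Z = np.full((1, 5), np.nan)
        np.testing.assert_array_equal(cumulative_masks(Z), np.zeros((1, 5)))

    def test_every_hour_counts_up(self):
        Z = np.ones((1, 4))
        np.testing.assert_array_equal(cumulative_masks(Z)[0], [1, 2, 3, 4])

    def test_arbitrary_pattern_matches_prefix_sums(self):
        rng = np.random.default_rng(2)
        Z = np.where(rng.random((3, 20)) < 0.4, 1.0, np.nan)
        expect = np.cumsum(~np.isnan(Z), axis=1)
        np.testing.assert_array_equal(cumulative_masks(Z), expect)
        assert np.all(np.diff(cumulative_masks(Z), axis=1) >= 0)


def tiny_grid(K=5, seed=0):
    rng = np.random.default_rng(seed)
    V = 2
    Z = np.where(rng.random((V, K + 1)) < 0.6, rng.normal(size=(V, K + 1)), np.nan)
    gr = GridRecord(
        patient_id=0,
        times=np.arange(K + 1, dtype=float),
        variables=["sofa", "creatinine"],
        Z=Z,
        masks=cumulative_masks(Z),
        A=rng.integers(0, 2, (3, K + 1)).astype(float),
        antibiotics=["Ceftriaxone", "Piperacillin/Tazobactam", "Vancomycin"],
        d=np.zeros(2),
        outcome_idx=np.array([0, 1]),
        z0=rng.normal(size=V),
    )
    return gr


class TestControlPath:
    def test_requires_imputed_initial_values(self):
        gr = tiny_grid()
        gr.z0 = None
        with pytest.raises(ValueError):
            build_rectilinear_path(gr)

    def test_knot_evaluation_reproduces_observations(self):
        gr = tiny_grid(seed=3)
        path = build_rectilinear_path(gr, time_scale=1.0, mask_scale=1.0)
        # at each value-update knot, observed channels equal the observation
        for j in range(1, gr.times.size):
            knot = path.knots[2 * j]
            assert knot[0] == gr.times[j]
            for vi in range(2):
                if not np.isnan(gr.Z[vi, j]):
                    assert knot[1 + vi] == gr.Z[vi, j]

    def test_time_then_value_ordering(self):
        gr = tiny_grid(seed=4)
        path = build_rectilinear_path(gr)
        for seg in range(path.n_segments):
            d = path.derivative(seg)
            if seg % 2 == 0:  # time advance
                assert d[0] != 0.0 and np.all(d[1:] == 0.0)
            else:             # value update at frozen time
                assert d[0] == 0.0

    def test_causality_appending_future_data_preserves_prefix(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            gr_full = tiny_grid(K=10, seed=trial)
            # truncated copy: same record up to hour 6
            gr_cut = GridRecord(
                patient_id=0,
                times=gr_full.times[:7],
                variables=gr_full.variables,
                Z=gr_full.Z[:, :7],
                masks=gr_full.masks[:, :7],
                A=gr_full.A[:, :7],
                antibiotics=gr_full.antibiotics,
                d=gr_full.d,
                outcome_idx=gr_full.outcome_idx,
                z0=gr_full.z0,
            )
            p_full = build_rectilinear_path(gr_full)
            p_cut = build_rectilinear_path(gr_cut)
            np.testing.assert_array_equal(p_full.knots[: p_cut.knots.shape[0]], p_cut.knots)

    def test_derivative_integrates_to_knot_difference(self):
        gr = tiny_grid(seed=6)
        path = build_rectilinear_path(gr)
        for seg in range(path.n_segments):
            lo = path.evaluate(seg)
            hi = path.evaluate(seg + 1)
            np.testing.assert_allclose(hi - lo, path.derivative(seg), atol=1e-12)


class TestPipeline:
    def test_deterministic_and_splits_share_statistics(self):
        cohort, _ = simulate_cohort(SimConfig(n_patients=25, seed=8))
        res1 = preprocess_cohort(cohort[:20])
        res2 = preprocess_cohort(cohort[:20])
        assert res1.variables == res2.variables
        assert res1.stats == res2.stats
        held = preprocess_cohort(cohort[20:], fitted=res1)
        assert held.variables == res1.variables
        assert held.stats == res1.stats
        # held-out grids live on the training grid length
        assert held.grids[0].times.size == res1.grids[0].times.size

    def test_grids_have_complete_initial_values(self):
        cohort, _ = simulate_cohort(SimConfig(n_patients=15, seed=9))
        res = preprocess_cohort(cohort)
        for g in res.grids:
            assert not np.isnan(g.z0).any()
            assert set(np.unique(g.A)) <= {0.0, 1.0}
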