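"""LMM engine, thinning maps, Krippendorff's alpha, follow-up stability."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import cortsub as cs
from cortsub.longitudinal import (
    fit_random_intercept_lmm,
    krippendorff_alpha,
)

from conftest import align_labels


def _simulate_lmm(n_subjects=200, n_visits=3, intercept=2.0, slope=0.5,
                  tau=0.3, sigma=0.2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.tile(np.arange(n_visits, dtype=float), n_subjects)
    subj = np.repeat(np.arange(n_subjects), n_visits)
    u = rng.normal(0, tau, n_subjects)
    y = intercept + slope * t + u[subj] + rng.normal(0, sigma, len(t))
    X = np.column_stack([np.ones_like(t), t])
    return y, X, subj


class TestRandomInterceptLMM:
    def test_parameter_recovery(self):
        y, X, subj = _simulate_lmm(seed=1)
        fit = fit_random_intercept_lmm(y, X, subj, ["intercept", "time"])
        assert abs(fit.params[1] - 0.5) < 3 * fit.se[1]
        assert abs(fit.params[0] - 2.0) < 3 * fit.se[0]
        # variance components in the right ballpark
        assert 0.2**2 * 0.5 < fit.sigma2 < 0.2**2 * 2.0
        assert 0.3**2 * 0.5 < fit.tau2 < 0.3**2 * 2.0

    def test_balanced_design_gls_equals_ols(self):
        # with identical within-subject designs, GLS fixed effects = OLS
        y, X, subj = _simulate_lmm(n_subjects=50, seed=2)
        fit = fit_random_intercept_lmm(y, X, subj)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, ols, atol=1e-8)

    def test_matches_statsmodels_mixedlm(self):
        # unbalanced design so GLS genuinely differs from OLS
        rng = np.random.default_rng(3)
        rows = []
        for s in range(80):
            for t in sorted(rng.choice([0.0, 1.0, 2.0, 3.0],
                                       size=rng.integers(2, 5), replace=False)):
                rows.append((s, t))
        subj = np.array([r[0] for r in rows])
        t = np.array([r[1] for r in rows])
        u = rng.normal(0, 0.4, 80)
        y = 1.0 - 0.3 * t + u[subj] + rng.normal(0, 0.25, len(t))
        X = np.column_stack([np.ones_like(t), t])
        ours = fit_random_intercept_lmm(y, X, subj, ["intercept", "time"])
        sm_fit = sm.MixedLM(y, X, groups=subj).fit(reml=True)
        np.testing.assert_allclose(ours.params, sm_fit.fe_params, atol=1e-5)
        np.testing.assert_allclose(ours.se, sm_fit.bse_fe, rtol=1e-3)
        np.testing.assert_allclose(ours.sigma2, sm_fit.scale, rtol=1e-3)

    def test_time_unit_equivariance(self):
        # time recorded in days instead of years: slope scales by 365.25
        y, X, subj = _simulate_lmm(n_subjects=60, seed=4)
        Xd = X.copy()
        Xd[:, 1] *= 365.25
        f_years = fit_random_intercept_lmm(y, X, subj)
        f_days = fit_random_intercept_lmm(y, Xd, subj)
        assert f_days.params[1] * 365.25 == pytest.approx(f_years.params[1],
                                                          rel=1e-8)
        # SEs agree up to the variance-ratio optimizer tolerance
        assert f_days.se[1] * 365.25 == pytest.approx(f_years.se[1], rel=1e-6)
        np.testing.assert_allclose(f_days.pvalues, f_years.pvalues, atol=1e-8)

    def test_rank_deficiency_names_aliased_column(self):
        y, X, subj = _simulate_lmm(n_subjects=20, seed=5)
        X2 = np.column_stack([X, 2.0 * X[:, 1]])
        with pytest.raises(cs.InvalidInputError, match="time_copy"):
            fit_random_intercept_lmm(y, X2, subj,
                                     ["intercept", "time", "time_copy"])

    def test_no_repeats_falls_back_to_ols(self, caplog):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = X @ [1.0, 2.0] + rng.normal(0, 0.1, 50)
        subj = np.arange(50)  # singletons only
        fit = fit_random_intercept_lmm(y, X, subj)
        assert fit.theta == 0.0 and fit.tau2 == 0.0
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, ols, atol=1e-10)

    def test_contrast_recovers_single_coefficients(self):
        y, X, subj = _simulate_lmm(n_subjects=40, seed=7)
        fit = fit_random_intercept_lmm(y, X, subj)
        est, se, p = fit.contrast([0.0, 1.0])
        assert est == pytest.approx(fit.params[1])
        assert se == pytest.approx(fit.se[1])
        assert p == pytest.approx(fit.pvalues[1])


class TestThinningBetamaps:
    def test_recovers_planted_slopes(self, cohort, fitted_model):
        table, labels, true_maps = cohort
        maps = cs.thinning_betamaps(table, fitted_model)
        assert [m.subtype_label for m in maps] == [1, 2]
        fitted_labels = align_labels(labels, fitted_model.subject_assignment)
        # match fitted map order to planted order via the relabelling
        flip = not np.array_equal(fitted_labels, fitted_model.subject_assignment)
        est = [maps[1], maps[0]] if flip else [maps[0], maps[1]]
        for true, got in zip(true_maps, est):
            within = np.abs(got.beta - true.beta) <= 3 * got.se
            assert within.mean() >= 0.95
        for m in maps:
            assert (m.se > 0).all()
            assert ((m.p >= 0) & (m.p <= 1)).all()

    def test_baseline_only_table_rejected(self, cohort, fitted_model):
        table, _, _ = cohort
        base_only = cs.RegionalThicknessTable(
            table.baseline(), table.roi_columns
        )
        with pytest.raises(cs.InvalidInputError, match="repeated measures"):
            cs.thinning_betamaps(base_only, fitted_model)


class TestCharacterizeSubtypes:
    def test_planted_covariate_directions(self, cohort, fitted_model):
        table, labels, _ = cohort
        out = cs.characterize_subtypes(table, fitted_model)
        fitted_labels = align_labels(labels, fitted_model.subject_assignment)
        flip = not np.array_equal(fitted_labels, fitted_model.subject_assignment)
        # planted subtype 1 is older, more amyloid, more APOE-e4
        sign = -1.0 if flip else 1.0
        assert sign * np.log(out.loc["age", "or"]) > 0
        assert sign * np.log(out.loc["centiloid", "or"]) > 0
        assert sign * np.log(out.loc["apoe4", "or"]) > 0
        assert set(["coef", "or", "or_low", "or_high", "p"]) <= set(out.columns)
        assert (out["or_low"] <= out["or"]).all()
        assert (out["or"] <= out["or_high"]).all()

    def test_requires_two_subtypes(self, cohort):
        table, _, _ = cohort
        base, ids = table.baseline_matrix()
        X, offsets = cs.invert_thickness(base)
        m3 = cs.fit_nmf(X, 3, n_restarts=3, seed=4, subject_ids=ids,
                        inversion_offsets=offsets)
        with pytest.raises(cs.InvalidArgumentError):
            cs.characterize_subtypes(table, m3)


class TestOutcomeModels:
    def test_centiloid_trajectory_recovery(self, cohort, fitted_model):
        table, labels, _ = cohort
        fit = cs.longitudinal_outcome_model(table, fitted_model, "centiloid")
        fitted_labels = align_labels(labels, fitted_model.subject_assignment)
        flip = not np.array_equal(fitted_labels, fitted_model.subject_assignment)
        # planted centiloid rates: 3.0 (subtype 1) vs 1.5 (subtype 2) CL/yr
        i_time = fit.param_names.index("time")
        i_int = fit.param_names.index("time:subtype2")
        ref_rate, diff = (1.5, 1.5) if flip else (3.0, -1.5)
        assert abs(fit.params[i_time] - ref_rate) < 3 * fit.se[i_time]
        assert abs(fit.params[i_int] - diff) < 3 * fit.se[i_int]

    def test_score_by_time_adds_interaction(self, cohort, fitted_model):
        table, _, _ = cohort
        fit = cs.longitudinal_outcome_model(table, fitted_model, "memory_score",
                                            score_by_time=True)
        assert "time:nmf_probability" in fit.param_names

    def test_unknown_outcome_rejected(self, cohort, fitted_model):
        table, _, _ = cohort
        with pytest.raises(cs.InvalidArgumentError, match="no_such"):
            cs.longitudinal_outcome_model(table, fitted_model, "no_such")


class TestKrippendorffAlpha:
    def test_frozen_oracle_partial_agreement(self):
        # independently enumerated coincidence-matrix computation
        a = np.array([1, 1, 2, 2, 2])
        b = np.array([1, 2, 2, 2, 1])
        assert krippendorff_alpha(a, b) == pytest.approx(0.25, abs=1e-12)

    def test_frozen_oracle_systematic_disagreement(self):
        assert krippendorff_alpha(np.array([1, 2]), np.array([2, 1])) == \
            pytest.approx(-0.5, abs=1e-12)

    def test_perfect_agreement(self):
        a = np.array([1, 2, 1, 2, 2])
        assert krippendorff_alpha(a, a.copy()) == 1.0

    def test_single_code_degenerate_is_one(self):
        assert krippendorff_alpha(np.ones(5, int), np.ones(5, int)) == 1.0

    def test_unit_order_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.integers(1, 4, 30)
        b = rng.integers(1, 4, 30)
        perm = rng.permutation(30)
        assert krippendorff_alpha(a, b) == pytest.approx(
            krippendorff_alpha(a[perm], b[perm]), abs=1e-12)

    def test_label_name_invariance(self):
        a = np.array([1, 1, 2, 2, 2])
        b = np.array([1, 2, 2, 2, 1])
        assert krippendorff_alpha(a * 10, b * 10) == pytest.approx(
            krippendorff_alpha(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(cs.InvalidArgumentError):
            krippendorff_alpha(np.array([1, 2]), np.array([1, 2, 1]))


class TestAssignFollowup:
    def test_baseline_self_assignment(self, cohort, fitted_model):
        table, _, _ = cohort
        base, ids = table.baseline_matrix()
        agree = 0
        for i in range(len(ids)):
            label, _ = cs.assign_followup(base[i], fitted_model)
            agree += label == fitted_model.subject_assignment[i]
        assert agree / len(ids) >= 0.95

    def test_shift_invariance(self, cohort, fitted_model):
        table, _, _ = cohort
        base, _ = table.baseline_matrix()
        l1, r1 = cs.assign_followup(base[0], fitted_model)
        l2, r2 = cs.assign_followup(base[0] - 0.37, fitted_model)
        assert l1 == l2
        np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_wrong_length_rejected(self, fitted_model):
        with pytest.raises(cs.InvalidArgumentError):
            cs.assign_followup(np.ones(3), fitted_model)

    def test_constant_vector_rejected(self, fitted_model):
        v = np.full(fitted_model.H.shape[1], 2.5)
        with pytest.raises(cs.InvalidInputError, match="zero-variance"):
            cs.assign_followup(v, fitted_model, use_inverted=False)


class TestStabilityAnalysis:
    def test_planted_cohort_is_stable(self, cohort, fitted_model):
        table, _, _ = cohort
        res = cs.stability_analysis(table, fitted_model)
        assert res.alpha >= 0.95
        assert res.n_unstable <= 0.05 * len(res.subject_ids)
        np.testing.assert_array_equal(
            res.stable_flag, res.baseline_labels == res.followup_labels)

    def test_forced_switches_lower_alpha(self, cohort, fitted_model):
        table, _, _ = cohort
        clean = cs.stability_analysis(table, fitted_model)
        # corrupt ~30% of last visits: replace ROI values by the baseline
        # of a subject assigned to the other subtype
        df = table.data.copy().reset_index(drop=True)
        base, ids = table.baseline_matrix()
        assign = pd.Series(fitted_model.subject_assignment,
                           index=fitted_model.subject_ids)
        rng = np.random.default_rng(9)
        last = df[df["time_years"] > 0].groupby("subject_id")["time_years"].idxmax()
        victims = rng.choice(last.index.to_numpy(), size=len(last) // 3,
                             replace=False)
        for s in victims:
            other = ids[assign.reindex(ids).to_numpy() != assign[s]]
            donor = other[rng.integers(len(other))]
            donor_row = base[list(ids).index(donor)]
            df.loc[last[s], table.roi_columns] = donor_row
        corrupted = cs.RegionalThicknessTable(df, table.roi_columns)
        res = cs.stability_analysis(corrupted, fitted_model)
        assert res.alpha < clean.alpha
        assert res.n_unstable >= 0.2 * len(res.subject_ids)
        assert res.logistic_table is not None

    def test_no_followups_rejected(self, cohort, fitted_model):
        table, _, _ = cohort
        base_only = cs.RegionalThicknessTable(table.baseline(),
                                              table.roi_columns)
        with pytest.raises(cs.InvalidInputError, match="follow-up"):
            cs.stability_analysis(base_only, fitted_model)
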