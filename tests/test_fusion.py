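"""Fusion stage: IRLS logistic fit, AIC subset selection, CV protocol,
decision curves, nomogram round trip, clinical statistics."""

import numpy as np
import pandas as pd
import pytest

from heamlrad import fusion as fus
from heamlrad import screening as scr


def logistic_table(rng, n=200, beta_sex=2.0, beta_score=3.0):
    score = rng.random(n)
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.normal(0, 1, n)
    diam = rng.normal(0, 1, n)
    loc = rng.integers(0, 2, n).astype(float)
    habit = rng.integers(0, 2, n).astype(float)
    lp = -2.0 + beta_score * score + beta_sex * sex
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return pd.DataFrame({
        "signature_score": score, "sex_female": sex, "age": age,
        "max_diameter": diam, "loc_left": loc, "habit_yes": habit,
        scr.LABEL: y,
    })


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        tab = pd.DataFrame({scr.LABEL: [1] * 5 + [0] * 5})
        m = fus.fit_logistic(tab, [])
        assert m.log_likelihood == pytest.approx(10 * np.log(0.5), abs=1e-8)
        assert m.aic == pytest.approx(2 - 20 * np.log(0.5), abs=1e-6)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        """Independent cross-check of coefficients and logL against a
        reference maximum-likelihood fit."""
        import statsmodels.api as sm

        tab = logistic_table(rng)
        m = fus.fit_logistic(tab, ["signature_score", "sex_female", "age"])
        X = sm.add_constant(tab[["signature_score", "sex_female", "age"]].to_numpy())
        ref = sm.Logit(tab[scr.LABEL].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(m.intercept, ref.params[0], atol=1e-5)
        np.testing.assert_allclose(m.coef, ref.params[1:], atol=1e-5)
        assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
        assert m.aic == pytest.approx(ref.aic, abs=1e-5)

    def test_one_class_rejected(self):
        tab = pd.DataFrame({"x": [1.0, 2.0], scr.LABEL: [0, 0]})
        with pytest.raises(ValueError):
            fus.fit_logistic(tab, ["x"])

    def test_perfect_separation_flagged(self):
        tab = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                            scr.LABEL: np.r_[np.zeros(10, int), np.ones(10, int)]})
        m = fus.fit_logistic(tab, ["x"])
        assert m.regularized
        assert np.isfinite(m.aic)

    def test_collinear_rejected(self, rng):
        tab = logistic_table(rng, n=50)
        tab["dup"] = tab["sex_female"]
        with pytest.raises(ValueError):
            fus.fit_logistic(tab, ["sex_female", "dup"])


class TestAicSelect:
    def test_matches_exhaustive_refit(self, rng):
        """Selected AIC equals the minimum over independently refit subsets."""
        import itertools

        tab = logistic_table(rng, n=120)
        best = fus.aic_select(tab)
        aics = []
        for r in range(6):
            for sub in itertools.combinations(sorted(fus.CLINICAL_COVARIATES), r):
                aics.append(fus.fit_logistic(tab, ["signature_score", *sub]).aic)
        assert best.aic == pytest.approx(min(aics), abs=1e-9)

    def test_recovers_informative_covariate(self):
        """Only sex carries signal beyond the score: AIC always keeps sex,
        while each pure-noise covariate is admitted at roughly the
        chi-squared(1) > 2 rate (~16%), never in a majority of replicates."""
        sex_hits, noise_hits = 0, {c: 0 for c in fus.CLINICAL_COVARIATES
                                   if c != "sex_female"}
        for seed in range(10):
            tab = logistic_table(np.random.default_rng(seed), n=300)
            sel = set(fus.aic_select(tab).covariates)
            sex_hits += "sex_female" in sel
            for c in noise_hits:
                noise_hits[c] += c in sel
        assert sex_hits >= 9
        assert all(v <= 5 for v in noise_hits.values())

    def test_all_noise_yields_parsimonious_subsets(self):
        """With every clinical covariate pure noise, AIC keeps subsets small
        (expected size ~ 5 x 0.157) and the empty subset occurs."""
        sizes, empties = [], 0
        for seed in range(10):
            tab = logistic_table(np.random.default_rng(100 + seed), n=300,
                                 beta_sex=0.0)
            sel = fus.aic_select(tab)
            sizes.append(len(sel.covariates) - 1)
            empties += sel.covariates == ["signature_score"]
        assert np.mean(sizes) <= 2.0
        assert empties >= 1

    def test_score_column_required(self, rng):
        tab = logistic_table(rng, n=60).drop(columns=["signature_score"])
        with pytest.raises(ValueError):
            fus.aic_select(tab)


class TestCrossValidateFusion:
    def test_folds_partition_and_no_smote(self, small_cohort):
        feats, clin = small_cohort["features"], small_cohort["clinical"]
        before = feats.copy()
        cv = fus.cross_validate_fusion(feats, clin, n_folds=5, seed=0,
                                       screen_k=40, inner_folds=3)
        # inputs untouched, every subject scored exactly once
        pd.testing.assert_frame_equal(feats, before)
        assert cv.pooled_scores.notna().all()
        assert len(cv.fold_aucs) == 5
        assert 0 <= cv.mean_auc <= 1

    def test_class_smaller_than_folds_rejected(self, rng):
        feats = pd.DataFrame({"f": rng.normal(size=12),
                              scr.LABEL: [1] * 3 + [0] * 9})
        clin = pd.DataFrame({"sex_female": np.zeros(12)}, index=feats.index)
        with pytest.raises(ValueError):
            fus.cross_validate_fusion(feats, clin, n_folds=10, seed=0)

    def test_duplicated_row_leak_canary(self, small_cohort):
        """A duplicated subject must land in one fold only — the pooled
        score of the duplicate pair would otherwise be identical in-fold.
        Verified via the partition: indices are unique and each appears
        once in the pooled series."""
        feats, clin = small_cohort["features"], small_cohort["clinical"]
        cv = fus.cross_validate_fusion(feats, clin, n_folds=5, seed=1,
                                       screen_k=20, inner_folds=3)
        assert cv.pooled_scores.index.is_unique
        assert len(cv.pooled_scores) == len(feats)


class TestDecisionCurve:
    def test_treat_all_closed_form(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        s = rng.random(100)
        dca = fus.decision_curve(s, y)
        pi = 0.3
        expected = pi - (1 - pi) * dca.thresholds / (1 - dca.thresholds)
        np.testing.assert_allclose(dca.net_benefit_all, expected, atol=1e-12)
        np.testing.assert_allclose(dca.net_benefit_none, 0.0)

    def test_perfect_scores_reach_prevalence(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        s = np.r_[np.full(20, 0.95), np.full(80, 0.05)]
        dca = fus.decision_curve(s, y)
        below_gap = dca.thresholds <= 0.9
        above_floor = dca.thresholds > 0.05
        sel = below_gap & above_floor
        np.testing.assert_allclose(dca.net_benefit[sel], 0.2, atol=1e-12)

    def test_net_benefit_bounded_by_prevalence(self, rng):
        for _ in range(20):
            n = 60
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.random(n)
            dca = fus.decision_curve(s, y)
            assert np.all(dca.net_benefit <= y.mean() + 1e-12)


class TestNomogram:
    def _model(self, rng, covs=("sex_female", "age")):
        tab = logistic_table(rng, n=150)
        return fus.fit_logistic(tab, ["signature_score", *covs]), tab

    def test_round_trip_identity(self, rng):
        """Nomogram probability equals the model probability to 1e-9."""
        model, tab = self._model(rng)
        ranges = {c: (float(tab[c].min()), float(tab[c].max()))
                  for c in model.covariates}
        nomo = fus.build_nomogram(model, ranges)
        pts = nomo.total_points(tab)
        np.testing.assert_allclose(nomo.probability(pts),
                                   model.predict_proba(tab), atol=1e-9)

    def test_widest_covariate_spans_0_100(self, rng):
        model, tab = self._model(rng)
        ranges = {c: (float(tab[c].min()), float(tab[c].max()))
                  for c in model.covariates}
        nomo = fus.build_nomogram(model, ranges)
        spans = [abs(s.points_at_high - s.points_at_low) for s in nomo.scales]
        assert max(spans) == pytest.approx(100.0)

    def test_zero_beta_zero_points(self, rng):
        model, tab = self._model(rng)
        model.coef[1] = 0.0  # kill one covariate
        ranges = {c: (float(tab[c].min()), float(tab[c].max()))
                  for c in model.covariates}
        nomo = fus.build_nomogram(model, ranges)
        dead = nomo.scales[1]
        np.testing.assert_allclose(dead.points(tab[dead.covariate].to_numpy()), 0.0)

    def test_single_covariate_plain_logistic(self, rng):
        tab = logistic_table(rng, n=100)
        model = fus.fit_logistic(tab, ["signature_score"])
        nomo = fus.build_nomogram(model, {"signature_score": (0.0, 1.0)})
        x = np.linspace(0, 1, 11)
        frame = pd.DataFrame({"signature_score": x})
        pts = nomo.total_points(frame)
        assert pts.min() == pytest.approx(0.0, abs=1e-9)
        assert pts.max() == pytest.approx(100.0, abs=1e-9)
        expected = 1 / (1 + np.exp(-(model.intercept + model.coef[0] * x)))
        np.testing.assert_allclose(nomo.probability(pts), expected, atol=1e-12)


class TestClinicalStats:
    def test_chi2_closed_form_any_2x2(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            stat, p = fus.chi2_2x2(a, b, c, d)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(expected, rel=1e-12)

    def test_published_sex_counts_significant(self):
        """Male/female 6/22 vs 93/35 gives chi-squared p < 0.001."""
        _, p = fus.chi2_2x2(22, 6, 35, 93)
        assert p < 0.001

    def test_identical_groups_p_one(self):
        base = pd.DataFrame({
            "sex": ["female", "male"] * 10, "age": list(range(20)),
            "max_diameter": np.linspace(2, 8, 20),
            "location": ["left", "right"] * 10, "habit": ["yes", "no"] * 10,
        })
        g1 = base.assign(group="HEAML")
        g0 = base.assign(group="non-HEAML")
        rep = fus.clinical_stats(pd.concat([g1, g0], ignore_index=True))
        assert rep.loc["age", "p_value"] == pytest.approx(1.0, abs=1e-9)
        assert rep.loc["sex", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_report_shape_and_floor(self, rng):
        n = 60
        df = pd.DataFrame({
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age": rng.normal(50, 10, n),
            "max_diameter": rng.normal(5, 1, n),
            "location": np.where(rng.random(n) < 0.5, "left", "right"),
            "habit": np.where(rng.random(n) < 0.5, "yes", "no"),
            "group": ["HEAML"] * 20 + ["non-HEAML"] * 40,
        })
        rep = fus.clinical_stats(df)
        assert set(rep.index) == {"sex", "location", "habit", "age", "max_diameter"}
        assert ((rep.p_value >= 0.001) | (rep.p_display == "<0.001")).all()
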