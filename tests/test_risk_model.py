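"""Logistic MLE, backward elimination, calibration/AUROC, risk statistics, WRS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pgxbleed import published
from pgxbleed.association import crosstab_2x2
from pgxbleed.cohort_io import carrier_encode
from pgxbleed.risk_model import (
    LogisticFit,
    SeparationWarning,
    attributable_risk,
    auroc,
    backward_eliminate,
    fit_logistic_mle,
    hosmer_lemeshow,
    nng,
    nng_audit,
    stratify_by_percentile,
    weighted_risk_score,
)
from pgxbleed.synthetic_cohort import SimConfig, exposure_frame, simulate_cohort


class TestLogisticMle:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(21), np.zeros(121)]
        fit = fit_logistic_mle(pd.DataFrame(index=range(142)), y)
        assert fit.beta["const"] == pytest.approx(math.log(21 / 121), abs=1e-8)

    def test_single_binary_predictor_equals_crude_or(self, demo_cohort):
        gm, pt = demo_cohort
        x = carrier_encode(gm, "rs5050")
        fit = fit_logistic_mle(pd.DataFrame({"rs5050": x}), pt.bleeding)
        ct = crosstab_2x2(x, pt.bleeding)
        crude = (ct.a * ct.d) / (ct.b * ct.c)
        assert fit.aor["rs5050"] == pytest.approx(crude, rel=1e-6)
        assert fit.gradient_norm < 1e-6

    def test_one_parameter_fit_matches_likelihood_grid(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        fit = fit_logistic_mle(pd.DataFrame({"x": x}), y, add_intercept=False)
        grid = np.arange(-5, 5, 1e-4)
        eta = np.outer(grid, x)
        ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=1)
        beta_star = grid[int(np.argmax(ll))]
        assert fit.beta["x"] == pytest.approx(beta_star, abs=1e-3)

    def test_recovers_generating_effects_at_large_n(self):
        gm, pt, truth = simulate_cohort(SimConfig(n_subjects=100_000, seed=31))
        fit = fit_logistic_mle(exposure_frame(truth), pt.bleeding)
        assert fit.aor["rs5050_carrier"] == pytest.approx(5.04, rel=0.05)
        assert fit.aor["rs2640543_carrier"] == pytest.approx(3.17, rel=0.06)
        assert fit.aor["ace_h2h2"] == pytest.approx(0.12, rel=0.15)

    def test_separation_flagged(self):
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.warns(SeparationWarning):
            fit = fit_logistic_mle(pd.DataFrame({"x": x}), x.copy())
        assert not fit.converged

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(0)
        x = (rng.random(50) < 0.5).astype(float)
        X = pd.DataFrame({"a": x, "b": x})
        y = (rng.random(50) < 0.3).astype(float)
        with pytest.raises(ValueError, match="aliased.*'b'"):
            fit_logistic_mle(X, y)

    def test_wald_ci_coverage_near_nominal(self):
        # 95% Wald intervals should cover each generating beta ~95% of the
        # time; band allows 3 SE of Monte-Carlo noise at 300 replicates
        cover = {t: 0 for t in published.ADJUSTED_OR}
        reps = 300
        for r in range(reps):
            _, pt, truth = simulate_cohort(SimConfig(n_subjects=2000, seed=5000 + r))
            fit = fit_logistic_mle(exposure_frame(truth), pt.bleeding)
            for t, aor in published.ADJUSTED_OR.items():
                lo, hi = np.log(fit.aor_ci.loc[t])
                cover[t] += lo <= math.log(aor) <= hi
        for t, c in cover.items():
            assert 0.92 <= c / reps <= 0.98, (t, c / reps)


class TestBackwardElimination:
    def test_all_null_design_reduces_to_intercept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.integers(0, 2, size=(400, 3)).astype(float),
                         columns=["a", "b", "c"])
        y = (rng.random(400) < 0.2).astype(float)
        res = backward_eliminate(X, y, ["a", "b", "c"])
        assert res.fit.terms == []
        assert len(res.path) == 3

    def test_weakest_term_removed_first(self):
        rng = np.random.default_rng(2)
        n = 800
        strong = (rng.random(n) < 0.4).astype(float)
        noise = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.08 + 0.25 * strong).astype(float)
        X = pd.DataFrame({"strong": strong, "noise": noise})
        res = backward_eliminate(X, y, ["strong", "noise"])
        assert res.path[0][0] == "noise"
        assert "strong" in res.fit.terms

    def test_forced_in_never_removed(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"junk": (rng.random(300) < 0.5).astype(float)})
        y = (rng.random(300) < 0.2).astype(float)
        res = backward_eliminate(X, y, [], forced_in=["junk"])
        assert res.fit.terms == ["junk"]

    def test_recovers_generating_terms_in_most_replicates(self):
        # full pipeline per replicate: simulate, phase, screen, eliminate
        from pgxbleed.association import univariate_screen
        from pgxbleed.cohort_io import AnalysisTable
        from pgxbleed.haplo_ld import (assign_diplotypes,
                                       em_haplotype_frequencies,
                                       filter_haplotypes, hom_indicator)

        target = {"rs5050_carrier", "rs2640543_carrier", "ace_h2h2"}
        hits = 0
        reps = 60
        for r in range(reps):
            gm, pt, _ = simulate_cohort(SimConfig(n_subjects=2000, seed=9000 + r))
            hs = filter_haplotypes(
                em_haplotype_frequencies(gm, published.ACE_LOCI), 0.01)
            h2 = hom_indicator(assign_diplotypes(hs, gm), published.H2_SEQUENCE)
            cols = {f"{s.snp_id}_carrier": carrier_encode(gm, s.snp_id)
                    for s in published.SNP_DEFS
                    if s.snp_id not in published.ACE_LOCI}
            cols["ace_h2h2"] = h2
            for c in ("sex_male", "age_ge_65", "hypertension",
                      "atrial_fibrillation"):
                cols[c] = pt.df[c].to_numpy(dtype=float)
            frame = pd.DataFrame(cols)
            frame.insert(0, "bleeding", pt.bleeding)
            screen = univariate_screen(AnalysisTable(frame=frame))
            res = backward_eliminate(frame[screen.selected], pt.bleeding,
                                     screen.selected)
            hits += set(res.fit.terms) >= target
        assert hits / reps > 0.8


class TestDiagnostics:
    def test_hosmer_lemeshow_df_follows_group_count(self):
        rng = np.random.default_rng(4)
        probs = rng.random(700)
        y = (rng.random(700) < probs).astype(float)
        res = hosmer_lemeshow(probs, y, g=7)
        assert res.g_used == 7 and res.df == 5
        assert hosmer_lemeshow(probs, y, g=10).df == 8

    def test_hosmer_lemeshow_constant_probs_degenerate(self):
        with pytest.warns(RuntimeWarning):
            res = hosmer_lemeshow(np.full(50, 0.2),
                                  np.r_[np.ones(10), np.zeros(40)])
        assert np.isnan(res.p_value)

    def test_hosmer_lemeshow_p_uniform_when_calibrated(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(150):
            n = 400
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-1.5 + 0.8 * x1 + 0.5 * x2)))
            y = (rng.random(n) < p).astype(float)
            fit = fit_logistic_mle(pd.DataFrame({"x1": x1, "x2": x2}), y)
            probs = fit.predict(pd.DataFrame({"x1": x1, "x2": x2}))
            pvals.append(hosmer_lemeshow(probs, y).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_auroc_extremes(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        assert auroc(np.r_[np.ones(5), np.zeros(5)], y) == 1.0
        rng = np.random.default_rng(7)
        big_y = (rng.random(20000) < 0.3).astype(float)
        assert auroc(rng.random(20000), big_y) == pytest.approx(0.5, abs=0.02)

    def test_auroc_single_class_errors(self):
        with pytest.raises(ValueError, match="one outcome class"):
            auroc(np.arange(4.0), np.ones(4))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=4, max_size=30),
           st.data())
    def test_auroc_equals_all_pairs_counting(self, scores, data):
        y = data.draw(st.lists(st.integers(0, 1), min_size=len(scores),
                               max_size=len(scores)))
        scores, y = np.array(scores, float), np.array(y, float)
        if len(set(y)) < 2:
            return
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(scores, y) == pytest.approx(wins / (len(pos) * len(neg)))


class TestRiskStatistics:
    @pytest.mark.parametrize("aor,pct", [(5.04, 80.2), (3.17, 68.5), (1.0, 0.0)])
    def test_attributable_risk_values(self, aor, pct):
        value, _, inverted = attributable_risk(aor)
        assert round(value, 1) == pct and not inverted

    def test_protective_aor_inverted(self):
        value, aor_used, inverted = attributable_risk(0.12)
        assert inverted and aor_used == pytest.approx(1 / 0.12)
        assert round(value, 1) == 88.0

    def test_attributable_risk_monotone(self):
        vals = [attributable_risk(a)[0] for a in (1.0, 1.5, 2.0, 5.0, 50.0)]
        assert vals == sorted(vals) and vals[0] == 0.0

    def test_nonpositive_aor_rejected(self):
        with pytest.raises(ValueError):
            attributable_risk(0.0)

    def test_nng_round_numbers(self):
        rs = nng(2.0, 0.5)
        assert (rs.rrr, rs.arr, rs.nng) == (0.5, 0.25, 4)

    def test_nng_h2_with_overall_incidence(self):
        rs = nng(0.12, published.OVERALL_INCIDENCE)
        assert rs.rrr == pytest.approx(0.88, abs=5e-4)
        assert rs.arr == pytest.approx(0.1302, abs=5e-4)
        assert rs.nng == 8

    def test_nng_near_null_flagged(self):
        rs = nng(1.0001, 0.1)
        assert rs.nng > 1e5 and "impractical" in rs.flagged
        assert nng(1.0, 0.1).nng == float("inf")

    def test_nng_audit_reports_all_conventions(self):
        audit = nng_audit(0.12, published.OVERALL_INCIDENCE,
                          exposed_risk=1 / 33, unexposed_risk=20 / 109)
        assert audit["overall_incidence"].nng == 8
        assert set(audit) == {"overall_incidence", "exposed_group_incidence",
                              "unexposed_group_incidence"}


def published_fit(n=8):
    """LogisticFit stub carrying the published adjusted effects."""
    terms = ["rs5050_carrier", "rs2640543_carrier", "ace_h2h2"]
    beta = pd.Series({"const": -3.0, **{t: math.log(published.ADJUSTED_OR[t])
                                        for t in terms}})
    dummy = pd.Series(0.3, index=beta.index)
    return LogisticFit(terms=terms, beta=beta, se=dummy, wald_p=dummy,
                       aor=np.exp(beta[terms]),
                       aor_ci=pd.DataFrame({"low": 0.0, "high": 99.0}, index=terms),
                       loglik=0.0, n=n, converged=True, gradient_norm=0.0)


class TestWeightedRiskScore:
    def frame(self):
        return pd.DataFrame({
            "rs5050_carrier":    [1.0, 0.0, 1.0, 0.0],
            "rs2640543_carrier": [1.0, 0.0, 0.0, 1.0],
            "ace_h2h2":          [0.0, 1.0, 1.0, 0.0],
        })

    def test_published_betas_give_points_2_1_2(self):
        rs = weighted_risk_score(published_fit(), self.frame())
        assert rs.points_map == {"rs5050_carrier": 2, "rs2640543_carrier": 1,
                                 "no_ace_h2h2": 2}
        # subject 0 carries everything adverse: maximum score 5
        assert rs.wrs.tolist() == [5.0, 0.0, 2.0, 3.0]

    def test_protective_term_recoded_to_absence(self):
        rs = weighted_risk_score(published_fit(), self.frame())
        assert rs.term_recode["no_ace_h2h2"] == ("ace_h2h2", True)

    def test_raw_beta_mode_is_linear_predictor_without_intercept(self):
        fit = published_fit()
        X = self.frame()
        rs = weighted_risk_score(fit, X, rounding="raw_beta")
        expect = (math.log(5.04) * X["rs5050_carrier"]
                  + math.log(3.17) * X["rs2640543_carrier"]
                  + (-math.log(0.12)) * (1 - X["ace_h2h2"]))
        np.testing.assert_allclose(rs.wrs, expect)

    def test_non_binary_term_rejected(self):
        X = self.frame()
        X["rs5050_carrier"] = [0.2, 0.4, 0.6, 0.8]
        with pytest.raises(ValueError, match="binary"):
            weighted_risk_score(published_fit(), X)


class TestStratification:
    def test_published_strata_odds_ratios(self):
        scores, outcome = published.demo_wrs_fixture()
        strat = stratify_by_percentile(scores, outcome,
                                       cuts=published.WRS_PERCENTILE_CUTS)
        assert strat.counts.loc["low", "n"] == 29
        assert strat.counts.loc["mid", "n"] == 102
        assert strat.counts.loc["high", "n"] == 11
        high = strat.group_or["high"]
        assert round(high.or_point, 2) == 11.98
        assert (round(high.ci_low, 2), round(high.ci_high, 2)) == (3.08, 46.65)
        low = strat.group_or["low"]
        assert low.or_point == pytest.approx(89 / 364, rel=1e-9)
        assert (round(low.ci_low, 2), round(low.ci_high, 2)) == (0.03, 1.95)

    def test_groups_partition_all_subjects(self):
        rng = np.random.default_rng(8)
        wrs = rng.integers(0, 6, size=500).astype(float)
        y = (rng.random(500) < 0.2).astype(float)
        strat = stratify_by_percentile(wrs, y)
        assert strat.counts["n"].sum() == 500

    def test_uniform_risk_gives_null_odds_ratios(self):
        rng = np.random.default_rng(9)
        wrs = rng.integers(0, 6, size=20000).astype(float)
        y = (rng.random(20000) < 0.2).astype(float)
        strat = stratify_by_percentile(wrs, y)
        for res in strat.group_or.values():
            assert res.or_point == pytest.approx(1.0, abs=0.15)

    def test_degenerate_scores_single_stratum(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            strat = stratify_by_percentile(np.full(40, 3.0),
                                           np.r_[np.ones(8), np.zeros(32)])
        assert strat.group_or == {}
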