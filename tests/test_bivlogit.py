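"""Plackett-Dale bivariate logistic regression: cells, likelihood, fitting."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from spatbiv import (
    Dataset,
    ModelSpec,
    SeparationError,
    SpatialWeights,
    ValidationError,
    add_spatial_autocovariate,
    bivariate_loglik,
    cell_probabilities,
    dataset_from_cells,
    fit_bivariate_logit,
    fit_univariate_logit,
    plackett_p11,
    summarize_fit,
)


def cells_odds_ratio(p1, p2, p11):
    return (p11 * (1 - p1 - p2 + p11)) / ((p1 - p11) * (p2 - p11))


class TestPlackettP11:
    def test_independence(self):
        assert plackett_p11(0.3, 0.4, 1.0) == pytest.approx(0.12, abs=1e-15)

    def test_strong_positive_association(self):
        # quadratic-root oracle: cells (0.41667, 0.08333, 0.08333, 0.41667) have OR 25
        p11 = plackett_p11(0.5, 0.5, 25.0)
        assert p11 == pytest.approx(0.41667, abs=5e-6)
        assert cells_odds_ratio(0.5, 0.5, p11) == pytest.approx(25.0, rel=1e-8)

    def test_survey_2000_joint_cell(self):
        # marginals and OR printed for the 2000 survey reproduce its joint cell
        assert plackett_p11(0.104, 0.055, 15.81) == pytest.approx(0.0313, abs=5e-5)

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValidationError):
            plackett_p11(0.3, 0.4, 0.0)
        with pytest.raises(ValidationError):
            plackett_p11(0.3, 0.4, -2.0)

    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        log_psi=st.floats(-4, 4),
    )
    @settings(max_examples=300, derandomize=True)
    def test_round_trip_and_frechet_bounds(self, p1, p2, log_psi):
        psi = float(np.exp(log_psi))
        p11 = plackett_p11(p1, p2, psi)
        assert max(0.0, p1 + p2 - 1.0) < p11 < min(p1, p2)
        assert cells_odds_ratio(p1, p2, p11) == pytest.approx(psi, rel=1e-6, abs=1e-8)

    def test_monotone_in_psi(self):
        psis = np.exp(np.linspace(-3, 3, 25))
        vals = [plackett_p11(0.3, 0.6, s) for s in psis]
        assert np.all(np.diff(vals) > 0)


class TestCellProbabilities:
    def test_symmetric_independence(self):
        c = cell_probabilities(0.0, 0.0, 0.0)
        for arr in (c.p11, c.p10, c.p01, c.p00):
            assert arr[0] == pytest.approx(0.25, abs=1e-12)

    def test_strong_association_cell(self):
        c = cell_probabilities(0.0, 0.0, np.log(25.0))
        assert c.p11[0] == pytest.approx(0.41667, abs=5e-6)

    @given(
        eta1=st.floats(-6, 6),
        eta2=st.floats(-6, 6),
        log_psi=st.floats(-3, 3),
    )
    @settings(max_examples=200, derandomize=True)
    def test_cells_sum_to_one_and_reproduce_marginals(self, eta1, eta2, log_psi):
        c = cell_probabilities(eta1, eta2, log_psi)
        total = c.p11 + c.p10 + c.p01 + c.p00
        assert total[0] == pytest.approx(1.0, abs=1e-10)
        assert (c.p11 + c.p10)[0] == pytest.approx(expit(eta1), abs=1e-10)
        assert (c.p11 + c.p01)[0] == pytest.approx(expit(eta2), abs=1e-10)


class TestBivariateLoglik:
    def test_independence_factorizes(self):
        ds = dataset_from_cells(12, 18, 8, 12)  # OR = 1 exactly
        spec = ModelSpec()
        p1 = 30 / 50
        p2 = 20 / 50
        params = np.array([logit(p1), logit(p2)])
        ll = bivariate_loglik(params, ds, spec, fixed_log_psi=0.0)
        bern = 30 * np.log(p1) + 20 * np.log(1 - p1) + 20 * np.log(p2) + 30 * np.log(1 - p2)
        assert ll == pytest.approx(bern, rel=1e-12)

    def test_grouped_equals_recordwise(self):
        # evaluating cell-count x log(p) by hand must equal the package's sum
        ds = dataset_from_cells(7, 3, 5, 11)
        params = np.array([0.3, -0.4, 0.8])
        ll = bivariate_loglik(params, ds, ModelSpec())
        c = cell_probabilities(0.3, -0.4, 0.8)
        manual = (
            7 * np.log(c.p11[0]) + 3 * np.log(c.p10[0]) + 5 * np.log(c.p01[0]) + 11 * np.log(c.p00[0])
        )
        assert ll == pytest.approx(manual, rel=1e-12)

    def test_saturated_maximum_is_multinomial_bound(self):
        cells = (250, 581, 189, 6946)
        ds = dataset_from_cells(*cells)
        fit = fit_bivariate_logit(ds, ModelSpec())
        n = sum(cells)
        bound = sum(c * np.log(c / n) for c in cells)
        assert fit.loglik == pytest.approx(bound, abs=1e-6)

    def test_wrong_parameter_count_rejected(self):
        ds = dataset_from_cells(1, 1, 1, 1)
        with pytest.raises(ValidationError, match="parameters"):
            bivariate_loglik(np.zeros(5), ds, ModelSpec())


class TestUnivariateLogit:
    def test_intercept_only_closed_form(self):
        ds = dataset_from_cells(15, 15, 35, 35)  # 30 ANC successes of 100
        fit = fit_univariate_logit(ds, 1, ModelSpec())
        assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)
        assert fit.coef[0] == pytest.approx(-0.8473, abs=5e-5)

    def test_binary_covariate_equals_log_odds_ratio(self):
        df = pd.DataFrame(
            {
                "anc": [1] * 30 + [0] * 70 + [1] * 60 + [0] * 40,
                "dc": 0,
                "zone": "A",
                "year": "2000",
                "x": ["a"] * 100 + ["b"] * 100,
            }
        )
        ds = Dataset(df, schema={"x": ["a", "b"]})
        fit = fit_univariate_logit(ds, 1, ModelSpec(covariates1=["x"]))
        log_or = np.log((60 * 70) / (40 * 30))
        assert fit.coef[1] == pytest.approx(log_or, abs=1e-8)

    def test_all_successes_is_separation(self):
        ds = dataset_from_cells(5, 5, 0, 0)  # anc == 1 for everyone
        with pytest.raises(SeparationError):
            fit_univariate_logit(ds, 1, ModelSpec())

    def test_rank_deficiency_detected(self):
        df = pd.DataFrame(
            {
                "anc": [1, 0, 1, 0],
                "dc": [0, 0, 1, 1],
                "zone": "A",
                "year": "2000",
                "x": ["a", "a", "b", "b"],
                "x2": ["a", "a", "b", "b"],
            }
        )
        ds = Dataset(df, schema={"x": ["a", "b"], "x2": ["a", "b"]})
        with pytest.raises(SeparationError, match="rank"):
            fit_univariate_logit(ds, 1, ModelSpec(covariates1=["x", "x2"]))


class TestAutocovariateColumns:
    def _two_zone_dataset(self):
        rows = []
        for zone, p_anc, p_dc in (("A", 0.2, 0.4), ("B", 0.8, 0.6)):
            n1 = int(10 * p_anc)
            nd = int(10 * p_dc)
            for i in range(10):
                rows.append((1 if i < n1 else 0, 1 if i < nd else 0, zone, "2000"))
        return Dataset(pd.DataFrame(rows, columns=["anc", "dc", "zone", "year"]))

    def test_two_zone_swap(self):
        ds = self._two_zone_dataset()
        w = SpatialWeights.from_edges([("A", "B")])
        out = add_spatial_autocovariate(ds, w)
        a = out.df[out.df["zone"] == "A"]
        b = out.df[out.df["zone"] == "B"]
        assert (a["Si1"] == 0.8).all() and (b["Si1"] == 0.2).all()
        assert (a["Si2"] == 0.6).all() and (b["Si2"] == 0.4).all()

    def test_island_gets_global_prevalence(self):
        ds = self._two_zone_dataset()
        w = SpatialWeights(["A", "B"], {"A": set(), "B": set()})
        with pytest.warns(UserWarning, match="island"):
            out = add_spatial_autocovariate(ds, w)
        assert np.allclose(out.df["Si1"], 0.5)  # overall ANC prevalence

    def test_zone_missing_from_registry(self):
        ds = self._two_zone_dataset()
        w = SpatialWeights.from_edges([("A", "C")])
        with pytest.raises(ValidationError, match="B"):
            add_spatial_autocovariate(ds, w)


class TestFitBivariate:
    def test_saturated_fit_matches_survey_2000(self):
        ds = dataset_from_cells(250, 581, 189, 6946)
        fit = fit_bivariate_logit(ds, ModelSpec())
        assert fit.dependency_or == pytest.approx(15.81, abs=0.01)
        cells = fit.fitted_cells(ds, ModelSpec())
        n = 7966
        assert cells.p11[0] == pytest.approx(250 / n, abs=1e-6)
        assert cells.p00[0] == pytest.approx(6946 / n, abs=1e-6)

    def test_fixed_independence_reproduces_univariate_mles(self, sim_small):
        ds, _, _ = sim_small
        spec = ModelSpec(["wealth", "residence"], ["wealth"])
        fit = fit_bivariate_logit(ds, spec, fix_log_psi=0.0)
        u1 = fit_univariate_logit(ds, 1, spec)
        u2 = fit_univariate_logit(ds, 2, spec)
        assert np.allclose(fit.beta1, u1.coef, atol=1e-6)
        assert np.allclose(fit.beta2, u2.coef, atol=1e-6)

    def test_mle_is_local_max_on_parameter_grid(self):
        # coordinate-wise grid at 1e-3 resolution around the reported MLE
        ds = dataset_from_cells(40, 25, 15, 70)
        fit = fit_bivariate_logit(ds, ModelSpec())
        opt = np.array([fit.beta1[0], fit.beta2[0], fit.log_psi])
        ll_opt = bivariate_loglik(opt, ds, ModelSpec())
        for j in range(3):
            for delta in (-5e-3, -1e-3, 1e-3, 5e-3):
                p = opt.copy()
                p[j] += delta
                assert bivariate_loglik(p, ds, ModelSpec()) <= ll_opt + 1e-10

    def test_spatial_fit_estimates_autocovariate_terms(self, sim_small):
        ds, w, _ = sim_small
        spec = ModelSpec(["wealth"], ["wealth"], include_spatial=True)
        fit = fit_bivariate_logit(ds, spec, W=w)
        assert fit.names1[-1] == "Si1" and fit.names2[-1] == "Si2"
        assert fit.converged
        assert fit.spatial

    def test_spatial_without_weights_rejected(self, sim_small):
        ds, _, _ = sim_small
        with pytest.raises(ValidationError, match="SpatialWeights"):
            fit_bivariate_logit(ds, ModelSpec(include_spatial=True))

    def test_weighted_fit_equals_replicated_records(self):
        # frequency weight w is the same likelihood as w copies of the record
        base = dataset_from_cells(6, 4, 3, 7)
        rep_df = pd.concat([base.df, base.df[base.df["anc"] == 1]], ignore_index=True)
        replicated = Dataset(rep_df)
        weighted_df = base.df.copy()
        weighted_df.loc[weighted_df["anc"] == 1, "weight"] = 2.0
        weighted = Dataset(weighted_df)
        f1 = fit_bivariate_logit(replicated, ModelSpec(), use_weights=False)
        f2 = fit_bivariate_logit(weighted, ModelSpec(), use_weights=True)
        assert np.allclose(f1.beta1, f2.beta1, atol=1e-6)
        assert f1.log_psi == pytest.approx(f2.log_psi, abs=1e-6)


class TestSummarizeFit:
    def test_or_and_ci_formula(self):
        # a coefficient of 0.2968 with SE 0.059 must give OR 1.346, CI by exp(est +- 1.96 se)
        est, se = 0.2968, 0.059
        assert np.exp(est) == pytest.approx(1.346, abs=5e-4)
        assert np.exp(est - 1.96 * se) == pytest.approx(1.199, abs=5e-3)
        assert np.exp(est + 1.96 * se) == pytest.approx(1.511, abs=5e-3)
        ds = dataset_from_cells(40, 25, 15, 70)
        fit = fit_bivariate_logit(ds, ModelSpec())
        tab = summarize_fit(fit)
        row = tab.iloc[0]
        assert row["odds_ratio"] == pytest.approx(np.exp(row["estimate"]))
        assert row["ci_low"] == pytest.approx(np.exp(row["estimate"] - 1.96 * row["se"]))

    def test_zero_estimate_symmetric_ci(self):
        lo, hi = np.exp(0 - 1.96 * 0.1), np.exp(0 + 1.96 * 0.1)
        assert lo * hi == pytest.approx(1.0)

    def test_report_round_trips_through_json(self):
        ds = dataset_from_cells(40, 25, 15, 70)
        tab = summarize_fit(fit_bivariate_logit(ds, ModelSpec()))
        recovered = pd.DataFrame(json.loads(tab.to_json(orient="records")))
        assert np.allclose(recovered["estimate"], tab["estimate"])
        assert list(recovered["term"]) == list(tab["term"])
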