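"""Comparative statistics layer: correlations, ANOVA, PCA imputation,
flight LMMs, marginal means, selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from pierisflight.stats import (
    MORPHO_VARIABLES,
    anova_morphology,
    cohens_d_from_fit,
    dredge_all_subsets,
    fit_flight_lmm,
    marginal_means,
    morphology_effects,
    pairwise_correlations,
    pca_with_imputation,
    stepwise_backward,
    temperature_models,
    term_test,
)


class TestCorrelations:
    def test_all_pairs_present(self, morpho_table):
        tab = pairwise_correlations(morpho_table)
        assert len(tab) == 10  # C(5, 2)
        assert tab.r.between(-1, 1).all()
        assert tab.p.between(0, 1).all()

    def test_perfect_correlation(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        tab = pairwise_correlations(df, variables=("a", "b"))
        assert tab.r.iloc[0] == pytest.approx(1.0)

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="constant"):
            pairwise_correlations(df, variables=("a", "b"))

    def test_too_few_cases(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan], "b": [2.0, np.nan, 3]})
        with pytest.raises(ValueError, match="complete cases"):
            pairwise_correlations(df, variables=("a", "b"))


class TestAnova:
    def test_shape_and_terms(self, morpho_table):
        tab = anova_morphology(morpho_table)
        assert len(tab) == 3 * len(MORPHO_VARIABLES)
        assert set(tab.term) == {"species", "form", "species:form"}
        assert (tab.F >= 0).all() and tab.p.between(0, 1).all()

    def test_single_level_factor_raises(self, morpho_table):
        sub = morpho_table[morpho_table.species == "P. napi"]
        with pytest.raises(ValueError, match="levels"):
            anova_morphology(sub)

    def test_saturated_cells_raise(self, morpho_table):
        one = morpho_table.groupby(["species", "form"]).head(1)
        with pytest.raises(ValueError, match="single observation"):
            anova_morphology(one)


class TestPCAImputation:
    def test_no_missing_equals_plain_pca(self, rng):
        X = rng.normal(size=(60, 5))
        df = pd.DataFrame(X, columns=list("abcde"))
        res = pca_with_imputation(df)
        Z = (X - X.mean(0)) / X.std(0)
        ref = PCA().fit(Z - Z.mean(0))
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   ref.explained_variance_ratio_,
                                   atol=1e-10)
        assert res.n_imputed == 0
        pd.testing.assert_frame_equal(res.completed, df)

    def test_rank2_exact_recovery(self, rng):
        # data exactly rank 2 after standardization: EM recovers the
        # deleted cells to numerical precision
        U = rng.normal(size=(80, 2))
        V = rng.normal(size=(2, 6))
        X = U @ V
        X = (X - X.mean(0)) / X.std(0)
        full = pd.DataFrame(X.copy(), columns=list("abcdef"))
        holes = pd.DataFrame(X.copy(), columns=list("abcdef"))
        idx = [(3, 0), (10, 2), (40, 5), (77, 1), (55, 3)]
        for i, j in idx:
            holes.iloc[i, j] = np.nan
        res = pca_with_imputation(holes, ncp=2)
        assert res.n_imputed == len(idx)
        np.testing.assert_allclose(res.completed.to_numpy(),
                                   full.to_numpy(), atol=1e-5)

    def test_too_much_missingness(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df.iloc[:3, 0] = np.nan  # 30%
        with pytest.raises(ValueError, match="20%"):
            pca_with_imputation(df)

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 4, 4]})
        with pytest.raises(ValueError, match="constant"):
            pca_with_imputation(df)


class TestFlightModels:
    def test_positive_response_logged(self, cohort):
        res = fit_flight_lmm(cohort.flights, "mean_velocity")
        assert res.log_transformed
        assert res.n_obs == 106 and res.n_groups == 31
        assert {"term", "estimate", "se", "df", "F", "p"} <= set(
            res.coef_table.columns)

    def test_signed_response_untransformed(self, cohort):
        res = fit_flight_lmm(cohort.flights, "ascent_angle")
        assert not res.log_transformed

    def test_log_transform_rejects_nonpositive(self, cohort):
        with pytest.raises(ValueError, match="log"):
            fit_flight_lmm(cohort.flights, "ascent_angle",
                           log_transform=True)

    def test_missing_responses_dropped(self, cohort):
        res = fit_flight_lmm(cohort.flights, "wingbeat_frequency")
        assert res.n_obs == 106 - 4

    def test_term_test(self, cohort):
        res = fit_flight_lmm(cohort.flights, "mean_velocity")
        out = term_test(res, "form")
        assert out["F"] == pytest.approx((out["estimate"]
                                          / out["se"]) ** 2)
        assert 0 <= out["p"] <= 1
        with pytest.raises(ValueError):
            term_test(res, "altitude")

    def test_form_velocity_gap_detected(self, cohort):
        # generator means 1.2 vs 1.7 m/s: the form effect must show
        res = fit_flight_lmm(cohort.flights, "mean_velocity")
        assert term_test(res, "form")["p"] < 0.01

    def test_cohens_d(self):
        assert cohens_d_from_fit(1.0, 0.5) == pytest.approx(2.0)
        assert round(cohens_d_from_fit(-2.99, 2.00), 2) == -1.50
        with pytest.raises(ValueError):
            cohens_d_from_fit(1.0, 0.0)


class TestMarginalMeans:
    def test_backtransformed_means_near_targets(self, cohort):
        res = fit_flight_lmm(cohort.flights, "mean_velocity")
        mm = marginal_means(res, "form", backtransform=True)
        means = mm.means.set_index("level").emmean
        assert means["summer"] > means["spring"]
        assert means["spring"] == pytest.approx(1.2, rel=0.2)
        assert means["summer"] == pytest.approx(1.7, rel=0.2)

    def test_tukey_not_smaller_than_unadjusted(self, cohort):
        res = fit_flight_lmm(cohort.flights, "turning_rate")
        mm = marginal_means(res, "form")
        assert (mm.contrasts.p_tukey
                >= mm.contrasts.p_unadjusted - 1e-12).all()

    def test_balanced_oneway_equals_raw_means(self):
        # balanced design, no covariates: emmeans = arithmetic group means
        rng = np.random.default_rng(2)
        n_ind, per = 12, 4
        form = np.repeat(["spring", "summer"], n_ind // 2 * per)
        ind = np.repeat([f"i{k}" for k in range(n_ind)], per)
        y = np.where(form == "summer", 2.0, 1.0) \
            + rng.normal(0, 0.1, len(form))
        df = pd.DataFrame({"specimen_id": ind, "form": form, "y": y})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_flight_lmm(df, "y", fixed=("form",), covariates=(),
                                 log_transform=False)
        mm = marginal_means(res, "form")
        raw = df.groupby("form").y.mean()
        for lv in ("spring", "summer"):
            assert mm.means.set_index("level").emmean[lv] == pytest.approx(
                raw[lv], abs=1e-9)

    def test_unknown_factor(self, cohort):
        res = fit_flight_lmm(cohort.flights, "mean_velocity")
        with pytest.raises(ValueError):
            marginal_means(res, "altitude")


def _morpho_flight_frame(cohort, morpho_table):
    keep = ["specimen_id", *MORPHO_VARIABLES]
    return cohort.flights.merge(morpho_table[keep], on="specimen_id")


class TestSelection:
    def test_morphology_effects_table(self, cohort, morpho_table):
        data = _morpho_flight_frame(cohort, morpho_table)
        res, tab = morphology_effects(data, "mean_velocity")
        assert set(tab.trait) == set(MORPHO_VARIABLES)
        np.testing.assert_allclose(tab.cohens_d, tab.slope / tab.se)
        assert res.n_obs == 106

    def test_stepwise_keeps_true_predictor(self):
        rng = np.random.default_rng(11)
        n_ind, per = 40, 3
        ind = np.repeat([f"i{k}" for k in range(n_ind)], per)
        aspect = np.repeat(rng.lognormal(0.6, 0.15, n_ind), per)
        decoy = np.repeat(rng.lognormal(0.0, 0.2, n_ind), per)
        y = np.exp(2.0 * np.log(aspect) + rng.normal(0, 0.05, len(ind)))
        df = pd.DataFrame({
            "specimen_id": ind, "sex": "male",
            "aspect_ratio": aspect, "decoy": decoy,
            "covered_distance": np.exp(rng.normal(1.5, 0.2, len(ind))),
            "y": y})
        sel = stepwise_backward(df, "y",
                                morpho_terms=("aspect_ratio", "decoy"))
        assert sel.retained == ["aspect_ratio"]
        assert sel.elimination_order == ["decoy"]

    def test_dredge_weights_and_best(self, cohort, morpho_table):
        data = _morpho_flight_frame(cohort, morpho_table)
        sel = dredge_all_subsets(
            data, "mean_velocity",
            morpho_terms=("aspect_ratio", "wing_loading_cm",
                          "outer_edge_index"))
        assert len(sel.table) == 8  # 2^3 subsets
        assert sel.table.weight.sum() == pytest.approx(1.0)
        assert sel.table.delta_aicc.iloc[0] == 0.0
        assert sel.variable_weights.between(0, 1).all()

    def test_dredge_term_cap(self, cohort, morpho_table):
        data = _morpho_flight_frame(cohort, morpho_table)
        with pytest.raises(ValueError, match="cap"):
            dredge_all_subsets(data, "mean_velocity",
                               morpho_terms=tuple(f"t{i}"
                                                  for i in range(13)))


class TestTemperature:
    def test_two_specifications(self, cohort):
        out = temperature_models(cohort.flights, "mean_velocity")
        assert set(out) == {"full", "daily"}
        assert "temperature_c" in out["full"].formula
        assert "day_mean_temperature" in out["daily"].formula

    def test_constant_temperature_raises(self, cohort):
        df = cohort.flights.assign(temperature_c=20.0)
        with pytest.raises(ValueError, match="constant"):
            temperature_models(df, "mean_velocity")
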