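import numpy as np
import pytest
from scipy import stats

from flavodoe import (
    GroundTruth,
    anova,
    box_behnken,
    fit_model,
    pareto_effects,
    plackett_burman,
    simulate_pbd_responses,
    simulate_responses,
)
from flavodoe.designs import DesignMatrix
from flavodoe.fitting import SingularModelError, build_model_matrix


def _random_bbd_instance(seed):
    rng = np.random.default_rng(seed)
    design = box_behnken(3, 5)
    y = rng.normal(18.0, 2.0, size=17)
    model = fit_model(design, y, order=2)
    return design, y, model


class TestCoefficientRecovery:
    def test_bbd_recovers_quadratic_truth_exactly(self, bbd_design, quad_truth, noiseless):
        y = simulate_responses(bbd_design, noiseless)
        model = fit_model(bbd_design, y, order=2)
        for term, value in quad_truth.coef.items():
            assert model.coef[term] == pytest.approx(value, abs=1e-8)
        assert model.coef["Intercept"] == pytest.approx(20.74, abs=1e-8)
        assert model.coef["ethanol^2"] == pytest.approx(-3.04, abs=1e-8)

    def test_pbd_recovers_first_order_truth_exactly(self, pbd_design, screening_truth, noiseless):
        y = simulate_pbd_responses(pbd_design, noiseless)
        model = fit_model(pbd_design, y, order=1)
        for term, value in screening_truth.coef.items():
            assert model.coef[term] == pytest.approx(value, abs=1e-8)
        assert model.coef["Intercept"] == pytest.approx(18.95, abs=1e-8)
        assert model.coef["ratio"] == pytest.approx(1.2, abs=1e-8)

    def test_constant_response_gives_intercept_only(self, bbd_design):
        model = fit_model(bbd_design, np.full(17, 7.25), order=2)
        assert model.coef["Intercept"] == pytest.approx(7.25, abs=1e-10)
        others = [v for t, v in model.coef.items() if t != "Intercept"]
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        """Brute-force (X'X)^-1 X'y on small instances agrees to 1e-10."""
        design, y, model = _random_bbd_instance(seed)
        X = build_model_matrix(design.levels, 2)
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(model.coef_vector(), beta_oracle, atol=1e-10)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        design, y, model = _random_bbd_instance(42)
        X = build_model_matrix(design.levels, 2)
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(model.coef_vector(), res.params, atol=1e-10)
        table = anova(model, design, y)
        assert table.stats["r_squared"] == pytest.approx(res.rsquared, abs=1e-10)
        assert table.stats["adj_r_squared"] == pytest.approx(res.rsquared_adj, abs=1e-10)
        # partial SS t-identity: our term t equals statsmodels' t
        p = pareto_effects(model, table)
        for term, idx in zip(model.terms[1:], range(1, len(model.terms))):
            trow = p.effects[p.effects.term == term]
            assert trow.t_abs.iloc[0] == pytest.approx(abs(res.tvalues[idx]), rel=1e-8)

    def test_rank_deficiency_names_aliased_terms(self):
        levels = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]])
        design = DesignMatrix(levels, ["a", "b"], "custom", np.zeros(5, bool))
        with pytest.raises(SingularModelError, match="b"):
            fit_model(design, np.arange(5.0), order=1)


class TestAnova:
    def test_degrees_of_freedom_structure(self, bbd_design):
        """17-run BBD: model 9, residual 7, lack-of-fit 3, pure error 4, total 16."""
        rng = np.random.default_rng(0)
        y = rng.normal(18, 1, 17)
        model = fit_model(bbd_design, y, order=2)
        table = anova(model, bbd_design, y)
        df = {r.Source: r.df for _, r in table.table.iterrows()}
        assert df["Model"] == 9
        assert df["Residual"] == 7
        assert df["Lack of Fit"] == 3
        assert df["Pure Error"] == 4
        assert df["Cor Total"] == 16

    def test_perfect_fit_zero_residual(self, bbd_design, noiseless):
        y = simulate_responses(bbd_design, noiseless)
        model = fit_model(bbd_design, y, order=2)
        table = anova(model, bbd_design, y)
        assert table.row("Residual").SS == pytest.approx(0.0, abs=1e-16)
        assert table.stats["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert table.stats["press"] == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("seed", range(20))
    def test_sum_of_squares_additivity(self, seed):
        design, y, model = _random_bbd_instance(seed)
        table = anova(model, design, y)
        ss = {r.Source: r.SS for _, r in table.table.iterrows()}
        total = ss["Cor Total"]
        assert ss["Model"] + ss["Residual"] == pytest.approx(total, rel=1e-8)
        assert ss["Lack of Fit"] + ss["Pure Error"] == pytest.approx(ss["Residual"], rel=1e-8)
        # brute-force total SS oracle
        assert total == pytest.approx(float(np.sum((y - y.mean()) ** 2)), rel=1e-12)

    def test_orthogonal_terms_partial_equals_sequential(self, pbd_design):
        y = simulate_pbd_responses(pbd_design, GroundTruth(), seed=3)
        model = fit_model(pbd_design, y, order=1)
        table = anova(model, pbd_design, y)
        # on an orthogonal design each term SS is n * beta^2
        for name in pbd_design.factor_names:
            assert table.row(name).SS == pytest.approx(12 * model.coef[name] ** 2, rel=1e-10)

    def test_no_replicates_omits_lack_of_fit(self, pbd_design):
        y = simulate_pbd_responses(pbd_design, GroundTruth(), seed=5)
        model = fit_model(pbd_design, y, order=1)
        table = anova(model, pbd_design, y)
        assert "Lack of Fit" not in set(table.table.Source)

    def test_response_length_mismatch_rejected(self, bbd_design):
        with pytest.raises(ValueError, match="17"):
            fit_model(bbd_design, np.ones(16), order=2)

    def test_fit_statistics_identities(self):
        design, y, model = _random_bbd_instance(11)
        table = anova(model, design, y)
        s = table.stats
        assert s["cv_percent"] == pytest.approx(100 * s["std_dev"] / s["mean"], rel=1e-12)
        assert s["std_dev"] == pytest.approx(np.sqrt(table.ms_residual), rel=1e-12)
        assert s["pred_r_squared"] <= s["r_squared"]

    def test_p_value_formatting(self, bbd_design, quad_truth):
        y = simulate_responses(bbd_design, GroundTruth(sigma=0.05), seed=2)
        model = fit_model(bbd_design, y, order=2)
        table = anova(model, bbd_design, y)
        shown = table.formatted()
        assert "< 0.0001" in set(shown.p)


class TestParetoEffects:
    def test_t_limit_matches_critical_value(self, pbd_design):
        """Two-sided 5% t limit on 6 residual df is 2.45 to two decimals."""
        y = simulate_pbd_responses(pbd_design, GroundTruth(), seed=1)
        model = fit_model(pbd_design, y, order=1)
        p = pareto_effects(model, anova(model, pbd_design, y), alpha=0.05)
        assert p.df_residual == 6
        assert round(p.t_limit, 2) == 2.45

    def test_bonferroni_uses_all_contrast_columns(self, pbd_design):
        y = simulate_pbd_responses(pbd_design, GroundTruth(), seed=1)
        model = fit_model(pbd_design, y, order=1)
        p = pareto_effects(model, anova(model, pbd_design, y))
        assert p.n_effects == 11
        assert p.bonferroni_limit == pytest.approx(
            stats.t.ppf(1 - 0.05 / 22, 6), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_t_squared_equals_term_F(self, seed):
        design, y, model = _random_bbd_instance(seed)
        table = anova(model, design, y)
        p = pareto_effects(model, table)
        for _, row in p.effects.iterrows():
            assert row.t_abs**2 == pytest.approx(table.row(row.term).F, rel=1e-6)

    def test_ratio_effect_sign_positive(self, pbd_design):
        y = simulate_pbd_responses(pbd_design, GroundTruth(), seed=9)
        model = fit_model(pbd_design, y, order=1)
        p = pareto_effects(model, anova(model, pbd_design, y))
        assert p.effects.loc[p.effects.term == "ratio", "sign"].iloc[0] == 1.0

    def test_effects_sorted_descending(self):
        design, y, model = _random_bbd_instance(3)
        p = pareto_effects(model, anova(model, design, y))
        assert list(p.effects.t_abs) == sorted(p.effects.t_abs, reverse=True)
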