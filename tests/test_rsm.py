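import numpy as np
import pytest
import statsmodels.api as sm

from uadese import build_bbd, fit_quadratic, anova, reduce_model, surface_grid, diagnostics
from uadese.design import FactorDef
from uadese.rsm import model_matrix, term_names
from uadese.synthetic import SurfaceSpec, reference_surface, simulate_bbd_responses


def _factors(k=4):
    return [FactorDef(f"x{i}", "u", center=0.0, step=1.0) for i in range(k)]


class TestFitQuadratic:
    def test_constant_response_gives_pure_intercept(self):
        table = build_bbd(_factors(), 5).with_responses([1.0] * 29)
        model = fit_quadratic(table)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(model.coefficients[1:], 0, atol=1e-12)

    def test_noiseless_synthetic_recovery(self, rng):
        """OLS recovers a known coefficient vector exactly on noiseless data."""
        truth = rng.normal(0, 0.1, 15)
        table = simulate_bbd_responses(
            SurfaceSpec(truth, noise_sd=0.0), build_bbd(_factors(), 5)
        )
        model = fit_quadratic(table)
        assert np.allclose(model.coefficients, truth, atol=1e-10)

    def test_matches_statsmodels_ols(self, study_table, full_model):
        M = model_matrix(study_table.coded_matrix)
        sm_fit = sm.OLS(study_table.responses, M).fit()
        assert np.allclose(full_model.coefficients, sm_fit.params, atol=1e-10)

    def test_missing_responses_listed(self):
        table = build_bbd(_factors(), 5)
        with pytest.raises(ValueError, match=r"\[1"):
            fit_quadratic(table)

    def test_rank_deficiency_names_collinear_terms(self):
        # duplicating a factor's column makes x0 and x1 indistinguishable
        table = build_bbd(_factors(3), 3)
        coded = table.coded_matrix
        coded[:, 1] = coded[:, 0]
        for run, row in zip(table.runs, coded):
            run.coded_levels = tuple(row)
        table = table.with_responses(np.arange(table.n_runs, dtype=float))
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(table)


class TestAnova:
    def test_additivity(self, study_anova):
        """SS and df decompose exactly: model + lack-of-fit + pure error = total."""
        a = study_anova
        ss = {r: a.row(r)["SS"] for r in
              ["Model", "Residual", "Lack of fit", "Pure error", "Corrected total"]}
        assert ss["Model"] + ss["Residual"] == pytest.approx(
            ss["Corrected total"], rel=1e-10)
        assert ss["Lack of fit"] + ss["Pure error"] == pytest.approx(
            ss["Residual"], rel=1e-10)
        df = {r: a.row(r)["df"] for r in
              ["Model", "Residual", "Lack of fit", "Pure error", "Corrected total"]}
        assert df["Model"] + df["Residual"] == df["Corrected total"] == 28
        assert df["Lack of fit"] + df["Pure error"] == df["Residual"]

    def test_pure_error_is_center_replicate_scatter(self, study_table, study_anova):
        center = study_table.center_responses()
        direct = float(((center - center.mean()) ** 2).sum())
        assert study_anova.row("Pure error")["SS"] == pytest.approx(direct, abs=1e-12)

    def test_partial_ss_closed_form_for_orthogonal_columns(self, study_table, full_model, study_anova):
        """For the orthogonal linear/interaction columns of a BBD the
        drop-one extra SS equals coefficient^2 * sum(column^2)."""
        M = model_matrix(study_table.coded_matrix)
        names = full_model.term_names
        k = 4
        lin_int = names[1 : 1 + k] + names[1 + 2 * k :]
        for name in lin_int:
            j = names.index(name)
            closed = full_model.coefficients[j] ** 2 * (M[:, j] ** 2).sum()
            assert study_anova.row(name)["SS"] == pytest.approx(closed, rel=1e-9)

    def test_noiseless_fit_is_perfect(self, rng):
        truth = rng.normal(0, 0.1, 15)
        table = simulate_bbd_responses(
            SurfaceSpec(truth, noise_sd=0.0), build_bbd(_factors(), 5)
        )
        a = anova(fit_quadratic(table), table)
        assert a.r2 == pytest.approx(1.0, abs=1e-9)
        assert a.row("Residual")["SS"] == pytest.approx(0.0, abs=1e-12)

    def test_no_center_replicates_warns_and_omits_split(self):
        table = build_bbd(_factors(), 1)
        spec = reference_surface(noise_sd=0.01, seed=3)
        table = simulate_bbd_responses(spec, table)
        model = fit_quadratic(table)
        with pytest.warns(UserWarning, match="center replicates"):
            a = anova(model, table)
        assert "Lack of fit" not in set(a.rows["source"])

    def test_r2_adj_below_r2(self, study_anova):
        assert 0 <= study_anova.r2_adj <= study_anova.r2 <= 1


class TestReduceModel:
    def test_study_term_set(self, reduced_model):
        kept = {n for n, m in zip(reduced_model.term_names, reduced_model.included) if m}
        assert kept == {
            "Intercept",
            "water_content", "extraction_temperature", "extraction_time",
            "water_content^2", "ultrasonic_power^2",
            "extraction_temperature^2", "extraction_time^2",
            "water_content*extraction_time",
            "ultrasonic_power*extraction_temperature",
        }

    def test_surviving_coefficients_unchanged(self, full_model, reduced_model):
        """BBD orthogonality: dropping terms leaves surviving linear and
        interaction coefficients identical to the full-model values."""
        names = full_model.term_names
        k = 4
        for name in names[1 : 1 + k] + names[1 + 2 * k :]:
            j = names.index(name)
            if reduced_model.included[j]:
                assert reduced_model.coefficients[j] == pytest.approx(
                    full_model.coefficients[j], abs=1e-10)

    def test_alpha_one_keeps_everything(self, full_model, study_anova, study_table):
        out = reduce_model(full_model, study_anova, study_table, alpha=1.0)
        assert out.included.all()
        assert np.allclose(out.coefficients, full_model.coefficients, atol=1e-12)

    def test_excluded_terms_are_exactly_zero(self, reduced_model):
        assert np.all(reduced_model.coefficients[~reduced_model.included] == 0)

    def test_r2_non_increasing_under_removal(self, full_model, study_anova, study_table, reduced_model):
        a_full = anova(full_model, study_table)
        a_red = anova(reduced_model, study_table)
        assert a_red.r2 <= a_full.r2 + 1e-12


class TestPredictAndGrid:
    def test_predict_at_origin_is_intercept(self, reduced_model):
        assert reduced_model.predict([0, 0, 0, 0]) == pytest.approx(
            reduced_model.intercept)

    def test_zero_model_predicts_zero(self):
        from uadese.rsm import QuadraticModel
        m = QuadraticModel(_factors(), np.zeros(15), np.ones(15, bool))
        assert m.predict([0.3, -0.7, 1.0, 0.2]) == 0.0

    def test_predict_length_mismatch(self, reduced_model):
        with pytest.raises(ValueError, match="entries"):
            reduced_model.predict([0.0, 0.0])

    def test_grid_matches_pointwise_predict(self, reduced_model):
        grid = surface_grid(reduced_model, (0, 3), resolution=3)
        assert len(grid) == 9
        for _, row in grid.iterrows():
            pt = [row["water_content_coded"], 0.0, 0.0, row["extraction_time_coded"]]
            assert row["predicted_yield"] == pytest.approx(reduced_model.predict(pt))

    def test_study_surface_maximum_is_interior(self, reduced_model):
        """Dense grid search over the water/time pair: the maximizer sits
        strictly inside the coded square (yield rises then falls)."""
        grid = surface_grid(reduced_model, (0, 3), resolution=81)
        best = grid.loc[grid["predicted_yield"].idxmax()]
        assert abs(best["water_content_coded"]) < 1
        assert abs(best["extraction_time_coded"]) < 1

    def test_identical_pair_rejected(self, reduced_model):
        with pytest.raises(ValueError, match="distinct"):
            surface_grid(reduced_model, (1, 1))

    def test_natural_coefficients_reproduce_predictions(self, reduced_model, rng):
        natc = reduced_model.natural_coefficients()
        for _ in range(10):
            coded = rng.uniform(-1, 1, 4)
            nat = [f.center + f.step * c for f, c in zip(reduced_model.factors, coded)]
            names = [f.name for f in reduced_model.factors]
            val = natc["Intercept"]
            val += sum(natc[n] * x for n, x in zip(names, nat))
            val += sum(natc[f"{n}^2"] * x**2 for n, x in zip(names, nat))
            import itertools
            for (i, j) in itertools.combinations(range(4), 2):
                val += natc[f"{names[i]}*{names[j]}"] * nat[i] * nat[j]
            assert val == pytest.approx(reduced_model.predict(coded), abs=1e-9)


class TestDiagnostics:
    def test_study_residuals_all_within_three(self, full_model, study_table):
        report = diagnostics(full_model, study_table)
        assert not report["flagged"].any()
        assert np.all(np.abs(report["studentized"]) <= 3)

    def test_noiseless_residuals_zero(self, rng):
        truth = rng.normal(0, 0.1, 15)
        table = simulate_bbd_responses(
            SurfaceSpec(truth, noise_sd=0.0), build_bbd(_factors(), 5)
        )
        report = diagnostics(fit_quadratic(table), table)
        assert np.allclose(report["residual"], 0, atol=1e-10)

    def test_gross_outlier_is_flagged(self):
        spec = reference_surface(noise_sd=0.0348, seed=11)
        table = simulate_bbd_responses(spec, build_bbd(_factors(), 5))
        responses = table.responses.copy()
        responses[7] += 10 * spec.noise_sd
        table = table.with_responses(responses)
        report = diagnostics(fit_quadratic(table), table)
        flagged_ids = set(report.loc[report["flagged"], "run_id"])
        assert 8 in flagged_ids
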