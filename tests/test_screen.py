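"""Regression screen: OLS correctness against the normal-equations oracle,
exact planted-coefficient recovery, and the selection rule."""

import numpy as np
import pandas as pd
import pytest

from gxescore.containers import ValidationError
from gxescore.phenotypes import compute_diet_deltas, compute_exercise_delta
from gxescore.screen import (
    RankDeficientError,
    fit_model_calorie,
    fit_model_diet,
    fit_model_exercise,
    fit_ols,
    screen_panel,
    select_snps,
)
from gxescore.simulate import (
    EffectSpec,
    SimConfig,
    generate_diet_outcomes,
    generate_exercise_series,
    generate_genotypes,
)


def _sim(n=200, seed=0, **kw):
    cfg = SimConfig(n_individuals=n, n_snps=4, seed=seed, **kw)
    g = generate_genotypes(cfg)
    diet = compute_diet_deltas(generate_diet_outcomes(cfg, g))
    exer = compute_exercise_delta(generate_exercise_series(cfg, g))
    return cfg, g, diet, exer


class TestFitOls:
    def test_exact_fit_recovers_slope_with_zero_residual(self):
        x = np.arange(1.0, 11.0)
        design = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_ols(design, 2.0 * x)
        assert fit.term("x")[0] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_normal_equations_oracle(self, oracle, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        X.insert(0, "const", 1.0)
        y = rng.normal(size=80)
        fit = fit_ols(X, y)
        beta, se, p = oracle(X, y)
        np.testing.assert_allclose(fit.params["coef"], beta, rtol=1e-10)
        np.testing.assert_allclose(fit.params["se"], se, rtol=1e-10)
        np.testing.assert_allclose(fit.params["p"], p, rtol=1e-8)

    def test_type_one_error_calibrated(self):
        # slope p-value under a pure-noise response rejects at ~alpha
        rng = np.random.default_rng(12345)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            design = pd.DataFrame({"const": 1.0, "x": x})
            if fit_ols(design, y).term("x")[2] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_constant_snp_column_raises_named_collinearity(self):
        design = pd.DataFrame({"const": 1.0, "snp": 0.0, "x": np.arange(10.0)})
        with pytest.raises(RankDeficientError, match="snp"):
            fit_ols(design, np.arange(10.0))

    def test_insufficient_n_raises(self):
        design = pd.DataFrame({"const": [1.0, 1.0], "x": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="insufficient"):
            fit_ols(design, np.array([1.0, 2.0]))

    def test_nan_rows_are_rejected(self):
        design = pd.DataFrame({"const": [1.0] * 5, "x": [1, 2, np.nan, 4, 5]})
        with pytest.raises(ValidationError, match="complete"):
            fit_ols(design, np.arange(5.0))


class TestModelFits:
    def test_diet_model_recovers_planted_interactions_exactly(self):
        cfg, g, diet, _ = _sim(
            n=120, seed=1, bodyfat_noise_sd=0.0,
            effects=[EffectSpec("snp0001", "CE", 0.01), EffectSpec("snp0001", "FE", -0.02)],
        )
        fr = fit_model_diet(diet, g, "snp0001")
        assert fr.target("CE")[0] == pytest.approx(0.01, rel=1e-8)
        assert fr.target("FE")[0] == pytest.approx(-0.02, rel=1e-8)

    def test_calorie_model_recovers_planted_interaction_exactly(self):
        cfg, g, diet, _ = _sim(
            n=120, seed=2, bodyfat_noise_sd=0.0,
            effects=[EffectSpec("snp0002", "TE", 0.0005)],
        )
        fr = fit_model_calorie(diet, g, "snp0002")
        assert fr.target("TE")[0] == pytest.approx(0.0005, rel=1e-8)

    def test_exercise_model_recovers_planted_main_effect_exactly(self):
        cfg, g, _, exer = _sim(
            n=120, seed=3, exercise_noise_sd=0.0,
            effects=[EffectSpec("snp0001", "EE", -0.14)],
        )
        fr = fit_model_exercise(exer, g, "snp0001")
        assert fr.target("EE")[0] == pytest.approx(-0.14, rel=1e-8)

    def test_missing_genotypes_reduce_complete_case_n(self):
        cfg, g, diet, _ = _sim(n=100, seed=4)
        col = g.counts["snp0001"].copy()
        col.iloc[:10] = np.nan
        g.counts["snp0001"] = col
        fr = fit_model_diet(diet, g, "snp0001")
        assert fr.fit.n_used == 90

    def test_constant_calorie_change_is_collinear(self, genotype_builder):
        cfg, g, diet, _ = _sim(n=50, seed=5)
        diet = diet.assign(d_kcal=100.0)
        with pytest.raises(RankDeficientError):
            fit_model_calorie(diet, g, "snp0001")

    def test_tiny_exercise_cohort_is_insufficient(self, genotype_builder, cohort_builder):
        g = genotype_builder({"s1": [1, 0, 2]})
        deltas = pd.DataFrame(
            {"gender": [0, 1, 0], "age": [50, 51, 52], "d_bodyfat_star": [0.1, -0.2, 0.3]},
            index=pd.Index(["I001", "I002", "I003"], name="individual"),
        )
        with pytest.raises(ValidationError, match="insufficient"):
            fit_model_exercise(deltas, g, "s1")

    def test_permuting_genotypes_destroys_planted_signal(self):
        cfg, g, _, exer = _sim(
            n=500, seed=6, effects=[EffectSpec("snp0001", "EE", -0.14)]
        )
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(20):
            perm = g.counts.sample(frac=1.0, random_state=rng.integers(2**31)).set_axis(
                g.counts.index
            )
            g_perm = type(g)(counts=perm, meta=g.meta)
            pvals.append(fit_model_exercise(exer, g_perm, "snp0001").target("EE")[2])
        assert np.median(pvals) > 0.05


class TestSelection:
    def _fits_with_pvalues(self, p_by_snp):
        cfg, g, diet, _ = _sim(n=80, seed=7)
        fits, _ = screen_panel(diet, None, g)
        # rewrite target p-values to the requested fixture values
        for fr in fits:
            if fr.model == 1 and fr.snp_id in p_by_snp:
                fr.fit.params.loc["d_carb:snp", "p"] = p_by_snp[fr.snp_id]
        return fits

    def test_strictly_below_alpha(self):
        fits = self._fits_with_pvalues({"snp0001": 0.04, "snp0002": 0.06})
        sel = select_snps(fits, alpha=0.05)
        assert "snp0001" in sel["CE"].snp_ids
        assert "snp0002" not in sel["CE"].snp_ids

    def test_exactly_alpha_not_selected(self):
        fits = self._fits_with_pvalues({"snp0001": 0.05})
        sel = select_snps(fits, alpha=0.05)
        assert "snp0001" not in sel["CE"].snp_ids

    def test_snp_can_join_multiple_categories(self):
        cfg, g, diet, _ = _sim(
            n=2000, seed=8,
            effects=[EffectSpec("snp0001", "CE", 0.02), EffectSpec("snp0001", "TE", 0.002)],
        )
        fits, _ = screen_panel(diet, None, g)
        sel = select_snps(fits, alpha=0.05)
        assert "snp0001" in sel["CE"].snp_ids
        assert "snp0001" in sel["TE"].snp_ids

    def test_rare_snps_are_skipped_with_reason(self, genotype_builder):
        cfg, g, diet, _ = _sim(n=100, seed=9)
        g.counts["snp0001"] = 0.0
        g.counts.loc[g.counts.index[:2], "snp0001"] = 1.0  # 2 carriers < 5
        fits, skipped = screen_panel(diet, None, g)
        assert "snp0001" in set(skipped["snp_id"])
        assert all(fr.snp_id != "snp0001" for fr in fits)
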