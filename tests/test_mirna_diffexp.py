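import dataclasses

import numpy as np
import pytest
from scipy import stats

from quiescence_mirnome import mirna_diffexp as md
from quiescence_mirnome import synthetic_data as synth
from quiescence_mirnome.core_io import ExpressionMatrix, SampleAnnotation
from quiescence_mirnome.errors import DesignError, ValidationError


def _nine_sample_annotations():
    out = []
    for iso in ("iso1", "iso2", "iso3"):
        for cond in ("proliferating", "serum_starved", "contact_inhibited"):
            out.append(SampleAnnotation(f"{iso}_{cond}", cond, iso))
    return out


class TestNormalizeTotalIntensity:
    def test_equal_totals_is_pure_log2(self):
        vals = np.array([[4.0, 2.0], [4.0, 6.0]])  # both columns total 8
        raw = ExpressionMatrix(vals, ["a", "b"], ["s1", "s2"])
        out = md.normalize_total_intensity(raw)
        assert np.allclose(out.values, np.log2(vals))

    def test_hand_computed_scale_factors(self):
        # totals (100, 300); mean 200 -> scales (2.0, 2/3)
        vals = np.array([[60.0, 100.0], [40.0, 200.0]])
        raw = ExpressionMatrix(vals, ["a", "b"], ["s1", "s2"])
        out = md.normalize_total_intensity(raw)
        expected = np.log2(vals * np.array([2.0, 2.0 / 3.0]))
        assert np.allclose(out.values, expected)

    def test_single_sample_unchanged(self):
        vals = np.array([[3.0], [5.0]])
        raw = ExpressionMatrix(vals, ["a", "b"], ["s1"])
        out = md.normalize_total_intensity(raw)
        assert np.allclose(out.values, np.log2(vals))

    def test_nonpositive_rejected(self):
        raw = ExpressionMatrix(np.array([[1.0, -2.0]]), ["a"], ["s1", "s2"])
        with pytest.raises(ValidationError):
            md.normalize_total_intensity(raw)


class TestBuildDesign:
    def test_nine_array_design_shape_and_rank(self):
        design = md.build_design(_nine_sample_annotations())
        assert design.matrix.shape == (9, 5)
        assert design.column_names == ["intercept", "x_Q", "x_S", "x_C1", "x_C2"]
        assert np.linalg.matrix_rank(design.matrix) == 5

    def test_serum_starved_indicators(self):
        design = md.build_design(_nine_sample_annotations())
        i = design.sample_ids.index("iso1_serum_starved")
        assert design.column("x_Q")[i] == 1.0
        assert design.column("x_S")[i] == 1.0

    def test_contact_inhibited_indicators(self):
        design = md.build_design(_nine_sample_annotations())
        i = design.sample_ids.index("iso2_contact_inhibited")
        assert design.column("x_Q")[i] == 1.0
        assert design.column("x_S")[i] == 0.0

    def test_missing_condition_rejected(self):
        annots = [a for a in _nine_sample_annotations()
                  if a.condition != "contact_inhibited"]
        with pytest.raises(DesignError):
            md.build_design(annots)


class TestFitExpressionModel:
    def test_noise_free_recovers_planted(self):
        cfg = synth.SyntheticConfig(seed=2, n_mirnas=30, noise_sd=1e-12,
                                    surrogate_effect_sd=0.0)
        expr, annots, truth = synth.gen_mirna_arrays(cfg)
        fit = md.fit_expression_model(expr, md.build_design(annots))
        for fid, planted in truth.responsive_mirnas.items():
            assert fit.coefficients.loc[fid, "x_Q"] == pytest.approx(planted, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(20, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(20)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        X = design.matrix
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ vals.T).T
        assert np.allclose(fit.coefficients.to_numpy(), beta_oracle, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(10, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(10)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        assert np.allclose(fit.residuals @ design.matrix, 0.0, atol=1e-10)
        assert fit.residual_df == 4

    def test_constant_feature_zero_slopes(self):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        expr = ExpressionMatrix(np.full((1, 9), 7.0), ["c"],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        for col in ("x_Q", "x_S", "x_C1", "x_C2"):
            assert fit.coefficients.loc["c", col] == pytest.approx(0.0, abs=1e-12)
        assert fit.coefficients.loc["c", "intercept"] == pytest.approx(7.0)

    def test_missing_feature_skipped(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(3, 9))
        vals[1, 4] = np.nan
        expr = ExpressionMatrix(vals, ["a", "b", "c"],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        assert fit.skipped_features == ["b"]
        assert fit.feature_ids == ["a", "c"]


class TestQuiescenceFTest:
    def test_f_equals_t_squared(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(5, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(5)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        f, _ = md.quiescence_f_test(fit)
        X = design.matrix
        xtx_inv = np.linalg.inv(X.T @ X)
        jq = design.column_names.index("x_Q")
        for i in range(5):
            sigma2 = (fit.residuals[i] ** 2).sum() / fit.residual_df
            t = fit.coefficients.iloc[i]["x_Q"] / np.sqrt(sigma2 * xtx_inv[jq, jq])
            assert f[i] == pytest.approx(t**2, rel=1e-9)

    def test_matches_nested_rss_oracle(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(4, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(4)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        f, p = md.quiescence_f_test(fit)
        X = design.matrix
        keep = [i for i, c in enumerate(design.column_names) if c != "x_Q"]
        Xr = X[:, keep]
        for i in range(4):
            y = vals[i]
            bf = np.linalg.lstsq(X, y, rcond=None)[0]
            br = np.linalg.lstsq(Xr, y, rcond=None)[0]
            rss_f = ((y - X @ bf) ** 2).sum()
            rss_r = ((y - Xr @ br) ** 2).sum()
            f_exp = (rss_r - rss_f) / (rss_f / fit.residual_df)
            assert f[i] == pytest.approx(f_exp, rel=1e-9)
            assert p[i] == pytest.approx(stats.f.sf(f_exp, 1, fit.residual_df))

    def test_null_pvalues_uniform(self):
        # 10^4 null features; KS against U(0,1) should not reject at 0.01
        rng = np.random.default_rng(77)
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(10_000, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(10_000)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        _, p = md.quiescence_f_test(fit)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestEstimateSurrogates:
    def test_planted_surrogate_recovered(self):
        cfg = synth.SyntheticConfig(seed=4, n_mirnas=150, noise_sd=0.1,
                                    surrogate_effect_sd=1.0)
        expr, annots, truth = synth.gen_mirna_arrays(cfg)
        design = md.build_design(annots)
        sva = md.estimate_surrogates(expr, design, n_permutations=300, seed=4)
        assert sva.n_significant == 1
        r = np.corrcoef(sva.vectors[:, 0], truth.surrogate_vector)[0, 1]
        assert abs(r) > 0.9

    def test_nothing_to_find_without_surrogate(self):
        none_found = 0
        for seed in range(10):
            cfg = synth.SyntheticConfig(seed=seed, n_mirnas=100,
                                        surrogate_effect_sd=0.0)
            expr, annots, _ = synth.gen_mirna_arrays(cfg)
            sva = md.estimate_surrogates(expr, md.build_design(annots),
                                         n_permutations=200, seed=seed)
            none_found += sva.n_significant == 0
        assert none_found >= 7

    def test_vectors_unit_norm(self):
        cfg = synth.SyntheticConfig(seed=4, surrogate_effect_sd=1.0, n_mirnas=80)
        expr, annots, _ = synth.gen_mirna_arrays(cfg)
        sva = md.estimate_surrogates(expr, md.build_design(annots),
                                     n_permutations=200, seed=1)
        for j in range(sva.vectors.shape[1]):
            assert np.linalg.norm(sva.vectors[:, j]) == pytest.approx(1.0)


class TestConditionResponses:
    def test_noise_free_equalities(self):
        cfg = synth.SyntheticConfig(seed=6, n_mirnas=25, noise_sd=1e-12,
                                    surrogate_effect_sd=0.0)
        expr, annots, truth = synth.gen_mirna_arrays(cfg)
        fit = md.fit_expression_model(expr, md.build_design(annots))
        resp = md.condition_responses(fit, annots)
        b_q = fit.coefficients["x_Q"].to_numpy()
        b_s = fit.coefficients["x_S"].to_numpy()
        assert np.allclose(resp.ss_response, b_q + b_s, atol=1e-8)
        assert np.allclose(resp.ci_response, b_q, atol=1e-8)

    def test_recomputation_oracle(self, rng):
        annots = _nine_sample_annotations()
        design = md.build_design(annots)
        vals = rng.normal(size=(6, 9))
        expr = ExpressionMatrix(vals, [f"f{i}" for i in range(6)],
                                [a.sample_id for a in annots])
        fit = md.fit_expression_model(expr, design)
        resp = md.condition_responses(fit, annots)
        cond = {a.sample_id: a.condition for a in annots}
        ss_cols = [j for j, s in enumerate(design.sample_ids)
                   if cond[s] == "serum_starved"]
        ci_cols = [j for j, s in enumerate(design.sample_ids)
                   if cond[s] == "contact_inhibited"]
        for i in range(6):
            ss_exp = (fit.coefficients.iloc[i]["x_Q"]
                      + fit.coefficients.iloc[i]["x_S"]
                      + np.mean([fit.residuals[i, j] for j in ss_cols]))
            ci_exp = (fit.coefficients.iloc[i]["x_Q"]
                      + np.mean([fit.residuals[i, j] for j in ci_cols]))
            assert resp.ss_response[i] == pytest.approx(ss_exp)
            assert resp.ci_response[i] == pytest.approx(ci_exp)


class TestQuiescenceSignature:
    # the 9-array design leaves <= 4 residual df, so recovery at stringent
    # FDR needs the 5-isolate variant (15 arrays)
    RECOVERY = dict(frac_quiescence_responsive=0.5, effect_size_log2=1.5,
                    noise_sd=0.3, n_isolates=5, n_mirnas=150)

    def test_planted_truth_recovery(self):
        sens, fdr = [], []
        for seed in range(20):
            cfg = synth.SyntheticConfig(seed=seed, **self.RECOVERY)
            expr, annots, truth = synth.gen_mirna_arrays(cfg)
            sig = md.quiescence_signature(expr, annots, q=0.01,
                                          n_permutations=150, seed=seed,
                                          input_scale="log2")
            called = set(sig.table.loc[sig.table["significant"], "feature_id"])
            truth_set = set(truth.responsive_mirnas)
            sens.append(len(called & truth_set) / len(truth_set))
            fdr.append((len(called) - len(called & truth_set)) / max(len(called), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 2 * 0.01

    def test_ss_ci_concordance(self):
        # effects planted identically in both quiescence conditions
        cfg = synth.SyntheticConfig(seed=9, **self.RECOVERY)
        expr, annots, _ = synth.gen_mirna_arrays(cfg)
        sig = md.quiescence_signature(expr, annots, q=0.01, n_permutations=150,
                                      seed=9, input_scale="log2")
        assert sig.pearson_r > 0.9

    def test_stringency_kills_tiny_effects(self):
        cfg = synth.SyntheticConfig(seed=10, n_mirnas=100,
                                    effect_size_log2=0.05, noise_sd=0.3)
        expr, annots, _ = synth.gen_mirna_arrays(cfg)
        sig = md.quiescence_signature(expr, annots, q=1e-9, n_permutations=100,
                                      seed=10, input_scale="log2")
        assert sig.n_significant <= 2

    def test_sorted_by_abs_mean_change(self):
        cfg = synth.SyntheticConfig(seed=11, n_mirnas=60)
        expr, annots, _ = synth.gen_mirna_arrays(cfg)
        sig = md.quiescence_signature(expr, annots, n_permutations=100, seed=11,
                                      input_scale="log2")
        mags = sig.table["mean_log2_change"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()


class TestSurrogateValue:
    def test_including_surrogate_reduces_residual_variance(self):
        cfg = synth.SyntheticConfig(seed=12, n_mirnas=120, noise_sd=0.2,
                                    surrogate_effect_sd=0.8)
        expr, annots, truth = synth.gen_mirna_arrays(cfg)
        base = md.build_design(annots)
        fit_without = md.fit_expression_model(expr, base)
        aug = base.with_surrogates(truth.surrogate_vector.reshape(-1, 1))
        fit_with = md.fit_expression_model(expr, aug)
        rv_without = (fit_without.residuals**2).sum(axis=1)
        rv_with = (fit_with.residuals**2).sum(axis=1)
        # features with strong planted surrogate loadings gain the most
        assert (rv_with <= rv_without + 1e-9).all()
        assert rv_with.sum() < 0.8 * rv_without.sum()
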