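import subprocess

import numpy as np
import pandas as pd
import pytest

from colonytrack import inference as inf
from colonytrack._lmm import poisson_glmm_fit


def metric_level_data(rng, n_plots=8, per_plot=9, beta_post=0.0, beta_pre=0.0,
                      beta_inter=0.0, noise=0.3):
    """Per-chick covariate/response table built directly at the metric level
    (no track simulation), for fast model checks."""
    n = n_plots * per_plot
    plots = np.repeat([f"P{k}" for k in range(n_plots)], per_plot)
    pre = rng.uniform(2, 6, n)
    post = rng.uniform(2, 6, n)
    sexm = rng.binomial(1, 0.5, n).astype(float)
    age = rng.integers(15, 26, n).astype(float)
    tarsus = 30 + 1.5 * age + rng.normal(0, 1.5, n)
    inter = (pre - pre.mean()) * (post - post.mean())
    lin = 1.0 + beta_pre * pre + beta_post * post + beta_inter * inter
    activity = (lin + rng.normal(0, noise, n)) ** 2
    strength = np.exp(lin + rng.normal(0, noise, n)).round().astype(int) + 1
    degree = rng.poisson(np.exp(0.5 + 0.2 * beta_post * (post - post.mean())))
    return pd.DataFrame(
        {
            "chick_id": [f"c{i}" for i in range(n)],
            "plot_id": plots,
            "nest_origin": [f"NO{i}" for i in range(n)],
            "nest_foster": [f"N{i // 2}" for i in range(n)],
            "sibling_group": [f"S{i // 2}" for i in range(n)],
            "sex": np.where(sexm > 0, "M", "F"),
            "age_days": age,
            "tarsus_mm": tarsus,
            "mass_g": 600.0,
            "nn3_prenatal_m": pre,
            "nn3_postnatal_m": post,
            "nn3_postnatal_tracked_m": post + 0.5,
            "near_fence": rng.binomial(1, 0.15, n).astype(bool),
            "movement_activity": activity,
            "area_m2": activity * 10,
            "degree": degree,
            "strength": strength,
            "sibling_events": 0,
        }
    )


def prep(df):
    cols_m = ["chick_id", "movement_activity", "area_m2", "degree", "strength"]
    cols_ch = ["chick_id", "nest_origin", "nest_foster", "sibling_group", "sex",
               "age_days", "tarsus_mm", "mass_g", "plot_id"]
    cols_cov = ["chick_id", "nn3_prenatal_m", "nn3_postnatal_m",
                "nn3_postnatal_tracked_m", "near_fence"]
    return inf.prepare_model_data(df[cols_m], df[cols_ch], df[cols_cov])


class TestBodySize:
    def test_chicks_on_regression_line_have_zero_residuals(self):
        chicks = pd.DataFrame({"age_days": [15.0, 20.0, 25.0],
                               "tarsus_mm": [52.5, 60.0, 67.5]})
        assert inf.body_size_index(chicks).to_numpy() == pytest.approx([0.0] * 3, abs=1e-9)

    def test_same_age_difference_preserved(self):
        chicks = pd.DataFrame({"age_days": [18.0, 18.0, 22.0, 22.0],
                               "tarsus_mm": [55.0, 58.0, 60.0, 61.0]})
        r = inf.body_size_index(chicks).to_numpy()
        assert r[1] - r[0] == pytest.approx(3.0)

    def test_residuals_sum_to_zero(self, rng):
        chicks = pd.DataFrame({"age_days": rng.integers(15, 26, 30).astype(float),
                               "tarsus_mm": rng.normal(58, 3, 30)})
        assert inf.body_size_index(chicks).sum() == pytest.approx(0.0, abs=1e-8)

    def test_zero_age_variance_rejected(self):
        chicks = pd.DataFrame({"age_days": [20.0] * 5, "tarsus_mm": [55.0] * 5})
        with pytest.raises(ValueError, match="age"):
            inf.body_size_index(chicks)


class TestFitModel:
    def test_exact_loglinear_strength_recovered(self, rng):
        df = metric_level_data(rng, noise=1e-8, beta_post=0.4)
        df["strength"] = np.exp(
            1.0 + 0.4 * df["nn3_postnatal_tracked_m"]
        )  # exact on the log scale
        fit = inf.fit_model(inf.STANDARD_MODELS["strength"], prep(df))
        assert fit.coef("nn3_post_tracked") == pytest.approx(0.4, abs=1e-6)
        for term in ("sex", "size", "nn3_pre", "fence"):
            assert abs(fit.coef(term)) < 1e-6

    def test_null_data_gives_small_coefficients(self, rng):
        df = metric_level_data(rng, per_plot=20)
        fit = inf.fit_model(inf.STANDARD_MODELS["strength"], prep(df))
        assert abs(fit.coef("nn3_post_tracked")) < 0.1
        assert fit.p("nn3_post_tracked") > 0.001

    def test_planted_slope_recovered_on_average(self):
        # parameter-recovery oracle: mean estimate over seeds ~ planted slope
        est = []
        for k in range(50):
            rng = np.random.default_rng(900 + k)
            df = metric_level_data(rng, beta_post=0.15, noise=0.2)
            fit = inf.fit_model(inf.STANDARD_MODELS["movement"], prep(df))
            est.append(fit.coef("nn3_post"))
        assert np.mean(est) == pytest.approx(0.15, abs=0.02)

    def test_gaussian_plot_model_matches_statsmodels(self, rng):
        from statsmodels.regression.mixed_linear_model import MixedLM

        df = metric_level_data(rng, beta_post=0.2)
        data = prep(df)
        fit = inf.fit_model(inf.STANDARD_MODELS["strength"], data)
        X = np.column_stack(
            [np.ones(len(data)), data["sex_male"], data["body_size"],
             data["nn3_prenatal_m"], data["nn3_postnatal_tracked_m"], data["near_fence"]]
        )
        m = MixedLM(np.log(data["strength"].to_numpy(dtype=float)), X,
                    data["plot_id"].to_numpy()).fit(reml=True)
        got = fit.terms["coef"].to_numpy()
        assert got == pytest.approx(m.fe_params[1:], abs=1e-4)

    def test_poisson_glmm_matches_lme4_glmer(self, rng, tmp_path):
        n_g, per = 8, 9
        groups = np.repeat(np.arange(n_g), per)
        x = rng.normal(size=n_g * per)
        b = rng.normal(0, 0.5, n_g)
        y = rng.poisson(np.exp(0.5 + 0.3 * x + b[groups]))
        X = np.column_stack([np.ones(len(y)), x])
        fit = poisson_glmm_fit(y, X, groups)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "g": groups}).to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f"suppressMessages(library(lme4));"
             f"d<-read.csv('{csv}');"
             f"m<-glmer(y~x+(1|g),data=d,family=poisson,nAGQ=25);"
             f"cat(fixef(m),sqrt(as.numeric(VarCorr(m)$g)),sep=',')"],
            capture_output=True, text=True, timeout=120,
        )
        assert r.returncode == 0, r.stderr
        ref = np.array([float(v) for v in r.stdout.strip().split(",")])
        assert fit.beta == pytest.approx(ref[:2], abs=1e-3)
        assert fit.tau == pytest.approx(ref[2], abs=1e-3)


class TestInteractionRule:
    def test_zero_interaction_dropped(self, rng):
        df = metric_level_data(rng, beta_post=0.2, beta_inter=0.0)
        spec, fit = inf.drop_nonsig_interaction(inf.STANDARD_MODELS["movement"], prep(df))
        assert "nn3_pre_x_post" not in spec.fixed_terms

    def test_strong_interaction_kept(self, rng):
        df = metric_level_data(rng, beta_post=0.2, beta_inter=0.3, noise=0.1)
        spec, fit = inf.drop_nonsig_interaction(inf.STANDARD_MODELS["movement"], prep(df))
        assert "nn3_pre_x_post" in spec.fixed_terms

    def test_alpha_one_keeps_full_model(self, rng):
        df = metric_level_data(rng)
        spec, _ = inf.drop_nonsig_interaction(inf.STANDARD_MODELS["movement"], prep(df),
                                              alpha=1.0 + 1e-9)
        assert "nn3_pre_x_post" in spec.fixed_terms


class TestPermutation:
    def test_constant_response_degenerate_null(self, rng):
        df = metric_level_data(rng)
        df["strength"] = 7
        res = inf.node_permutation_test(inf.STANDARD_MODELS["strength"], prep(df),
                                        n_perm=99, seed=1)
        for r in res.values():
            assert r.p_two == pytest.approx(1.0)

    def test_monotone_response_attains_minimum_p(self, rng):
        n = 12
        df = metric_level_data(rng, n_plots=1, per_plot=n)
        df["nn3_postnatal_tracked_m"] = np.arange(n, dtype=float)
        df["strength"] = np.exp(0.5 * np.arange(n))  # strictly monotone in covariate
        spec = inf.ModelSpec("strength", "gaussian", ("nn3_post_tracked",), "plot")
        res = inf.node_permutation_test(spec, prep(df), n_perm=999, seed=3)
        assert res["nn3_post_tracked"].p_two == pytest.approx(1.0 / 1000.0)
        assert res["nn3_post_tracked"].outside_central_95

    def test_null_covariate_type_one_error(self):
        # quick calibration check at the metric level; the full track-level
        # rate check lives in the acceptance suite
        rejections = 0
        n_rep = 150
        for k in range(n_rep):
            rng = np.random.default_rng(3000 + k)
            df = metric_level_data(rng)
            spec = inf.STANDARD_MODELS["strength"]
            res = inf.node_permutation_test(spec, prep(df), n_perm=400, seed=k,
                                            terms=("nn3_post_tracked",))
            rejections += res["nn3_post_tracked"].p_two < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_flag_agrees_with_p_value_mostly(self):
        agree, total = 0, 0
        for k in range(40):
            rng = np.random.default_rng(7000 + k)
            df = metric_level_data(rng)
            res = inf.node_permutation_test(inf.STANDARD_MODELS["strength"], prep(df),
                                            n_perm=400, seed=k)
            for r in res.values():
                agree += (r.p_two < 0.05) == r.outside_central_95
                total += 1
        assert agree / total >= 0.90

    def test_plot_constant_covariate_coefficient_unchanged(self, rng):
        # permuting within plots cannot move the coefficient of a covariate
        # that is constant within each plot
        df = metric_level_data(rng)
        plot_val = {f"P{k}": float(k) for k in range(8)}
        df["nn3_postnatal_tracked_m"] = df["plot_id"].map(plot_val)
        spec = inf.ModelSpec("strength", "gaussian", ("nn3_post_tracked",), "plot")
        res = inf.node_permutation_test(spec, prep(df), n_perm=60, seed=5)
        r = res["nn3_post_tracked"]
        assert np.allclose(r.null_coefs, r.observed_coef, atol=1e-6)


class TestSiblingCorrelation:
    def chicks_with_pairs(self, n_pairs):
        rows = []
        for g in range(n_pairs):
            for j in range(2):
                rows.append({"chick_id": f"c{g}_{j}", "sibling_group": f"S{g}",
                             "nest_foster": f"N{g}"})
        return pd.DataFrame(rows)

    def test_identical_pairs_r_one(self):
        chicks = self.chicks_with_pairs(5)
        vals = pd.Series({f"c{g}_{j}": float(g) for g in range(5) for j in range(2)})
        sc = inf.sibling_correlation(vals, chicks)
        assert sc.r == pytest.approx(1.0)

    def test_independent_values_near_zero(self, rng):
        chicks = self.chicks_with_pairs(200)
        vals = pd.Series({c: rng.normal() for c in chicks["chick_id"]})
        sc = inf.sibling_correlation(vals, chicks)
        assert abs(sc.r) < 0.15

    def test_shared_component_recovered(self, rng):
        chicks = self.chicks_with_pairs(300)
        target = 0.9
        vals = {}
        for g in range(300):
            shared = rng.normal()
            for j in range(2):
                vals[f"c{g}_{j}"] = np.sqrt(target) * shared + np.sqrt(1 - target) * rng.normal()
        sc = inf.sibling_correlation(pd.Series(vals), chicks)
        assert sc.r == pytest.approx(target, abs=0.06)
        assert sc.r_symmetric == pytest.approx(sc.r, abs=0.05)

    def test_too_few_pairs_rejected(self, rng):
        chicks = self.chicks_with_pairs(2)
        vals = pd.Series({c: rng.normal() for c in chicks["chick_id"]})
        with pytest.raises(ValueError, match="pairs"):
            inf.sibling_correlation(vals, chicks)


class TestDensityClasses:
    def test_separated_classes_highly_significant(self, rng):
        n = 40
        plots = np.repeat([f"P{k}" for k in range(8)], 5)
        cls = pd.Series(np.where(np.arange(n) % 10 < 5, "HD", "LD"))
        nn = pd.Series(np.where(cls == "HD", 3.0, 5.0) + rng.normal(0, 0.3, n))
        chi2, p = inf.compare_density_classes(nn, cls, pd.Series(plots))
        assert p < 0.001

    def test_identical_distributions_small_statistic(self):
        stats = []
        for k in range(30):
            rng = np.random.default_rng(100 + k)
            plots = pd.Series(np.repeat([f"P{j}" for j in range(8)], 5))
            cls = pd.Series(["HD", "LD"] * 20)
            nn = pd.Series(rng.normal(4.0, 1.0, 40))
            chi2, p = inf.compare_density_classes(nn, cls, plots)
            stats.append(p)
        assert np.mean(np.array(stats) < 0.05) < 0.2

    def test_missing_class_rejected(self, rng):
        plots = pd.Series(["P1"] * 6)
        cls = pd.Series(["HD"] * 6)
        nn = pd.Series(rng.normal(3, 0.5, 6))
        with pytest.raises(ValueError, match="class"):
            inf.compare_density_classes(nn, cls, plots)
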