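"""EWAS models, mixed-model oracle checks, deconvolution, prior enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmeth import ewas, synth
from conftest import toy_beta


def _cohort_design(cohort):
    per_ind = cohort.samples[cohort.samples.tissue == "blood"].set_index(
        "individual")
    cov = per_ind[["age", "batch"]].copy()
    cov["obesity"] = ewas.encode_binary(per_ind["group"], reference="lean")
    return cov


def _normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestCellComposition:
    def test_pure_sample_recovers_unit_fraction(self):
        cfg = synth.SimConfig(n_individuals=4, noise_sd=0.0, seed=2)
        ref, _, _ = synth.generate_reference_profiles(cfg, 3)
        beta = ref[["cd4t"]].rename(columns={"cd4t": "sample1"})
        fr, resid = ewas.estimate_cell_composition(beta, ref)
        np.testing.assert_allclose(fr.loc["sample1", "cd4t"], 1.0, atol=1e-8)
        assert fr.loc["sample1"].drop("cd4t").abs().max() < 1e-8
        assert resid.iloc[0] < 1e-10

    def test_exact_half_half_mixture(self):
        cfg = synth.SimConfig(n_individuals=4, noise_sd=0.0, seed=2)
        ref, _, _ = synth.generate_reference_profiles(cfg, 2)
        mix = 0.5 * ref.iloc[:, 0] + 0.5 * ref.iloc[:, 1]
        beta = mix.to_frame("s")
        fr, _ = ewas.estimate_cell_composition(beta, ref)
        np.testing.assert_allclose(fr.to_numpy(), [[0.5, 0.5]], atol=1e-8)

    def test_round_trip_recovery_six_cell_types(self):
        cfg = synth.SimConfig(n_individuals=40, noise_sd=0.02, seed=19)
        ref, mixed, truth = synth.generate_reference_profiles(cfg, 6)
        est, _ = ewas.estimate_cell_composition(mixed, ref)
        mae = np.abs(est.to_numpy() - truth.to_numpy()).mean()
        assert mae < 0.05

    def test_rank_deficient_reference_errors(self):
        ref = pd.DataFrame({"a": [0.1, 0.9, 0.5], "b": [0.1, 0.9, 0.5]},
                           index=["p0", "p1", "p2"])
        beta = toy_beta([[0.2], [0.8], [0.5]], samples=["s"])
        with pytest.raises(ValueError, match="rank"):
            ewas.estimate_cell_composition(beta, ref)


class TestSingleTissue:
    def test_zero_noise_null_effect(self):
        cfg = synth.SimConfig(n_probes=50, n_individuals=12, n_obese=4,
                              noise_sd=0.0, batch_effect_sd=0.0, seed=3,
                              class_fractions={})
        c = synth.generate_cohort(cfg)
        res = ewas.ewas_single_tissue(c.blood,
                                      ewas.DesignSpec(_cohort_design(c)))
        np.testing.assert_allclose(res["effect"], 0, atol=1e-12)

    def test_planted_effect_recovered(self):
        cfg = synth.SimConfig(n_probes=200, n_individuals=43, n_obese=22,
                              noise_sd=0.01, seed=5,
                              class_fractions={"obesity_associated": 1.0})
        c = synth.generate_cohort(cfg)
        res = ewas.ewas_single_tissue(c.blood,
                                      ewas.DesignSpec(_cohort_design(c)))
        assert 0.015 < res["effect"].mean() < 0.025
        # sign convention: positive = higher methylation in obese
        assert (res["effect"] > 0).mean() > 0.95

    def test_matches_normal_equations_oracle(self, rng):
        cov = pd.DataFrame({
            "obesity": [0, 0, 0, 1, 1, 1],
            "age": [30.0, 35, 40, 29, 36, 44],
        }, index=[f"i{k}" for k in range(6)])
        beta = toy_beta(rng.uniform(0.2, 0.8, (5, 6)),
                        samples=list(cov.index))
        res = ewas.ewas_single_tissue(beta, ewas.DesignSpec(cov, "obesity",
                                                            categorical=()))
        X = np.column_stack([np.ones(6), cov["obesity"], cov["age"]])
        for i in range(5):
            coef = _normal_equations(X, beta.iloc[i].to_numpy())
            assert res["effect"].iloc[i] == pytest.approx(coef[1], abs=1e-10)

    def test_collinear_design_names_columns(self, rng):
        cov = pd.DataFrame({
            "obesity": [0, 0, 1, 1, 1, 0],
            "age": [30.0, 35, 40, 29, 36, 44],
        }, index=[f"i{k}" for k in range(6)])
        cov["age_copy"] = cov["age"]
        beta = toy_beta(rng.uniform(0, 1, (2, 6)), samples=list(cov.index))
        with pytest.raises(ValueError, match="age"):
            ewas.ewas_single_tissue(beta, ewas.DesignSpec(cov, "obesity",
                                                          categorical=()))


class TestMixedModel:
    def test_matches_statsmodels_mixedlm_oracle(self):
        cfg = synth.SimConfig(n_probes=8, n_individuals=40, n_obese=12,
                              noise_sd=0.01, individual_sd=0.01, seed=7,
                              class_fractions={"obesity_associated": 0.5})
        c = synth.generate_cohort(cfg)
        d = ewas.DesignSpec(_cohort_design(c))
        fast = ewas.ewas_mixed(c.blood, c.sperm, d)
        oracle = ewas.ewas_mixed(c.blood, c.sperm, d, method="mixedlm")
        np.testing.assert_allclose(fast["effect"], oracle["effect"],
                                   atol=1e-8)
        np.testing.assert_allclose(fast["se"], oracle["se"], rtol=0.05)
        np.testing.assert_allclose(fast["tau2"], oracle["tau2"], atol=1e-5)

    def test_zero_random_intercept_equals_pooled_ols(self):
        cfg = synth.SimConfig(n_probes=30, n_individuals=20, n_obese=6,
                              noise_sd=0.01, individual_sd=0.0,
                              polarised=False, seed=9, class_fractions={})
        c = synth.generate_cohort(cfg)
        cov = _cohort_design(c)
        res = ewas.ewas_mixed(c.blood, c.sperm, ewas.DesignSpec(cov))
        # pooled OLS with a tissue indicator
        X, names = ewas.build_design_matrix(ewas.DesignSpec(cov))
        n = X.shape[0]
        Xl = np.vstack([np.hstack([X, np.zeros((n, 1))]),
                        np.hstack([X, np.ones((n, 1))])])
        j = names.index("obesity")
        for i in range(10):
            y = np.concatenate([c.blood.iloc[i], c.sperm.iloc[i]])
            coef = _normal_equations(Xl, y)
            assert res["effect"].iloc[i] == pytest.approx(coef[j], abs=1e-6)

    def test_collapses_to_single_tissue_ols_with_one_observation(self):
        cfg = synth.SimConfig(n_probes=20, n_individuals=15, n_obese=5,
                              seed=11, class_fractions={})
        c = synth.generate_cohort(cfg)
        d = ewas.DesignSpec(_cohort_design(c))
        collapsed = ewas.ewas_mixed(c.blood, None, d)
        ols = ewas.ewas_single_tissue(c.blood, d)
        np.testing.assert_allclose(collapsed["effect"], ols["effect"])
        np.testing.assert_allclose(collapsed["p"], ols["p"])

    def test_planted_cross_tissue_effect_power_at_study_size(self):
        """0.02 planted shift, 68 lean + 22 obese, noise 0.01, intercept
        0.01: the mixed model recovers the effect and reaches its analytic
        power (~0.77 at the array-wide threshold with Satterthwaite df)."""
        cfg = synth.SimConfig(n_probes=400, n_individuals=90, n_obese=22,
                              noise_sd=0.01, individual_sd=0.01, seed=13,
                              class_fractions={"obesity_associated": 1.0})
        c = synth.generate_cohort(cfg)
        res = ewas.ewas_mixed(c.blood, c.sperm,
                              ewas.DesignSpec(_cohort_design(c)))
        assert 0.015 < res["effect"].mean() < 0.025
        power = (res["p"] < 9e-8).mean()
        # analytic power 0.77; allow 3 binomial SDs of Monte-Carlo noise
        assert abs(power - 0.77) < 3 * np.sqrt(0.77 * 0.23 / 400)


class TestInteractionScan:
    def _toy(self, rng, slope_diff=0.0, n=24, noise=0.01):
        obesity = np.array([0] * (n // 2) + [1] * (n // 2), dtype=float)
        cov = pd.DataFrame({
            "obesity": obesity,
            "age": rng.uniform(25, 50, n).round(1),
        }, index=[f"i{k}" for k in range(n)])
        sperm = rng.uniform(0.2, 0.8, (3, n))
        slope = 0.3 + slope_diff * obesity
        blood = 0.1 + slope * sperm + rng.normal(0, noise, (3, n))
        return (toy_beta(blood, list(cov.index)),
                toy_beta(sperm, list(cov.index)), cov)

    def test_equal_slopes_null_interaction(self, rng):
        blood, sperm, cov = self._toy(rng, slope_diff=0.0, noise=0.0)
        res = ewas.interaction_scan(blood, sperm, cov, categorical=(),
                                    loo_diagnostic=False)
        np.testing.assert_allclose(res["effect"], 0, atol=1e-10)

    def test_planted_slope_difference_recovered(self, rng):
        blood, sperm, cov = self._toy(rng, slope_diff=0.5)
        res = ewas.interaction_scan(blood, sperm, cov, categorical=())
        assert res["effect"].between(0.4, 0.6).all()

    def test_matches_normal_equations_on_toy_pairs(self, rng):
        blood, sperm, cov = self._toy(rng, slope_diff=0.2, n=8)
        res = ewas.interaction_scan(blood, sperm, cov, categorical=(),
                                    loo_diagnostic=False)
        for i in range(3):
            x = sperm.iloc[i].to_numpy()
            g = cov["obesity"].to_numpy()
            X = np.column_stack([np.ones(8), g, cov["age"], x, x * g])
            coef = _normal_equations(X, blood.iloc[i].to_numpy())
            assert res["effect"].iloc[i] == pytest.approx(coef[-1], abs=1e-10)

    def test_loo_diagnostic_matches_explicit_refits(self, rng):
        blood, sperm, cov = self._toy(rng, slope_diff=0.3, n=16)
        res = ewas.interaction_scan(blood, sperm, cov, categorical=())
        i = 0
        x = sperm.iloc[i].to_numpy()
        g = cov["obesity"].to_numpy()
        X = np.column_stack([np.ones(16), g, cov["age"], x, x * g])
        y = blood.iloc[i].to_numpy()

        def t_int(Xs, ys):
            coef = _normal_equations(Xs, ys)
            e = ys - Xs @ coef
            s2 = (e @ e) / (len(ys) - Xs.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(Xs.T @ Xs)[-1, -1])
            return coef[-1] / se

        t_full = t_int(X, y)
        changes = [abs(t_full - t_int(np.delete(X, k, 0), np.delete(y, k)))
                   for k in range(16)]
        assert res["loo_max_t_change"].iloc[i] == pytest.approx(
            max(changes), rel=1e-6)

    def test_outlier_driven_interaction_has_large_diagnostic(self, rng):
        blood, sperm, cov = self._toy(rng, slope_diff=0.0)
        # one obese individual displaced in both tissues fakes an interaction
        sperm.iloc[:, -1] = 0.95
        blood.iloc[:, -1] = 0.95
        res = ewas.interaction_scan(blood, sperm, cov, categorical=())
        null = self._toy(rng, slope_diff=0.0)
        res_null = ewas.interaction_scan(null[0], null[1], null[2],
                                         categorical=())
        assert res["loo_max_t_change"].mean() > \
            5 * res_null["loo_max_t_change"].mean()

    def test_too_few_pairs_na(self, rng):
        blood, sperm, cov = self._toy(rng, n=8)
        blood.iloc[0, :5] = np.nan
        res = ewas.interaction_scan(blood, sperm, cov, categorical=())
        assert np.isnan(res["p"].iloc[0])


class TestPriorComparison:
    def test_minimum_rank_sum_matches_enumeration(self):
        pvals = pd.Series(np.linspace(0.01, 0.99, 10),
                          index=[f"p{i}" for i in range(10)])
        prior = ["p0", "p1", "p2"]  # the 3 smallest p-values
        res = ewas.prior_probe_enrichment(pvals, prior)
        # exact two-sided p by enumerating all C(10,3) assignments of the
        # prior ranks; the observed rank sum is the minimum possible
        from itertools import combinations
        obs = sum([1, 2, 3])
        sums = [sum(cmb) for cmb in combinations(range(1, 11), 3)]
        more_extreme = np.mean([s <= obs for s in sums])
        exact_two_sided = 2 * more_extreme
        assert res["p"] == pytest.approx(exact_two_sided, rel=1e-9)

    def test_null_prior_set_gives_uniform_p(self, rng):
        ps = []
        idx = [f"p{i}" for i in range(60)]
        for _ in range(500):
            pvals = pd.Series(rng.uniform(0, 1, 60), index=idx)
            prior = rng.choice(idx, 10, replace=False)
            ps.append(ewas.prior_probe_enrichment(pvals, prior)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monotone_transform_gives_unit_spearman(self, rng):
        idx = [f"p{i}" for i in range(20)]
        local = pd.Series(rng.normal(0, 1, 20), index=idx)
        prior = pd.Series(np.exp(2 * local) + 3, index=idx)
        rho, _ = ewas.effect_concordance(local, prior)
        assert rho == pytest.approx(1.0)

    def test_small_intersection_errors(self):
        pvals = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            ewas.prior_probe_enrichment(pvals, ["a"])
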