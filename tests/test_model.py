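"""Hierarchical model: design construction, sampler correctness against
independent oracles, convergence diagnostics and posterior predictive checks."""

import copy
import dataclasses

import numpy as np
import pandas as pd
import pytest

import cricketsize as cs
from cricketsize.design import Site, StudyDesign, TraitEffects
from cricketsize.results import TraitModelResults

from conftest import FAST, MEDIUM


class TestBuildDesign:
    def test_pooled_column_count(self, records):
        d = cs.build_design(records, "femur", "pooled")
        assert d.p == 9  # intercept + 4 main effects + 4 interactions
        assert d.names[0] == "intercept"

    def test_sex_specific_columns(self, records):
        d = cs.build_design(records, "ovipositor", "female_only")
        assert d.names == ["intercept", "isolation", "origin", "year",
                           "isolation:origin"]
        assert set(d.rows["sex"]) == {"female"}

    def test_three_way_is_product_of_parents(self, records):
        d = cs.build_design(records, "femur", "pooled")
        iso = d.X[:, d.names.index("isolation")]
        org = d.X[:, d.names.index("origin")]
        sex = d.X[:, d.names.index("sex")]
        np.testing.assert_array_equal(
            d.X[:, d.names.index("isolation:origin:sex")], iso * org * sex)

    def test_missing_trait_rows_dropped_and_counted(self, records):
        df = records.copy()
        df.loc[df.index[:5], "wing"] = np.nan
        d = cs.build_design(df, "wing", "pooled")
        assert d.n_dropped == 5
        assert d.n == len(df) - 5

    def test_genital_trait_requires_matching_sex_mode(self, records):
        with pytest.raises(ValueError, match="male"):
            cs.build_design(records, "cerci", "pooled")
        with pytest.raises(ValueError):
            cs.build_design(records, "ovipositor", "male_only")

    def test_unknown_factor_level(self, records):
        df = records.copy()
        df.loc[df.index[0], "origin"] = "greenhouse"
        with pytest.raises(ValueError, match="origin"):
            cs.build_design(df, "femur", "pooled")

    def test_single_isolation_class_is_singular(self, digital_records):
        sub = digital_records[digital_records["isolation"] == "continuous"]
        with pytest.raises(ValueError, match="singular"):
            cs.TraitModel(sub, "femur")


class TestSamplerBasics:
    def test_seeded_reproducibility(self, digital_records):
        a = cs.TraitModel(digital_records, "femur").fit(seed=3, **FAST)
        b = cs.TraitModel(digital_records, "femur").fit(seed=3, **FAST)
        for key in a.posterior:
            np.testing.assert_array_equal(a.posterior[key], b.posterior[key])

    def test_calliper_rows_without_conversion_rejected(self, records):
        with pytest.raises(ValueError, match="conversion"):
            cs.TraitModel(records, "femur")

    def test_zero_offset_conversion_equals_no_conversion(self, digital_records):
        # a (0, 0) conversion leaves the observation layer untouched, so the
        # draws must be identical, not merely close
        df = digital_records.copy()
        df.loc[(df.origin == "field") & (df.year == 2008), "instrument"] = "calliper"
        with_conv = cs.TraitModel(
            df, "femur", conversion=cs.identity_conversion("femur")
        ).fit(seed=4, **FAST)
        without = cs.TraitModel(digital_records, "femur").fit(seed=4, **FAST)
        np.testing.assert_array_equal(with_conv.posterior["beta"],
                                      without.posterior["beta"])

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            cs.MCMCSettings(chains=0)
        with pytest.raises(ValueError):
            cs.MCMCSettings(burn_in=0)


class TestOracleEquivalence:
    def test_posterior_means_match_ols_without_site_or_instrument_error(self):
        """In the no-measurement-error, vanishing-site-variance, weak-prior
        limit the posterior mean must agree with ordinary least squares."""
        import statsmodels.api as sm

        design = StudyDesign(
            sites=[Site("C1", "continuous"), Site("C2", "continuous"),
                   Site("I1", "isolated"), Site("I2", "isolated")],
            counts={(s, o, x, y): 25
                    for s in ("C1", "C2", "I1", "I2")
                    for o in ("field", "laboratory")
                    for x in ("male", "female")
                    for y in (2008, 2010)},
            traits=("femur",), calliper_cells=frozenset())
        eff = {"femur": TraitEffects(intercept=13.0,
                                     betas={"isolation": 0.5, "origin": -0.5,
                                            "sex": 1.0, "year": 0.1},
                                     site_sd=0.0, residual_sd=0.7)}
        rec = cs.simulate_individuals(design, eff, seed=30)
        priors = cs.Priors(site_sd_scale=1e-4)  # pin site variance near zero
        res = cs.TraitModel(rec, "femur", priors=priors).fit(
            seed=31, chains=2, burn_in=1000, samples=3000)

        d = cs.build_design(rec, "femur", "pooled")
        ols = sm.OLS(d.y, d.X).fit()
        ess = res.ess()
        for k, term in enumerate(d.names):
            draws = res.posterior["beta"][:, :, k].reshape(-1)
            mcse = draws.std(ddof=1) / np.sqrt(ess[term])
            tol = max(2 * mcse, 2e-3)
            assert abs(draws.mean() - ols.params[k]) < tol, term

    def test_beta_recovery_within_three_posterior_sd(self, femur_fit,
                                                     study_effects):
        truth = study_effects["femur"]
        summ = femur_fit.summary()
        for term in ("isolation", "origin", "sex", "year", "isolation:sex",
                     "isolation:origin", "origin:sex", "isolation:origin:sex"):
            err = abs(summ.loc[term, "mean"] - truth.betas.get(term, 0.0))
            assert err < 3 * summ.loc[term, "sd"], term

    def test_group_precision_improves_with_sample_size(self):
        sds = []
        for n_cell, seed in ((4, 40), (15, 41), (60, 42)):
            design = StudyDesign(
                sites=[Site("C1", "continuous"), Site("C2", "continuous"),
                       Site("I1", "isolated"), Site("I2", "isolated")],
                counts={(s, o, "male", y): n_cell
                        for s in ("C1", "C2", "I1", "I2")
                        for o in ("field", "laboratory")
                        for y in (2008, 2010)},
                traits=("femur",), calliper_cells=frozenset())
            eff = {"femur": TraitEffects(intercept=13.0,
                                         betas={"isolation": 0.5},
                                         site_sd=0.05, residual_sd=0.7)}
            rec = cs.simulate_individuals(design, eff, seed=seed)
            res = cs.TraitModel(rec, "femur", sex_mode="male_only").fit(
                seed=seed, **FAST)
            g = res.predict_group("isolated", "field", year=2010)
            sds.append(g.sd)
        assert sds[0] > sds[1] > sds[2]


class TestDiagnostics:
    def _dup_chain(self, res, shift=0.0):
        post = {k: np.stack([v[0], v[0] + shift]) for k, v in res.posterior.items()}
        return TraitModelResults(res.model, post, res.settings)

    def test_identical_chains_rhat_near_one(self, femur_fit):
        dup = self._dup_chain(femur_fit)
        assert (dup.rhat() < 1.01).all()

    def test_divergent_chains_flagged(self, femur_fit):
        bad = self._dup_chain(femur_fit, shift=10.0)
        report = bad.check_convergence()
        assert not report.passed
        assert (bad.rhat() > 1.1).all()

    def test_default_fit_converges(self, femur_fit):
        report = femur_fit.check_convergence()
        assert report.passed, report.flagged
        assert report.rhat.max() < 1.05

    def test_rhat_requires_two_chains(self, femur_fit):
        post = {k: v[:1] for k, v in femur_fit.posterior.items()}
        single = TraitModelResults(femur_fit.model, post, femur_fit.settings)
        with pytest.raises(ValueError, match="two chains"):
            single.rhat()

    def test_priors_flat_over_posterior_range(self, femur_fit):
        # the minimally-informative priors must be effectively constant over
        # the region the posterior occupies
        flatness = femur_fit.prior_flatness()
        assert (flatness > 0.99).all()

    def test_summary_layout(self, femur_fit):
        summ = femur_fit.summary()
        assert {"mean", "sd", "ci_2.5%", "ci_97.5%", "rhat", "ess_bulk"} <= set(
            summ.columns)
        assert "site_sd" in summ.index and "residual_sd" in summ.index
        assert summ.loc["residual_sd", "mean"] > 0


class TestPosteriorPredictive:
    def test_self_consistency(self, femur_fit):
        # data drawn from the very process the model assumes should not be
        # flagged by its own posterior predictive distribution
        for stat in ("mean", "cv"):
            ppc = femur_fit.posterior_predictive_check(stat, seed=0)
            assert 0.1 < ppc.bayes_p < 0.9, stat
            assert ppc.passed

    def test_shifted_data_fails_mean_check(self, femur_fit):
        shifted = copy.deepcopy(femur_fit.model)
        shifted._y_obs = shifted._y_obs + 10.0
        res = TraitModelResults(shifted, femur_fit.posterior,
                                femur_fit.settings)
        ppc = res.posterior_predictive_check("mean", seed=0)
        assert ppc.bayes_p < 0.01
        assert not ppc.passed

    def test_bayes_p_is_a_proportion(self, femur_fit):
        for stat in ("mean", "cv"):
            p = femur_fit.posterior_predictive_check(stat, seed=1).bayes_p
            assert 0.0 <= p <= 1.0

    def test_unknown_statistic(self, femur_fit):
        with pytest.raises(ValueError):
            femur_fit.posterior_predictive_check("median")
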