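"""Group predictions, paired differences and directional probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cricketsize as cs
from cricketsize import contrasts as ctr
from cricketsize.results import GroupPrediction

from conftest import FAST


class TestProbGreater:
    def test_all_positive(self):
        assert cs.prob_greater(np.full(10, 0.5)) == 1.0

    def test_symmetric_two_draws(self):
        assert cs.prob_greater(np.array([-1.0, 1.0])) == 0.5

    def test_zero_draws_not_counted(self):
        assert cs.prob_greater(np.array([0.0, 1.0])) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.prob_greater(np.array([]))

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1,
                    max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_probability_properties(self, draws):
        d = np.asarray(draws)
        p = cs.prob_greater(d)
        assert 0.0 <= p <= 1.0
        if not np.any(d == 0):
            assert p + cs.prob_greater(-d) == pytest.approx(1.0)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                    max_size=40),
           st.floats(-3, 3, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_difference_location_invariance_property(self, draws, shift):
        from cricketsize.results import GroupPrediction
        a = GroupPrediction({}, np.asarray(draws))
        b = GroupPrediction({}, np.asarray(draws)[::-1].copy())
        base = cs.difference(a, b)
        moved = cs.difference(GroupPrediction({}, a.draws + shift),
                              GroupPrediction({}, b.draws + shift))
        np.testing.assert_allclose(moved.draws, base.draws, atol=1e-9)

    def test_complementarity(self, femur_fit):
        a = femur_fit.predict_group("isolated", "field", sex="male")
        b = femur_fit.predict_group("continuous", "field", sex="male")
        d1, d2 = cs.difference(a, b), cs.difference(b, a)
        if not np.any(d1.draws == 0):
            assert d1.p_greater + d2.p_greater == pytest.approx(1.0)


class TestDifference:
    def test_self_difference_is_zero(self, femur_fit):
        a = femur_fit.predict_group("isolated", "laboratory", sex="male")
        d = cs.difference(a, a)
        assert d.diff_mean == 0.0 and d.diff_sd == 0.0

    def test_antisymmetry_drawwise(self, femur_fit):
        a = femur_fit.predict_group("isolated", "field", sex="female")
        b = femur_fit.predict_group("continuous", "field", sex="female")
        np.testing.assert_allclose(cs.difference(a, b).draws,
                                   -cs.difference(b, a).draws)

    def test_unpaired_draws_rejected(self, femur_fit):
        a = femur_fit.predict_group("isolated", "field", sex="male")
        b = GroupPrediction(label={}, draws=a.draws[:-1])
        with pytest.raises(ValueError, match="unpaired"):
            cs.difference(a, b)

    def test_location_invariance(self, femur_fit):
        a = femur_fit.predict_group("isolated", "field", sex="male")
        b = femur_fit.predict_group("continuous", "field", sex="male")
        shifted = cs.difference(
            GroupPrediction(a.label, a.draws + 3.7),
            GroupPrediction(b.label, b.draws + 3.7))
        base = cs.difference(a, b)
        assert shifted.diff_mean == pytest.approx(base.diff_mean)
        assert shifted.diff_sd == pytest.approx(base.diff_sd)
        assert shifted.p_greater == base.p_greater

    def test_paired_sd_bounded_by_sum(self, femur_fit):
        a = femur_fit.predict_group("isolated", "field", sex="male")
        b = femur_fit.predict_group("continuous", "field", sex="male")
        d = cs.difference(a, b)
        assert d.diff_sd <= a.sd + b.sd + 1e-12
        # and matches brute-force subtraction of the stored draws
        assert d.diff_sd == pytest.approx(np.std(a.draws - b.draws, ddof=1))


class TestPredictGroup:
    def test_matches_brute_force_linear_predictor(self, femur_fit):
        """The prediction draws must equal the draw-wise linear predictor
        assembled directly from the stored posterior arrays."""
        res = femur_fit
        g = res.predict_group("isolated", "laboratory", sex="female", year=2010)
        names = res.model.design.names
        total = res.n_chains * res.n_draws
        beta = res.posterior["beta"].reshape(total, -1)
        expected = (beta[:, names.index("intercept")]
                    + beta[:, names.index("isolation")]
                    + beta[:, names.index("origin")]
                    + beta[:, names.index("sex")]
                    + beta[:, names.index("year")]
                    + beta[:, names.index("isolation:sex")]
                    + beta[:, names.index("isolation:origin")]
                    + beta[:, names.index("origin:sex")]
                    + beta[:, names.index("isolation:origin:sex")])
        u = res.posterior["site_effect"].reshape(total, -1)
        codes = res.model.design.site_codes
        iso_cols = [codes.index(c) for c in ("ALA", "VAS")]
        expected = expected + u[:, iso_cols].mean(axis=1)
        np.testing.assert_allclose(g.draws, expected)

    def test_site_specific_uses_own_effect(self, femur_fit):
        pop = femur_fit.predict_group("isolated", "field", sex="male")
        ala = femur_fit.predict_group("isolated", "field", sex="male",
                                      site="ALA")
        vas = femur_fit.predict_group("isolated", "field", sex="male",
                                      site="VAS")
        np.testing.assert_allclose(pop.draws, 0.5 * (ala.draws + vas.draws))

    def test_unknown_levels_rejected(self, femur_fit):
        with pytest.raises(ValueError):
            femur_fit.predict_group("semi", "field", sex="male")
        with pytest.raises(ValueError):
            femur_fit.predict_group("isolated", "field", sex="male", site="XXX")
        with pytest.raises(ValueError, match="sex"):
            femur_fit.predict_group("isolated", "field")

    def test_year_mix_between_reference_years(self, femur_fit):
        ref08 = femur_fit.predict_group("isolated", "field", sex="male",
                                        year=2008)
        ref10 = femur_fit.predict_group("isolated", "field", sex="male",
                                        year=2010)
        mix = femur_fit.predict_group("isolated", "field", sex="male",
                                      year="mix")
        lo, hi = sorted([ref08.mean, ref10.mean])
        assert lo <= mix.mean <= hi


class TestGeneralContrast:
    def test_between_field_and_laboratory(self, femur_fit):
        fld = ctr.isolation_contrast(femur_fit, "field", sex="male")
        lab = ctr.isolation_contrast(femur_fit, "laboratory", sex="male")
        gen = ctr.general_contrast(femur_fit, sex="male")
        lo, hi = sorted([fld.diff_mean, lab.diff_mean])
        assert lo <= gen.diff_mean <= hi
        # equal-weight draw pooling, verified against the stored draws
        np.testing.assert_allclose(gen.draws, 0.5 * (fld.draws + lab.draws))


class TestNullData:
    def test_null_contrasts_near_half(self):
        """Without any group structure the directional probability must not
        show confident direction."""
        design = cs.default_study_design()
        effects = cs.null_effects()
        eff = {"femur": effects["femur"]}
        import dataclasses
        design = dataclasses.replace(design, traits=("femur",),
                                     calliper_cells=frozenset())
        # no between-site variance: the only signal is sampling noise
        eff["femur"] = dataclasses.replace(eff["femur"], site_sd=0.0)
        rec = cs.simulate_individuals(design, eff, seed=77)
        res = cs.TraitModel(rec, "femur").fit(seed=78, **FAST)
        for origin in ("field", "laboratory"):
            for sex in ("male", "female"):
                p = ctr.isolation_contrast(res, origin, sex=sex).p_greater
                assert 0.05 < p < 0.95, (origin, sex, p)


@pytest.fixture(scope="module")
def small_results(records, conversions):
    cfg = cs.PipelineConfig(traits=["femur", "cerci"], **FAST, seed=50)
    return cs.fit_all_traits(records, conversions, cfg)


class TestResultTables:
    def test_group_estimates_layout(self, small_results):
        tab = ctr.group_estimates_table(small_results)
        # femur: 2 sexes x 2 origins; cerci: 1 sex x 2 origins
        assert len(tab) == 6
        assert {"continuous_mean", "isolated_mean", "p_iso_gt_con"} <= set(
            tab.columns)
        assert tab["p_iso_gt_con"].between(0, 1).all()

    def test_differences_table_layout(self, small_results):
        tab = ctr.isolation_differences_table(small_results)
        assert len(tab) == 3
        for cond in ("field", "laboratory", "general"):
            assert f"{cond}_diff_mean" in tab.columns

    def test_site_table_layout(self, small_results):
        tab = ctr.site_estimates_table(small_results)
        # femur: 4 sites x 2 origins x 2 sexes; cerci: 4 x 2 x 1
        assert len(tab) == 24
        assert (tab["sd"] > 0).all()

    def test_make_results_tables_keys(self, small_results):
        tabs = ctr.make_results_tables(small_results)
        assert set(tabs) == {"group_estimates", "isolation_differences",
                             "site_estimates"}

    def test_forest_plot_returns_axis(self, small_results):
        import matplotlib
        matplotlib.use("Agg")
        ax = cs.plot_forest(small_results)
        assert ax.get_xlabel().startswith("isolated")
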