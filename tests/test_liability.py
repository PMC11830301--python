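"""Tetrachoric correlations, ACE/AE WLS, exclusive-trait ML rg, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from pmdd._bvn import bvn_sf
from pmdd.exceptions import ConfigError, DataError
from pmdd.liability import (AceLiabilityModel, GeneticCorrelationModel, LiabilityFit,
                            PairCrossTable, TetrachoricResult, bootstrap_fits,
                            compare_models, cross_table, percentile_ci,
                            rg_difference_test, tetrachoric)
from pmdd.registry import TraitSpec, simulate_pairs


def _table_from(p11, p1, p2, n=10_000):
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1 - p10 - p01 - p11
    return np.array([[p00, p01], [p10, p11]]) * n


class TestTetrachoric:
    def test_independence_gives_zero(self):
        t = _table_from(0.06, 0.2, 0.3)
        r = tetrachoric(t)
        assert r.rho == pytest.approx(0.0, abs=1e-9)

    def test_arcsine_closed_form(self):
        # z1 = z2 = 0 and p11 = 1/3:  P11 = 1/4 + arcsin(rho)/(2 pi) -> rho = 0.5
        t = _table_from(1 / 3, 0.5, 0.5)
        r = tetrachoric(t)
        assert r.rho == pytest.approx(0.5, abs=1e-9)
        assert r.z1 == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_against_exact_orthant(self):
        # generate p11 from the exact orthant probability and invert
        for rho in (-0.7, -0.2, 0.4, 0.85):
            for z1, z2 in ((-1.0, 0.5), (0.0, 2.0), (1.5, 1.5)):
                from scipy.special import ndtr
                p1, p2 = 1 - ndtr(z1), 1 - ndtr(z2)
                p11 = float(bvn_sf(z1, z2, rho))
                r = tetrachoric(_table_from(p11, p1, p2, n=1.0))
                assert r.rho == pytest.approx(rho, abs=1e-8)

    def test_zero_cell_returns_boundary_with_flag(self):
        t = np.array([[50.0, 20.0], [30.0, 0.0]])
        r = tetrachoric(t)
        assert r.boundary and r.rho == -1.0

    def test_empty_table_and_margin_errors(self):
        with pytest.raises(DataError, match="empty"):
            tetrachoric(np.zeros((2, 2)))
        with pytest.raises(DataError, match="margin"):
            tetrachoric(np.array([[10.0, 0.0], [10.0, 0.0]]))

    def test_prevalence_constraint_overrides_margins(self):
        t = _table_from(0.06, 0.2, 0.3)
        r = tetrachoric(t, prevalence_constraint=(0.2, 0.3))
        assert r.rho == pytest.approx(0.0, abs=1e-9)
        r2 = tetrachoric(t, prevalence_constraint=(0.15, 0.25))
        assert r2.rho != pytest.approx(0.0, abs=1e-3)

    def test_se_shrinks_with_n(self):
        r1 = tetrachoric(_table_from(0.1, 0.2, 0.3, n=1000))
        r2 = tetrachoric(_table_from(0.1, 0.2, 0.3, n=100_000))
        assert r2.se == pytest.approx(r1.se / 10, rel=1e-9)


class TestAceWls:
    @staticmethod
    def _tetra(rho, se=1.0):
        return TetrachoricResult(rho=rho, se=se, z1=2.0, z2=2.0, n=1e6)

    def test_two_equation_closed_form(self):
        # r_FS = 0.15, r_C = 0.0375, equal weights
        m = AceLiabilityModel({"full_sib": self._tetra(0.15),
                               "cousin": self._tetra(0.0375)})
        ae = m.fit("AE")
        assert ae.a2 == pytest.approx(0.30, abs=1e-12)
        assert ae.fit_statistic == pytest.approx(0.0, abs=1e-20)
        ace = m.fit("ACE")
        assert ace.a2 == pytest.approx(8 * 0.0375, abs=1e-9)   # a2 = 8 r_C
        assert ace.c2 == pytest.approx(0.15 - 4 * 0.0375, abs=1e-9)

    def test_zero_correlations_give_zero_a2(self):
        m = AceLiabilityModel({"full_sib": self._tetra(0.0),
                               "cousin": self._tetra(0.0)})
        assert m.fit("AE").a2 == pytest.approx(0.0, abs=1e-12)

    def test_model_consistent_input_zero_statistic(self):
        # structural values for a2 = 0.4, c2 = 0.1
        m = AceLiabilityModel({"full_sib": self._tetra(0.5 * 0.4 + 0.1),
                               "cousin": self._tetra(0.125 * 0.4)})
        f = m.fit("ACE")
        assert f.fit_statistic == pytest.approx(0.0, abs=1e-18)
        assert f.params["a2"] == pytest.approx(0.4, abs=1e-9)
        assert f.params["c2"] == pytest.approx(0.1, abs=1e-9)

    def test_cousins_exceeding_sibs_pins_boundary(self):
        m = AceLiabilityModel({"full_sib": self._tetra(0.01),
                               "cousin": self._tetra(0.2)})
        f = m.fit("ACE")
        assert f.boundary
        assert f.params["c2"] == pytest.approx(0.0, abs=1e-9)

    def test_weights_applied(self):
        # down-weighting the cousin equation pulls the AE fit toward r_FS
        m = AceLiabilityModel({"full_sib": self._tetra(0.20, se=0.001),
                               "cousin": self._tetra(0.0, se=10.0)})
        f = m.fit("AE")
        assert f.a2 == pytest.approx(0.40, abs=1e-4)


def _exclusive_traits(a1=0.30, a2=0.40, k1=0.02, k2=0.10):
    t1 = TraitSpec("p", a1, 0.0, 1 - a1, k1, exclusive_with="q",
                   exclusivity_rule="p")
    t2 = TraitSpec("q", a2, 0.0, 1 - a2, k2, exclusive_with="p",
                   exclusivity_rule="p")
    return [t1, t2]


@pytest.fixture(scope="module")
def exclusive_tables():
    traits = _exclusive_traits()
    rg = {("p", "q"): 0.5}
    tabs = {}
    for kin, n in (("full_sib", 400_000), ("cousin", 800_000)):
        df = simulate_pairs(n, kin, traits, rg=rg, seed=61)
        tabs[kin] = cross_table(df, ["p", "q"], kin, exclusive=True)
    return tabs


class TestGeneticCorrelationML:
    def test_probabilities_sum_to_one(self, exclusive_tables):
        gm = GeneticCorrelationModel(exclusive_tables,
                                     {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                     exclusive=True, winner="p")
        for kin in ("full_sib", "cousin"):
            z1, z2 = gm._thresholds(0.5)
            cells = gm._cells(z1, z2)
            corr = gm._corr(0.5, kin)
            from pmdd._mvn4 import mvn4_rect_multi
            total = sum(mvn4_rect_multi(c, cells, corr).sum() for c in cells)
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_ml_recovers_generating_rg(self, exclusive_tables):
        gm = GeneticCorrelationModel(exclusive_tables,
                                     {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                     exclusive=True, winner="p")
        fit = gm.fit(lrt=False)
        assert fit.rg == pytest.approx(0.5, abs=4 * fit.se["rg"])

    def test_small_tables_match_monte_carlo_oracle(self):
        """Category probabilities agree with brute-force Monte-Carlo
        integration of the 4-D liability normal."""
        traits = _exclusive_traits(k1=0.05, k2=0.15)
        gm_tabs = {}
        df = simulate_pairs(50_000, "full_sib", traits, rg={("p", "q"): 0.5}, seed=67)
        gm_tabs["full_sib"] = cross_table(df, ["p", "q"], "full_sib", exclusive=True)
        gm = GeneticCorrelationModel(gm_tabs, {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                     exclusive=True, winner="p")
        # force thresholds to the exact generating values via margins:
        P = gm.category_probabilities(0.5, "full_sib")
        Ps = (P + P.T) / 2

        rng = np.random.default_rng(71)
        corr = gm._corr(0.5, "full_sib")
        L = np.linalg.cholesky(corr)
        z1, z2 = gm._thresholds(0.5)
        n_mc = 2_000_000
        counts = np.zeros((3, 3))
        for _ in range(5):
            z = rng.standard_normal((n_mc // 5, 4)) @ L.T
            ca = np.where(z[:, 0] > z1, 1, np.where(z[:, 1] > z2, 2, 0))
            cb = np.where(z[:, 2] > z1, 1, np.where(z[:, 3] > z2, 2, 0))
            counts += np.bincount(ca * 3 + cb, minlength=9).reshape(3, 3)
        emp = counts / n_mc
        emp_s = (emp + emp.T) / 2
        for i in range(3):
            for j in range(3):
                se = np.sqrt(max(Ps[i, j] * (1 - Ps[i, j]), 1e-12) / n_mc)
                assert abs(Ps[i, j] - emp_s[i, j]) < 5 * se + 1e-6

    def test_rg_invariant_to_trait_order(self, exclusive_tables):
        gm1 = GeneticCorrelationModel(exclusive_tables,
                                      {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                      exclusive=True, winner="p")
        # swap trait order: categories 1 and 2 exchange
        swapped = {}
        perm = [0, 2, 1]
        for kin, tab in exclusive_tables.items():
            swapped[kin] = PairCrossTable(kin, ("q", "p"),
                                          tab.counts[np.ix_(perm, perm)],
                                          exclusive=True)
        gm2 = GeneticCorrelationModel(swapped,
                                      {"q": {"a2": 0.4}, "p": {"a2": 0.3}},
                                      exclusive=True, winner="p")
        f1, f2 = gm1.fit(lrt=False), gm2.fit(lrt=False)
        assert f1.rg == pytest.approx(f2.rg, abs=5e-4)

    def test_independence_concordance_gives_null_rg(self):
        traits = _exclusive_traits(k1=0.05, k2=0.15)
        tabs = {}
        for kin, n in (("full_sib", 300_000), ("cousin", 300_000)):
            df = simulate_pairs(n, kin, traits, rg={("p", "q"): 0.0}, seed=73)
            tabs[kin] = cross_table(df, ["p", "q"], kin, exclusive=True)
        gm = GeneticCorrelationModel(tabs, {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                     exclusive=True, winner="p")
        fit = gm.fit(lrt=True)
        assert abs(fit.rg) < 4 * fit.se["rg"]
        assert fit.details["lrt_rg=0"]["p_value"] > 0.01


class TestGeneticCorrelationWls:
    def test_wls_recovers_nonexclusive_rg(self):
        t1 = TraitSpec("u", 0.3, 0.0, 0.7, 0.02)
        t2 = TraitSpec("v", 0.7, 0.0, 0.3, 0.05)
        tabs = {}
        for kin, n in (("full_sib", 400_000), ("cousin", 800_000)):
            df = simulate_pairs(n, kin, [t1, t2], rg={("u", "v"): 0.67}, seed=79)
            tabs[kin] = cross_table(df, ["u", "v"], kin)
        gm = GeneticCorrelationModel(tabs, {"u": {"a2": 0.3}, "v": {"a2": 0.7}})
        fit = gm.fit(method="wls")
        assert fit.rg == pytest.approx(0.67, abs=4 * fit.se["rg"])

    def test_wls_requires_nonexclusive(self, exclusive_tables):
        gm = GeneticCorrelationModel(exclusive_tables,
                                     {"p": {"a2": 0.3}, "q": {"a2": 0.4}},
                                     exclusive=True)
        with pytest.raises(ConfigError, match="exclusive"):
            gm.fit(method="wls")


class TestBootstrap:
    def _pair_cats(self, rng, n=4000, rho=0.0, prev=0.3):
        from scipy.special import ndtri
        z = ndtri(1 - prev)
        l1 = rng.standard_normal(n)
        l2 = rho * l1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return pd.DataFrame({
            "family_id": np.arange(n), "kinship": "full_sib",
            "cat_a": (l1 > z).astype(int), "cat_b": (l2 > z).astype(int),
        })

    def test_reproducible_given_seed(self, rng):
        pc = self._pair_cats(np.random.default_rng(83), rho=0.3)
        fit = lambda tabs: {"rho": tetrachoric(tabs["full_sib"].counts).rho}
        d1 = bootstrap_fits(pc, 2, fit, n_boot=50, seed=11)
        d2 = bootstrap_fits(pc, 2, fit, n_boot=50, seed=11)
        pd.testing.assert_frame_equal(d1, d2)

    def test_degenerate_data_zero_width_ci(self):
        # every family identical -> every resample identical -> zero width
        pc = pd.DataFrame({"family_id": np.arange(100), "kinship": "full_sib",
                           "cat_a": [0, 1] * 50, "cat_b": [1, 0] * 50})
        # families all carry one discordant pair each, so the resampled
        # table is always proportional to the original
        fit = lambda tabs: {"p01": tabs["full_sib"].counts[0, 1]
                            / tabs["full_sib"].n_pairs}
        draws = bootstrap_fits(pc, 2, fit, n_boot=40, seed=13)
        ci = percentile_ci(draws)["p01"]
        # symmetric storage halves the off-diagonal cell; width is exactly 0
        assert ci[0] == ci[1] == 0.5

    def test_ci_brackets_point_estimate(self):
        pc = self._pair_cats(np.random.default_rng(89), n=8000, rho=0.4)
        fit = lambda tabs: {"rho": tetrachoric(tabs["full_sib"].counts).rho}
        point = fit({"full_sib": PairCrossTable.from_categories(
            pc["cat_a"], pc["cat_b"], 2, "full_sib", ("t",))})["rho"]
        draws = bootstrap_fits(pc, 2, fit, n_boot=200, seed=17)
        lo, hi = percentile_ci(draws)["rho"]
        assert lo < point < hi
        assert hi - lo < 0.4


class TestModelComparison:
    def test_identical_fits_give_p_one(self):
        f = LiabilityFit("ACE", "WLS", {"a2": 0.3}, fit_statistic=1.0, n_params=2)
        g = LiabilityFit("AE", "WLS", {"a2": 0.3}, fit_statistic=1.0, n_params=1)
        assert compare_models(f, g)["p_value"] == pytest.approx(1.0)

    def test_chi_square_reference_value(self):
        # 1-df statistic 3.84 -> p = 0.05
        f = LiabilityFit("ACE", "ML", {}, loglike=-100.0, n_params=2)
        g = LiabilityFit("AE", "ML", {}, loglike=-100.0 - 3.841458820694124 / 2,
                         n_params=1)
        assert compare_models(f, g)["p_value"] == pytest.approx(0.05, abs=1e-9)

    def test_boundary_mixture_halves_p(self):
        f = LiabilityFit("ACE", "ML", {}, loglike=-99.0, n_params=2)
        g = LiabilityFit("AE", "ML", {}, loglike=-100.0, n_params=1)
        plain = compare_models(f, g)["p_value"]
        mixed = compare_models(f, g, boundary_mixture=True)["p_value"]
        assert mixed == pytest.approx(plain / 2)

    def test_c_not_significant_when_generated_without_c(self):
        trait = [TraitSpec("x", 0.3, 0.0, 0.7, 0.05)]
        tabs = {}
        for kin, n in (("full_sib", 300_000), ("cousin", 600_000)):
            df = simulate_pairs(n, kin, trait, seed=97)
            tabs[kin] = cross_table(df, ["x"], kin)
        m = AceLiabilityModel(tabs)
        res = compare_models(m.fit("ACE"), m.fit("AE"), boundary_mixture=True)
        assert res["p_value"] > 0.05


class TestRgDifference:
    def test_identical_draws_give_p_one(self):
        d = np.full(200, 0.5)
        res = rg_difference_test(d, d)
        assert res["p_value"] == pytest.approx(1.0)

    def test_separated_draws_significant(self):
        rng = np.random.default_rng(101)
        a = rng.normal(0.67, 0.03, 500)
        b = rng.normal(0.46, 0.03, 500)
        res = rg_difference_test(a, b)
        assert res["p_value"] < 0.01
        assert res["diff"] == pytest.approx(0.21, abs=0.01)


class TestParameterRecoveryGrid:
    @pytest.mark.parametrize("a2", [0.1, 0.5])
    def test_ae_estimate_unbiased_within_mc_error(self, a2):
        trait = [TraitSpec("x", a2, 0.0, 1 - a2, 0.05)]
        tabs = {}
        for kin, n in (("full_sib", 250_000), ("cousin", 500_000)):
            df = simulate_pairs(n, kin, trait, seed=int(103 + 100 * a2))
            tabs[kin] = cross_table(df, ["x"], kin)
        f = AceLiabilityModel(tabs).fit("AE")
        assert f.a2 == pytest.approx(a2, abs=4 * f.se["a2"])
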