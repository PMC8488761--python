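"""Invasion analysis: growth factors, analytic thresholds, outcome classes."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cytosweep import (
    CytotypeState,
    FixedBenefitParams,
    FreqDepParams,
    ImpossibleOriginError,
    NoResidentEquilibriumError,
    classify_invasion,
    introduce_mutant,
    mutant_growth_factor,
    resident_equilibrium,
    threshold_t_model_i,
    threshold_t_model_ii_displacement,
    threshold_t_model_ii_invasion,
)

from conftest import random_params


class TestIntroduceMutant:
    def test_uninfected_origin_bookkeeping(self):
        eq = CytotypeState.resident(0.2833)
        out = introduce_mutant(eq, "uninfected", 1e-5)
        assert out.p == 0.2833
        assert out.q == pytest.approx(0.7167 - 1e-5, abs=1e-15)
        assert out.s == 1e-5 and out.r == 0
        assert out.p + out.q + out.r + out.s == pytest.approx(1.0, abs=1e-12)

    def test_infected_origin_bookkeeping(self):
        eq = CytotypeState.resident(0.78415)
        out = introduce_mutant(eq, "infected", 1e-5)
        assert out.r == 1e-5
        assert out.p == pytest.approx(0.78415 - 1e-5, abs=1e-15)

    def test_empty_origin_compartment_raises(self):
        with pytest.raises(ImpossibleOriginError):
            introduce_mutant(CytotypeState.resident(1.0), "uninfected", 1e-5)
        with pytest.raises(ImpossibleOriginError):
            introduce_mutant(CytotypeState.resident(0.0), "infected", 1e-5)

    def test_rejects_nonresident_state(self):
        with pytest.raises(ValueError):
            introduce_mutant(CytotypeState(0.5, 0.4, 0.1, 0), "infected")


class TestGrowthFactor:
    def test_unit_growth_exactly_at_model_i_threshold(self):
        B, mu = 0.075, 0.05
        t_star = threshold_t_model_i(B, mu)
        assert t_star == pytest.approx(0.02125, abs=1e-12)
        gf = mutant_growth_factor(
            FixedBenefitParams(B=B, mu=mu, t=t_star), "uninfected"
        )
        assert gf == pytest.approx(1.0, abs=1e-12)

    def test_model_i_uninfected_growth_closed_form(self, fig1_params):
        gf = mutant_growth_factor(fig1_params, "uninfected")
        B, mu, t = fig1_params.B, fig1_params.mu, fig1_params.t
        assert gf == pytest.approx((1 + t) / ((1 - mu) * (1 + B)), rel=1e-12)
        assert gf < 1  # t = 0.02 < threshold 0.02125

    @pytest.mark.parametrize("model", ["i", "ii", "iii"])
    def test_infected_origin_grows_whenever_beneficial(self, model):
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = random_params(model, rng)
            if params.t > 0:
                assert mutant_growth_factor(params, "infected") > 1

    def test_neutral_mutant_growth_by_origin(self):
        """A neutral mitotype (t = 0) replicates at exactly the resident rate
        in the infected pool, but an uninfected lineage multiplies below
        replacement: the uninfected class persists only through segregant
        inflow, so neutral variants arising there are deterministically
        lost."""
        params = FixedBenefitParams(B=0.2, mu=0.05, t=0.0)
        assert mutant_growth_factor(params, "infected") == pytest.approx(1.0, abs=1e-12)
        p_star = resident_equilibrium(params).p_star
        expected = 1.0 / (1.0 + params.B * p_star)
        gf = mutant_growth_factor(params, "uninfected")
        assert gf == pytest.approx(expected, rel=1e-12)
        assert gf < 1

    def test_requires_resident_equilibrium(self):
        with pytest.raises(NoResidentEquilibriumError):
            mutant_growth_factor(FixedBenefitParams(B=0.05, mu=0.3, t=0.02), "infected")


class TestThresholds:
    def test_model_i_values(self):
        assert threshold_t_model_i(0.075, 0.05) == pytest.approx(0.02125)
        assert threshold_t_model_i(0.3, 0.0) == pytest.approx(0.3)
        # algebraic inversion: mu = (B - t)/(1 + B) recovers the threshold
        B, target = 0.1, 0.02
        mu = (B - target) / (1 + B)
        assert mu == pytest.approx(0.072727, abs=1e-6)
        assert threshold_t_model_i(B, mu) == pytest.approx(target, abs=1e-12)

    def test_model_i_requires_persistence(self):
        with pytest.raises(NoResidentEquilibriumError):
            threshold_t_model_i(0.05, 0.1)

    def test_model_ii_displacement_values(self):
        assert threshold_t_model_ii_displacement(0.1, 0.05, 0.02) == pytest.approx(
            1.05 * 0.98 - 1, abs=1e-12
        )
        # mu = 0 reduces to t > b - c
        assert threshold_t_model_ii_displacement(0.1, 0.04, 0.0) == pytest.approx(0.06)
        assert threshold_t_model_ii_displacement(0.1, 0.0, 0.0) == pytest.approx(0.1)

    def test_model_ii_invasion_threshold_zero_without_loss(self):
        """mu = 0: the equilibrium benefit exactly offsets the cost, so any
        positive t lets the mutant rise within the uninfected fraction."""
        assert threshold_t_model_ii_invasion(0.1, 0.03, 0.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_model_ii_invasion_threshold_matches_growth_root(self):
        """The closed-form invasion threshold is the root of the linearised
        growth factor, found numerically."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            b = float(rng.uniform(0.05, 0.4))
            c = float(rng.uniform(0.0, 0.5 * b))
            net = b - c
            mu = float(rng.uniform(0.01, 0.9 * net / (1 + net)))
            t_star = threshold_t_model_ii_invasion(b, c, mu)

            def gf_minus_one(t):
                return mutant_growth_factor(
                    FreqDepParams(b=b, c=c, mu=mu, t=t), "uninfected"
                ) - 1.0

            root = brentq(gf_minus_one, 0.0, 0.9, xtol=1e-14)
            assert root == pytest.approx(t_star, abs=1e-10)

    def test_invade_but_not_displace_band_exists(self):
        """For mu > 0 the invasion threshold sits strictly below the
        displacement threshold: a band of invasion without exclusion."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            b = float(rng.uniform(0.05, 0.5))
            c = float(rng.uniform(0.0, 0.6 * b))
            net = b - c
            mu = float(rng.uniform(1e-4, 0.9 * net / (1 + net)))
            assert threshold_t_model_ii_invasion(b, c, mu) < (
                threshold_t_model_ii_displacement(b, c, mu)
            )

    def test_fig4_parameters_sit_inside_the_coexistence_band(self, fig4_params):
        b, c, mu = fig4_params.b, fig4_params.c, fig4_params.mu
        assert threshold_t_model_ii_invasion(b, c, mu) < 0.02
        assert threshold_t_model_ii_displacement(b, c, mu) == pytest.approx(0.029)
        assert 0.02 < threshold_t_model_ii_displacement(b, c, mu)


class TestClassifyInvasion:
    def test_infected_origin_fixes_and_preserves_prevalence(self, fig1_params):
        res = classify_invasion(fig1_params, "infected")
        assert res.outcome == "mitotype_fixed_symbiont_retained"
        assert abs(res.final_state.symbiont_freq - res.baseline) < 1e-6

    def test_uninfected_origin_below_threshold_is_lost(self, fig1_params):
        # t = 0.02 < threshold 0.02125: advantageous yet unable to invade
        res = classify_invasion(fig1_params, "uninfected")
        assert res.outcome == "mitotype_lost"
        assert res.growth_factor < 1

    def test_uninfected_origin_above_threshold_excludes_symbiont(self):
        params = FixedBenefitParams(B=0.075, mu=0.05, t=0.03)  # > 0.02125
        res = classify_invasion(params, "uninfected")
        assert res.outcome == "mitotype_fixed_symbiont_excluded"

    def test_freqdep_uninfected_origin_partitions(self, fig4_params):
        res = classify_invasion(fig4_params, "uninfected")
        assert res.outcome == "coexistence_partitioned"
        final = res.final_state
        # symbiont prevalence is lowered, the infected pool keeps the
        # ancestral mitotype (r stays empty for an uninfected origin), and
        # segregants keep the ancestral type circulating among uninfected
        assert final.symbiont_freq < res.baseline - 1e-3
        assert final.r == 0.0
        assert final.p > 1e-3 and final.q > 1e-3 and final.s > 0.5

    def test_ci_infected_origin_fixes_with_symbiont_at_e3(self, fig6_params):
        res = classify_invasion(fig6_params, "infected")
        assert res.outcome == "mitotype_fixed_symbiont_retained"
        assert res.final_state.symbiont_freq == pytest.approx(res.baseline, abs=1e-6)

    def test_boundary_growth_reported_indeterminate(self):
        """Exactly on the invasion threshold the growth factor is 1 and the
        outcome is not forced into a class."""
        t_star = threshold_t_model_i(0.075, 0.05)
        params = FixedBenefitParams(B=0.075, mu=0.05, t=t_star)
        res = classify_invasion(params, "uninfected", horizon=5000)
        assert res.outcome == "indeterminate"
        assert res.growth_factor == pytest.approx(1.0, abs=1e-12)

    def test_freqdep_perfect_transmission_partition_rule(self):
        """mu = 0, infected origin: t <= b - c leaves the mitotype confined
        to symbiont carriers; t > b - c drives the symbiont to fixation."""
        modest = classify_invasion(
            FreqDepParams(b=0.1, c=0.04, mu=0.0, t=0.02), "infected"
        )
        assert modest.outcome == "coexistence_partitioned"
        assert modest.final_state.s == 0.0  # no segregation: mutant stays infected
        assert modest.final_state.q > 1e-3  # ancestral mitotype in uninfected pool
        strong = classify_invasion(
            FreqDepParams(b=0.1, c=0.04, mu=0.0, t=0.08), "infected"
        )
        assert strong.final_state.symbiont_freq == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("model", ["i", "ii", "iii"])
    def test_growth_factor_sign_predicts_fate(self, model):
        """Away from the neutral band, growth factor > 1 must coincide with
        invasion and < 1 with loss of the mutant."""
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 12:
            params = random_params(model, rng)
            gf = mutant_growth_factor(params, "uninfected")
            if abs(gf - 1) < 1e-3:  # skip the slow boundary band
                continue
            res = classify_invasion(params, "uninfected", horizon=300_000)
            if res.outcome == "indeterminate":
                continue
            assert (gf > 1) == (res.outcome != "mitotype_lost"), (params, gf, res)
            checked += 1

    @pytest.mark.parametrize("model", ["i", "ii", "iii"])
    def test_infected_origin_never_lowers_prevalence(self, model):
        """Segregational loss feeds the swept mitotype back into the
        uninfected pool, leaving equilibrium prevalence intact."""
        rng = np.random.default_rng(41)
        for _ in range(5):
            params = random_params(model, rng, margin=0.8)
            if params.mu == 0 or params.t == 0:
                continue
            res = classify_invasion(params, "infected", horizon=400_000)
            if res.outcome == "indeterminate":
                continue
            assert res.final_state.symbiont_freq >= res.baseline - 1e-6
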