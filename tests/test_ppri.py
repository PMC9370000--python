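"""Reactive-intermediate budget: OH, carbonate radical, triplets, dibromide."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photonox import (
    DegenerateScenarioError,
    OHBudget,
    RateConstantSet,
    ValidationError,
    WaterScenario,
    cage_enhancement_factor,
    carbonate_radical_state,
    compute_ppri,
    dibromide_state,
    oh_formation_rates,
    oh_scavenging_capacity,
    steady_state_oh,
    triplet_singlet_state,
)
from photonox.spectra import PhotonField, depth_averaged_absorbed_photons

# the hand-derived scavenging sums below assume the low-end OH+DOM constant
LOW_K_OH_DOM = RateConstantSet().with_overrides(k_OH_DOM=2.5e4)


def make_budget(formation=1e-12, **sinks):
    defaults = dict(sink_dom=2.5e4, sink_bicarbonate=8.5e3, sink_carbonate=3.9e3,
                    sink_bromide=0.0, sink_nitrite=1e4)
    defaults.update(sinks)
    return OHBudget(formation_nitrate=formation, formation_nitrite=0.0,
                    formation_cdom=0.0, **defaults)


class TestCageEnhancement:
    def test_unity_without_inorganic_carbon(self):
        assert cage_enhancement_factor(0.0, 0.0) == 1.0

    def test_monotone_in_bicarbonate(self):
        assert cage_enhancement_factor(2e-3, 0.0) >= cage_enhancement_factor(1e-3, 0.0)

    def test_saturating_form_at_default_parameters(self):
        # f = 1 + 1.0 * c/(1 mM + c) at c = 1.01 mM total inorganic carbon
        expected = 1.0 + 1.01e-3 / (1e-3 + 1.01e-3)
        assert cage_enhancement_factor(1e-3, 1e-5) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            cage_enhancement_factor(-1e-3, 0.0)

    def test_never_below_one(self):
        for hco3 in (0.0, 1e-5, 1e-3, 1e-1):
            assert cage_enhancement_factor(hco3, hco3 / 100) >= 1.0


class TestOHFormation:
    def test_zero_nitrate_means_no_photolysis_source(self):
        scenario = WaterScenario(nitrate=0.0, nitrite=1e-6, doc=1.0)
        field = depth_averaged_absorbed_photons(scenario)
        budget = oh_formation_rates(scenario, field)
        assert budget.formation_nitrate == 0.0

    def test_doubling_irradiance_doubles_each_formation_rate(self):
        # optically thin column so the absorbed rates are linear in flux
        base = WaterScenario(nitrate=1e-6, nitrite=1e-8, doc=0.01, depth=0.05,
                             uv_irradiance=22.0)
        bright = base.replace(uv_irradiance=44.0)
        b0 = oh_formation_rates(base, depth_averaged_absorbed_photons(base))
        b1 = oh_formation_rates(bright, depth_averaged_absorbed_photons(bright))
        for name in ("formation_nitrate", "formation_nitrite", "formation_cdom"):
            assert getattr(b1, name) == pytest.approx(2 * getattr(b0, name), rel=1e-2)

    def test_photolysis_rate_is_yield_times_cage_times_absorption(self):
        scenario = WaterScenario(nitrate=1e-4, bicarbonate=1e-3, carbonate=1e-5)
        constants = RateConstantSet()
        field = PhotonField(rates={"nitrate": 3e-12, "nitrite": 0.0, "cdom": 0.0},
                            total=3e-12)
        budget = oh_formation_rates(scenario, field, constants)
        cage = cage_enhancement_factor(1e-3, 1e-5, constants)
        assert budget.formation_nitrate == pytest.approx(
            constants.phi_OH_nitrate * cage * 3e-12, rel=1e-14)


class TestScavengingCapacity:
    def test_hand_summed_default_capacity(self):
        # 2.5e4*1 + 8.5e6*1e-3 + 3.9e8*1e-5 + 1e10*1e-6 = 4.74e4 s^-1
        scenario = WaterScenario(doc=1.0, bicarbonate=1e-3, carbonate=1e-5,
                                 nitrite=1e-6, bromide=0.0)
        sinks = oh_scavenging_capacity(scenario, LOW_K_OH_DOM)
        assert sum(sinks.values()) == pytest.approx(4.74e4, rel=1e-12)

    def test_seawater_bromide_adds_its_own_term(self):
        # 1.1e10 * 8e-4 = 8.8e6 s^-1
        fresh = WaterScenario(doc=1.0, bicarbonate=1e-3, carbonate=1e-5, nitrite=1e-6)
        salty = fresh.replace(bromide=8e-4)
        s0 = sum(oh_scavenging_capacity(fresh, LOW_K_OH_DOM).values())
        s1 = sum(oh_scavenging_capacity(salty, LOW_K_OH_DOM).values())
        assert s1 - s0 == pytest.approx(8.8e6, rel=1e-12)


class TestSteadyStateOH:
    def test_quotient(self):
        budget = make_budget(formation=1e-12)
        assert steady_state_oh(budget) == pytest.approx(1e-12 / 4.74e4, rel=1e-12)

    def test_zero_formation_gives_zero(self):
        assert steady_state_oh(make_budget(formation=0.0)) == 0.0

    def test_all_zero_sinks_refused(self):
        budget = make_budget(sink_dom=0, sink_bicarbonate=0, sink_carbonate=0,
                             sink_nitrite=0)
        with pytest.raises(DegenerateScenarioError):
            steady_state_oh(budget)

    def test_seawater_bromide_suppresses_oh_187_fold(self):
        budget = make_budget(formation=1e-12)
        salty = make_budget(formation=1e-12, sink_bromide=8.8e6)
        factor = steady_state_oh(budget) / steady_state_oh(salty)
        assert factor == pytest.approx((8.8e6 + 4.74e4) / 4.74e4, rel=1e-10)


class TestCarbonateRadical:
    def test_zero_without_carbonate_or_triplet(self):
        scenario = WaterScenario(doc=1.0)
        assert carbonate_radical_state(scenario, oh=1e-17, triplet=0.0) == 0.0

    def test_ratio_to_oh_with_defaults(self):
        # (8.5e3 + 3.9e3) / (k_CO3_DOM * DOC) = 12400 / 100 = 124
        scenario = WaterScenario(doc=1.0, bicarbonate=1e-3, carbonate=1e-5)
        oh = 2e-17
        co3 = carbonate_radical_state(scenario, oh=oh, triplet=0.0)
        assert co3 / oh == pytest.approx(124.0, rel=1e-12)

    def test_doc_increase_decreases_concentration(self):
        s1 = WaterScenario(doc=1.0, bicarbonate=1e-3, carbonate=1e-5)
        s2 = s1.replace(doc=3.0)
        assert (carbonate_radical_state(s2, 1e-17, 0.0)
                < carbonate_radical_state(s1, 1e-17, 0.0))

    def test_zero_doc_with_formation_refused(self):
        scenario = WaterScenario(doc=0.0, bicarbonate=1e-3)
        with pytest.raises(DegenerateScenarioError):
            carbonate_radical_state(scenario, oh=1e-17, triplet=0.0)


class TestTripletSinglet:
    def test_zero_doc_gives_zero_both(self):
        scenario = WaterScenario(doc=0.0)
        field = depth_averaged_absorbed_photons(scenario)
        assert triplet_singlet_state(scenario, field) == (0.0, 0.0)

    def test_reference_anchor_order_of_magnitude(self):
        """DOC 1, 5 m, 22 W/m2: both pools sit near 1e-16 M (within 3x)."""
        scenario = WaterScenario(doc=1.0, depth=5.0, uv_irradiance=22.0)
        field = depth_averaged_absorbed_photons(scenario)
        triplet, singlet = triplet_singlet_state(scenario, field)
        assert 1e-16 / 3 < triplet < 1e-16 * 3
        assert 1e-16 / 3 < singlet < 1e-16 * 3

    def test_singlet_proportional_to_triplet(self):
        constants = RateConstantSet()
        scenario = WaterScenario(doc=1.0)
        field = depth_averaged_absorbed_photons(scenario)
        triplet, singlet = triplet_singlet_state(scenario, field, constants)
        expected_ratio = (constants.f_delta * constants.k_triplet_loss
                          / constants.k_singlet_loss)
        assert singlet / triplet == pytest.approx(expected_ratio, rel=1e-12)


class TestDibromide:
    def test_no_bromide_no_dibromide(self):
        scenario = WaterScenario(doc=1.0, bromide=0.0)
        conc, rate = dibromide_state(scenario, make_budget())
        assert (conc, rate) == (0.0, 0.0)

    def test_linear_regime_quotient(self):
        """Linear sinks 320 s^-1 dominate: [Br2-] = rate / 320 to < 1e-4."""
        scenario = WaterScenario(doc=1.0, nitrite=1e-6, bromide=8e-4)
        budget = make_budget(formation=3.2e-13 / (8.8e6 / (8.8e6 + 4.74e4)),
                             sink_bromide=8.8e6)
        conc, rate = dibromide_state(scenario, budget, LOW_K_OH_DOM)
        assert rate == pytest.approx(3.2e-13, rel=1e-12)
        assert conc == pytest.approx(1e-15, rel=1e-4)

    def test_root_satisfies_quadratic(self):
        constants = RateConstantSet()
        scenario = WaterScenario(doc=0.5, nitrite=1e-7, bromide=8e-4)
        budget = make_budget(formation=1e-11, sink_bromide=8.8e6)
        conc, rate = dibromide_state(scenario, budget, constants)
        linear = constants.k_Br2_DOM * 0.5 + constants.k_Br2_NO2 * 1e-7
        residual = 2 * constants.k_Br2_dimer * conc ** 2 + linear * conc - rate
        assert abs(residual) < 1e-10 * rate

    def test_dimer_free_limit_equals_linear_quotient(self):
        constants = RateConstantSet().with_overrides(k_Br2_dimer=0.0)
        scenario = WaterScenario(doc=1.0, nitrite=1e-6, bromide=8e-4)
        budget = make_budget(formation=1e-12, sink_bromide=8.8e6)
        conc, rate = dibromide_state(scenario, budget, constants)
        assert conc == rate / 320.0

    def test_no_sink_refused(self):
        constants = RateConstantSet().with_overrides(k_Br2_dimer=0.0,
                                                     k_Br2_DOM=0.0, k_Br2_NO2=0.0)
        scenario = WaterScenario(doc=1.0, bromide=8e-4)
        with pytest.raises(DegenerateScenarioError):
            dibromide_state(scenario, make_budget(sink_bromide=8.8e6), constants)


scenario_strategy = st.builds(
    WaterScenario,
    nitrate=st.floats(1e-7, 1e-3),
    nitrite=st.floats(1e-9, 1e-5),
    doc=st.floats(0.1, 20.0),
    bicarbonate=st.floats(0.0, 5e-3),
    carbonate=st.floats(0.0, 1e-4),
    bromide=st.floats(0.0, 1e-3),
    depth=st.floats(0.5, 20.0),
    uv_irradiance=st.floats(1.0, 60.0),
)


class TestSteadyStateProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scenario=scenario_strategy)
    def test_concentration_times_sink_equals_source(self, scenario):
        """Steady-state identity for every species on arbitrary scenarios."""
        constants = RateConstantSet()
        state = compute_ppri(scenario, constants)
        budget = state.oh_budget
        assert state.oh * budget.scavenging_capacity == pytest.approx(
            budget.total_formation, rel=1e-10)
        # dibromide: quadratic closure
        linear = (constants.k_Br2_DOM * scenario.doc
                  + constants.k_Br2_NO2 * scenario.nitrite)
        lhs = 2 * constants.k_Br2_dimer * state.br2_radical ** 2 + linear * state.br2_radical
        assert lhs == pytest.approx(state.br2_formation_rate, rel=1e-10, abs=1e-300)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scenario=scenario_strategy)
    def test_oh_strictly_decreasing_in_doc_and_bromide(self, scenario):
        state = compute_ppri(scenario)
        more_doc = compute_ppri(scenario.replace(doc=scenario.doc * 2))
        more_br = compute_ppri(scenario.replace(bromide=scenario.bromide + 1e-4))
        assert more_doc.oh < state.oh
        assert more_br.oh < state.oh

    def test_irradiance_linearity_optically_thin(self):
        thin = WaterScenario(nitrate=1e-6, nitrite=1e-8, doc=0.01, depth=0.05,
                             bicarbonate=1e-4, carbonate=1e-6, bromide=1e-4)
        s1 = compute_ppri(thin)
        s2 = compute_ppri(thin.replace(uv_irradiance=44.0))
        for attr in ("oh", "co3_radical", "triplet", "singlet_oxygen", "br2_radical"):
            assert getattr(s2, attr) == pytest.approx(2 * getattr(s1, attr), rel=1e-2)

    def test_br2_zero_iff_no_bromide_or_no_source(self):
        with_br = compute_ppri(WaterScenario(nitrate=1e-4, doc=1.0, bromide=1e-4))
        assert with_br.br2_radical > 0
        dark = compute_ppri(WaterScenario(nitrate=1e-4, doc=1.0, bromide=1e-4,
                                          uv_irradiance=0.0))
        assert dark.br2_radical == 0.0
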