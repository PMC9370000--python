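"""Photochemically produced reactive intermediates (PPRIs).

Formation rates and steady-state concentrations of the hydroxyl radical
(with its full scavenging budget), the carbonate radical, CDOM triplet
states, singlet oxygen and the dibromide radical anion. Each species obeys
the steady-state closure

    [X] = (total formation rate) / (total pseudo-first-order sink),

except the dibromide radical, whose dimerization adds a quadratic sink term.

The OH budget is the hub of the model: nitrate photolysis, nitrite photolysis
and CDOM photochemistry all feed it; DOM, bicarbonate, carbonate, bromide and
nitrite drain it. The bromide share of the drain is not lost — it is relayed
to nitrite via the Br-/Br2- electron shuttle, which is why saltwater keeps
making the NO2 radical even though OH itself is suppressed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .constants import RateConstantSet
from .errors import DegenerateScenarioError, ValidationError
from .scenario import WaterScenario
from .spectra import PhotonField, SpectrumTable, depth_averaged_absorbed_photons

__all__ = [
    "OHBudget",
    "PPRIState",
    "cage_enhancement_factor",
    "oh_formation_rates",
    "oh_scavenging_capacity",
    "steady_state_oh",
    "carbonate_radical_state",
    "triplet_singlet_state",
    "dibromide_state",
    "compute_ppri",
]

logger = logging.getLogger(__name__)

#: below this bromide level the quantitative Br -> Br2- conversion assumption
#: is shaky; the model still applies it but logs a warning.
_BR_QUANTITATIVE_FLOOR_M = 1e-5


@dataclass(frozen=True)
class OHBudget:
    """Hydroxyl-radical sources (M s^-1) and sinks (s^-1), itemized."""

    formation_nitrate: float
    formation_nitrite: float
    formation_cdom: float
    sink_dom: float
    sink_bicarbonate: float
    sink_carbonate: float
    sink_bromide: float
    sink_nitrite: float

    @property
    def total_formation(self) -> float:
        return self.formation_nitrate + self.formation_nitrite + self.formation_cdom

    @property
    def scavenging_capacity(self) -> float:
        """Total pseudo-first-order OH sink S, s^-1."""
        return (self.sink_dom + self.sink_bicarbonate + self.sink_carbonate
                + self.sink_bromide + self.sink_nitrite)


@dataclass(frozen=True)
class PPRIState:
    """Steady-state concentrations (M) of every reactive intermediate."""

    oh: float
    co3_radical: float
    triplet: float
    singlet_oxygen: float
    br2_radical: float
    br2_formation_rate: float
    oh_budget: OHBudget
    photon_field: PhotonField


def cage_enhancement_factor(bicarbonate: float, carbonate: float,
                            constants: RateConstantSet | None = None) -> float:
    """Solvent-cage enhancement of nitrate photolysis by inorganic carbon.

    Bicarbonate/carbonate inhibit in-cage geminate recombination of the
    photofragments (O radical anion and NO2 radical), raising the effective
    photolysis quantum yield. Modelled as a saturating function of total
    inorganic carbon c: ``f = 1 + delta * c / (c_half + c)``; 1 at c = 0.
    """
    if bicarbonate < 0 or carbonate < 0:
        raise ValidationError("inorganic carbon concentrations must be >= 0")
    constants = constants or RateConstantSet()
    c_ic = bicarbonate + carbonate
    if c_ic == 0:
        return 1.0
    return 1.0 + constants.cage_delta * c_ic / (constants.cage_half_M + c_ic)


def oh_formation_rates(scenario: WaterScenario, photon_field: PhotonField,
                       constants: RateConstantSet | None = None) -> OHBudget:
    """Itemized OH formation rates plus the scavenging sinks, as one budget.

    Nitrate photolysis: quantum yield x cage factor x absorbed photons
    (and the same rate is the NO2-radical photolysis source, 1:1).
    Nitrite photolysis and CDOM photochemistry contribute with their own
    yields, to OH only.
    """
    constants = constants or RateConstantSet()
    cage = cage_enhancement_factor(scenario.bicarbonate, scenario.carbonate, constants)
    sinks = oh_scavenging_capacity(scenario, constants)
    return OHBudget(
        formation_nitrate=constants.phi_OH_nitrate * cage * photon_field.rates.get("nitrate", 0.0),
        formation_nitrite=constants.phi_OH_nitrite * photon_field.rates.get("nitrite", 0.0),
        formation_cdom=constants.phi_OH_CDOM * photon_field.rates.get("cdom", 0.0),
        **sinks,
    )


def oh_scavenging_capacity(scenario: WaterScenario,
                           constants: RateConstantSet | None = None) -> dict[str, float]:
    """Per-sink pseudo-first-order OH scavenging terms (s^-1)."""
    constants = constants or RateConstantSet()
    return {
        "sink_dom": constants.k_OH_DOM * scenario.doc,
        "sink_bicarbonate": constants.k_OH_HCO3 * scenario.bicarbonate,
        "sink_carbonate": constants.k_OH_CO3 * scenario.carbonate,
        "sink_bromide": constants.k_OH_Br * scenario.bromide,
        "sink_nitrite": constants.k2_OH_nitrite * scenario.nitrite,
    }


def steady_state_oh(budget: OHBudget) -> float:
    """[OH] = total formation / scavenging capacity."""
    if budget.scavenging_capacity <= 0:
        raise DegenerateScenarioError(
            "OH scavenging capacity is zero (no DOM, inorganic carbon, bromide "
            "or nitrite): the OH steady state is undefined")
    return budget.total_formation / budget.scavenging_capacity


def carbonate_radical_state(scenario: WaterScenario, oh: float, triplet: float,
                            constants: RateConstantSet | None = None) -> float:
    """Steady-state carbonate radical concentration (M).

    Sources: OH oxidation of bicarbonate and carbonate, plus triplet-CDOM
    oxidation of carbonate. Sink: DOM. (The carbonate radical is *not* fed
    back into NO2-radical formation: its reaction with nitrite is an
    insignificant NO2 source.)
    """
    constants = constants or RateConstantSet()
    if oh < 0 or triplet < 0:
        raise ValidationError("concentrations must be >= 0")
    formation = ((constants.k_OH_HCO3 * scenario.bicarbonate
                  + constants.k_OH_CO3 * scenario.carbonate) * oh
                 + constants.k_3CDOM_CO3 * scenario.carbonate * triplet)
    if formation == 0:
        return 0.0
    sink = constants.k_CO3_DOM * scenario.doc
    if sink <= 0:
        raise DegenerateScenarioError(
            "carbonate-radical sink is zero (DOC = 0) while its formation is "
            "nonzero: steady state undefined")
    return formation / sink


def triplet_singlet_state(scenario: WaterScenario, photon_field: PhotonField,
                          constants: RateConstantSet | None = None
                          ) -> tuple[float, float]:
    """Steady-state [3CDOM*] and [1O2] (M).

    Triplets: intersystem-crossing yield x CDOM-absorbed photons over the
    total triplet loss constant. Singlet oxygen: the fraction of triplet
    decays that transfer to O2, over the solvent-collision loss constant.
    """
    constants = constants or RateConstantSet()
    absorbed = photon_field.rates.get("cdom", 0.0)
    triplet_formation = constants.phi_ISC * absorbed
    triplet = triplet_formation / constants.k_triplet_loss if triplet_formation else 0.0
    singlet_formation = constants.f_delta * triplet_formation
    singlet = singlet_formation / constants.k_singlet_loss if singlet_formation else 0.0
    return triplet, singlet


def dibromide_state(scenario: WaterScenario, oh_budget: OHBudget,
                    constants: RateConstantSet | None = None
                    ) -> tuple[float, float]:
    """Steady-state dibromide radical concentration and its formation rate.

    OH + Br- yields the Br atom, which in excess bromide is converted
    quantitatively to the dibromide radical anion; the formation rate is
    therefore the total OH formation times the bromide share of the OH
    scavenging capacity. Sinks: DOM and nitrite (linear) plus dimerization
    (quadratic); the reported concentration is the positive root of

        2 k_dim x^2 + (k_DOM DOC + k_NO2 [NO2-]) x = rate.
    """
    constants = constants or RateConstantSet()
    capacity = oh_budget.scavenging_capacity
    if scenario.bromide == 0 or capacity == 0 or oh_budget.total_formation == 0:
        return 0.0, 0.0
    if 0 < scenario.bromide < _BR_QUANTITATIVE_FLOOR_M:
        logger.warning(
            "bromide %.3g M is below %.0e M: the quantitative Br -> Br2- "
            "conversion assumption is marginal", scenario.bromide,
            _BR_QUANTITATIVE_FLOOR_M)
    rate = oh_budget.total_formation * (oh_budget.sink_bromide / capacity)
    linear = (constants.k_Br2_DOM * scenario.doc
              + constants.k_Br2_NO2 * scenario.nitrite)
    quad = 2.0 * constants.k_Br2_dimer
    if linear == 0 and quad == 0:
        raise DegenerateScenarioError(
            "dibromide radical has no sink (no DOM, no nitrite, dimerization "
            "disabled) while its formation is nonzero")
    if quad == 0:
        return rate / linear, rate
    # numerically stable positive root of quad*x^2 + linear*x - rate = 0
    x = 2.0 * rate / (linear + math.sqrt(linear * linear + 4.0 * quad * rate))
    return x, rate


def compute_ppri(scenario: WaterScenario,
                 constants: RateConstantSet | None = None,
                 solar: SpectrumTable | None = None) -> PPRIState:
    """Run the whole photochemical core on one scenario."""
    constants = constants or RateConstantSet()
    photon_field = depth_averaged_absorbed_photons(scenario, solar=solar)
    budget = oh_formation_rates(scenario, photon_field, constants)
    if budget.total_formation == 0:
        oh = 0.0
    else:
        oh = steady_state_oh(budget)
    triplet, singlet = triplet_singlet_state(scenario, photon_field, constants)
    br2, br2_rate = dibromide_state(scenario, budget, constants)
    co3 = carbonate_radical_state(scenario, oh, triplet, constants)
    return PPRIState(oh=oh, co3_radical=co3, triplet=triplet,
                     singlet_oxygen=singlet, br2_radical=br2,
                     br2_formation_rate=br2_rate, oh_budget=budget,
                     photon_field=photon_field)
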