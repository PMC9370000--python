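"""Coupled NO2-radical / N2O4 steady state.

Reactions:

    NO3- + hv (+H+)      -> OH + NO2          (photolysis source)
    NO2- + OH            -> NO2 + OH-         (k2)
    2 NO2  <->  N2O4                           (k3 forward, k-3 back)
    NO2 + DOM            -> products           (k4, per mg_C)
    N2O4 + H2O           -> NO3- + NO2- + 2H+  (k5)

Setting d[NO2]/dt = d[N2O4]/dt = 0 and eliminating N2O4 gives a single
quadratic in x = [NO2]:

    R = a x^2 + b x,   a = 2 k3 k5 / (k-3 + k5),   b = k4 DOC,

whose positive root is the exact steady state; [N2O4] = k3 x^2 / (k-3 + k5).
Because the DOM sink overwhelms the dimerization/hydrolysis channel in real
waters, the linear simplification x = R / (k4 DOC) is accurate to a few
per-mille; this module provides both, their deviation, and an independent
ODE-relaxation oracle for verification.

Optional NO2 sources beyond the two baseline terms: nitrite oxidation by the
dibromide radical (saltwater) and by CDOM triplets (an upper-limit variant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .constants import RateConstantSet
from .errors import DegenerateScenarioError, ValidationError
from .ppri import PPRIState
from .scenario import WaterScenario

__all__ = [
    "NOxSourceOptions",
    "NOxState",
    "no2_formation_rate",
    "no2_steady_state_exact",
    "no2_steady_state_simplified",
    "n2o4_steady_state",
    "approximation_deviation_permil",
    "ode_relaxation_oracle",
    "solve_nox",
]


@dataclass(frozen=True)
class NOxSourceOptions:
    """Which NO2-radical sources are active."""

    include_nitrate_photolysis: bool = True
    include_nitrite_oh: bool = True
    include_nitrite_br2: bool = False
    include_nitrite_triplet_upper_limit: bool = False


@dataclass(frozen=True)
class NOxState:
    """Source-decomposed NO2 formation and the resulting steady state."""

    r_photolysis: float          # M s^-1
    r_oh_pathway: float
    r_br2_pathway: float
    r_triplet_pathway: float
    no2_exact: float             # M
    no2_simplified: float        # M (nan when DOC = 0)
    n2o4: float                  # M
    deviation_permil: float      # (simplified - exact)/exact * 1000

    @property
    def r_total(self) -> float:
        return (self.r_photolysis + self.r_oh_pathway
                + self.r_br2_pathway + self.r_triplet_pathway)

    @property
    def log10_ratio_no2_n2o4(self) -> float:
        """log10([NO2]/[N2O4]); inf when N2O4 is zero."""
        if self.n2o4 == 0:
            return math.inf
        return math.log10(self.no2_exact / self.n2o4)


def _quadratic_coefficient(constants: RateConstantSet) -> float:
    """a = 2 k3 k5 / (k-3 + k5), the effective quadratic NO2 sink (M^-1 s^-1)."""
    return (2.0 * constants.k3_dimerization * constants.k5_hydrolysis
            / (constants.k_minus3 + constants.k5_hydrolysis))


def no2_formation_rate(ppri: PPRIState, scenario: WaterScenario,
                       options: NOxSourceOptions | None = None,
                       constants: RateConstantSet | None = None
                       ) -> dict[str, float]:
    """Source-decomposed NO2-radical formation rate (M s^-1).

    The photolysis term equals the nitrate-derived OH formation rate (the two
    fragments of reaction NO3- + hv are produced 1:1); the OH pathway is
    k2 [OH][NO2-]; optional terms add the dibromide and triplet oxidations
    of nitrite.
    """
    options = options or NOxSourceOptions()
    constants = constants or RateConstantSet()
    rates = {
        "r_photolysis": (ppri.oh_budget.formation_nitrate
                         if options.include_nitrate_photolysis else 0.0),
        "r_oh_pathway": (constants.k2_OH_nitrite * ppri.oh * scenario.nitrite
                         if options.include_nitrite_oh else 0.0),
        "r_br2_pathway": (constants.k_Br2_NO2 * ppri.br2_radical * scenario.nitrite
                          if options.include_nitrite_br2 else 0.0),
        "r_triplet_pathway": (constants.k_3CDOM_NO2_upper * ppri.triplet * scenario.nitrite
                              if options.include_nitrite_triplet_upper_limit else 0.0),
    }
    rates["r_total"] = sum(rates.values())
    return rates


def no2_steady_state_exact(r_total: float, doc: float,
                           constants: RateConstantSet | None = None
                           ) -> tuple[float, float]:
    """Exact steady-state ([NO2], [N2O4]) from the quadratic closure.

    Solves R = a x^2 + b x with b = k4 DOC in the cancellation-free form
    x = 2R / (b + sqrt(b^2 + 4 a R)), valid down to DOC = 0 (pure
    dimerization/hydrolysis sink).
    """
    constants = constants or RateConstantSet()
    if r_total < 0 or doc < 0:
        raise ValidationError("formation rate and DOC must be >= 0")
    if r_total == 0:
        return 0.0, 0.0
    a = _quadratic_coefficient(constants)
    b = constants.k4_NO2_DOM * doc
    no2 = 2.0 * r_total / (b + math.sqrt(b * b + 4.0 * a * r_total))
    return no2, n2o4_steady_state(no2, constants)


def no2_steady_state_simplified(r_total: float, doc: float,
                                constants: RateConstantSet | None = None) -> float:
    """Linear steady state [NO2] = R / (k4 DOC) (DOM as the only sink)."""
    constants = constants or RateConstantSet()
    if r_total < 0 or doc < 0:
        raise ValidationError("formation rate and DOC must be >= 0")
    if doc == 0:
        raise DegenerateScenarioError(
            "the simplified NO2 steady state is undefined at DOC = 0; use the "
            "exact quadratic solution instead")
    return r_total / (constants.k4_NO2_DOM * doc)


def n2o4_steady_state(no2: float, constants: RateConstantSet | None = None) -> float:
    """[N2O4] = k3 [NO2]^2 / (k-3 + k5)."""
    constants = constants or RateConstantSet()
    if no2 < 0:
        raise ValidationError("[NO2] must be >= 0")
    return (constants.k3_dimerization * no2 * no2
            / (constants.k_minus3 + constants.k5_hydrolysis))


def approximation_deviation_permil(r_total: float, doc: float,
                                   constants: RateConstantSet | None = None) -> float:
    """Per-mille overshoot of the linear form over the exact quadratic one.

    1000 (simplified - exact)/exact; always >= 0 because dropping the
    quadratic sink can only raise the steady state. -> 0 as R -> 0.
    """
    constants = constants or RateConstantSet()
    exact, _ = no2_steady_state_exact(r_total, doc, constants)
    if exact == 0:
        return 0.0
    simplified = no2_steady_state_simplified(r_total, doc, constants)
    return 1000.0 * (simplified - exact) / exact


def ode_relaxation_oracle(r_total: float, doc: float,
                          constants: RateConstantSet | None = None,
                          horizon: float | None = None) -> tuple[float, float]:
    """Steady state by time-integrating the two-species rate equations.

        d[NO2]/dt  = R - 2 k3 x^2 + 2 k-3 y - k4 DOC x
        d[N2O4]/dt = k3 x^2 - (k-3 + k5) y

    from zero initial conditions until both derivatives are below 1e-6 of the
    source term. Independent check of the closed-form quadratic solution.
    """
    constants = constants or RateConstantSet()
    if r_total < 0 or doc < 0:
        raise ValidationError("formation rate and DOC must be >= 0")
    if r_total == 0:
        return 0.0, 0.0
    k3, km3, k5 = (constants.k3_dimerization, constants.k_minus3,
                   constants.k5_hydrolysis)
    b = constants.k4_NO2_DOM * doc
    a = _quadratic_coefficient(constants)
    x_scale = 2.0 * r_total / (b + math.sqrt(b * b + 4.0 * a * r_total))
    if horizon is None:
        # slowest relaxation: the linear NO2 sink at scale x, or the N2O4 pool
        horizon = 50.0 * max(1.0 / (b + a * x_scale), 1.0 / (km3 + k5))

    def rhs(_t: float, state: np.ndarray) -> list[float]:
        x, y = state
        return [r_total - 2.0 * k3 * x * x + 2.0 * km3 * y - b * x,
                k3 * x * x - (km3 + k5) * y]

    def jac(_t: float, state: np.ndarray) -> list[list[float]]:
        x, _y = state
        return [[-4.0 * k3 * x - b, 2.0 * km3],
                [2.0 * k3 * x, -(km3 + k5)]]

    y_scale = k3 * x_scale * x_scale / (km3 + k5)
    sol = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0], method="Radau", jac=jac,
                    rtol=1e-10, atol=[x_scale * 1e-12, max(y_scale, 1e-300) * 1e-12])
    x_end, y_end = sol.y[:, -1]
    dx, dy = rhs(sol.t[-1], np.array([x_end, y_end]))
    if abs(dx) > 1e-6 * r_total or abs(dy) > 1e-6 * max(k3 * x_end * x_end, r_total):
        raise RuntimeError(
            f"relaxation did not converge within horizon {horizon:.3g} s: "
            f"d[NO2]/dt = {dx:.3e}, d[N2O4]/dt = {dy:.3e} M/s")
    return float(x_end), float(y_end)


def solve_nox(ppri: PPRIState, scenario: WaterScenario,
              options: NOxSourceOptions | None = None,
              constants: RateConstantSet | None = None) -> NOxState:
    """Full NO2/N2O4 state for one scenario: sources, both closures, deviation."""
    constants = constants or RateConstantSet()
    rates = no2_formation_rate(ppri, scenario, options, constants)
    r_total = rates["r_total"]
    exact, n2o4 = no2_steady_state_exact(r_total, scenario.doc, constants)
    if scenario.doc > 0:
        simplified = no2_steady_state_simplified(r_total, scenario.doc, constants)
        deviation = (1000.0 * (simplified - exact) / exact) if exact > 0 else 0.0
    else:
        simplified, deviation = math.nan, math.nan
    return NOxState(
        r_photolysis=rates["r_photolysis"],
        r_oh_pathway=rates["r_oh_pathway"],
        r_br2_pathway=rates["r_br2_pathway"],
        r_triplet_pathway=rates["r_triplet_pathway"],
        no2_exact=exact, no2_simplified=simplified, n2o4=n2o4,
        deviation_permil=deviation)
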