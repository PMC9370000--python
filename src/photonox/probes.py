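"""Pathway apportionment of probe-compound phototransformation.

A dissolved probe that does not photolyse directly (glutathione is the
default) is degraded by the reactive intermediates in parallel; each pathway
contributes a pseudo-first-order constant

    k_path = k_2nd(probe, species) x [species]_ss

and the fractions of the total tell which species drives the loss. GSH is
attacked by OH (3.5e9 M^-1 s^-1), CDOM triplets (8e7), the dibromide radical
(2e8) and the NO2 radical (~1e7, nitrosation to nitroso-GSH); the carbonate
radical and singlet oxygen channels are available for other probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .nox import NOxState
from .ppri import PPRIState

__all__ = ["ProbeReactivity", "Apportionment", "GSH", "apportion", "half_life"]

PATHWAYS = ("oh", "triplet", "br2_radical", "no2", "co3_radical", "singlet_oxygen")


@dataclass(frozen=True)
class ProbeReactivity:
    """Second-order rate constants (M^-1 s^-1) of one probe vs each species."""

    probe_id: str
    k_oh: float = 0.0
    k_triplet: float = 0.0
    k_br2: float = 0.0
    k_no2: float = 0.0
    k_co3: float = 0.0
    k_singlet: float = 0.0

    def __post_init__(self) -> None:
        ks = (self.k_oh, self.k_triplet, self.k_br2, self.k_no2,
              self.k_co3, self.k_singlet)
        if any(k < 0 for k in ks):
            raise ValidationError(f"{self.probe_id}: rate constants must be >= 0")
        if all(k == 0 for k in ks):
            raise ValidationError(f"{self.probe_id}: at least one rate constant must be > 0")


#: glutathione: no direct photolysis; the NO2 constant is an order-of-magnitude
#: literature estimate (1e7) and can be overridden per probe.
GSH = ProbeReactivity("GSH", k_oh=3.5e9, k_triplet=8e7, k_br2=2e8, k_no2=1e7)


@dataclass(frozen=True)
class Apportionment:
    """Per-pathway pseudo-first-order constants and their shares."""

    probe_id: str
    rate_constants: dict[str, float]     # s^-1 per pathway
    fractions: dict[str, float]          # sum to 1 when total > 0
    total: float                         # s^-1
    defined: bool                        # False when every concentration is zero

    @property
    def half_life_s(self) -> float:
        return half_life(self)


def apportion(probe: ProbeReactivity, ppri: PPRIState, nox: NOxState) -> Apportionment:
    """Split the probe's phototransformation among the reactive species.

    The NO2 concentration is taken from the exact steady-state solution.
    When every pathway rate is zero the fractions are undefined and flagged.
    """
    concentrations = {
        "oh": ppri.oh,
        "triplet": ppri.triplet,
        "br2_radical": ppri.br2_radical,
        "no2": nox.no2_exact,
        "co3_radical": ppri.co3_radical,
        "singlet_oxygen": ppri.singlet_oxygen,
    }
    seconds_order = {
        "oh": probe.k_oh,
        "triplet": probe.k_triplet,
        "br2_radical": probe.k_br2,
        "no2": probe.k_no2,
        "co3_radical": probe.k_co3,
        "singlet_oxygen": probe.k_singlet,
    }
    rate_constants = {p: seconds_order[p] * concentrations[p] for p in PATHWAYS}
    total = sum(rate_constants.values())
    if total > 0:
        fractions = {p: k / total for p, k in rate_constants.items()}
        defined = True
    else:
        fractions = {p: math.nan for p in PATHWAYS}
        defined = False
    return Apportionment(probe_id=probe.probe_id, rate_constants=rate_constants,
                         fractions=fractions, total=total, defined=defined)


def half_life(apportionment: Apportionment) -> float:
    """ln 2 over the total pseudo-first-order constant; inf when total is 0."""
    if apportionment.total <= 0:
        return math.inf
    return math.log(2.0) / apportionment.total
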