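"""Rate constants and photophysical parameters of the kinetic model.

Every named second-order/first-order rate constant used anywhere in the model
lives in :class:`RateConstantSet`, together with the photophysical parameters
of the photochemical core (quantum yields, triplet/singlet loss constants,
solvent-cage enhancement parameters). Defaults are the literature values the
model is built on; every one of them can be overridden from a config mapping
via :meth:`RateConstantSet.with_overrides`.

Units
-----
Second-order constants are M^-1 s^-1 except the DOM ones, which are per unit
dissolved organic carbon (L mg_C^-1 s^-1) because DOM has no molar mass.
First-order constants are s^-1. Quantum yields are dimensionless (mol per
einstein absorbed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError

__all__ = ["RateConstantSet", "phenol_rate_to_per_mgC", "PHENOL_CARBON_G_PER_MOL"]

#: Carbon content of phenol (C6H5OH): 6 x 12 g C per mole.
PHENOL_CARBON_G_PER_MOL = 72.0


def phenol_rate_to_per_mgC(k_molar: float = 1e4,
                           carbon_g_per_mol: float = PHENOL_CARBON_G_PER_MOL) -> float:
    """Convert a per-molar rate constant into a per-mg-carbon basis.

    DOM is quantified by its carbon mass, not by moles, so a rate constant
    measured against a model compound (phenol, k ~ 1e4 M^-1 s^-1 for NO2
    radical) is mapped onto DOM by dividing by the compound's carbon content:

        k [M^-1 s^-1] / (carbon g_C mol^-1 * 1000 mg g^-1)  ->  L mg_C^-1 s^-1

    With the defaults this gives 0.14 L mg_C^-1 s^-1 (2 s.f.), the DOM
    scavenging constant used for the NO2 radical throughout the model.
    """
    if k_molar < 0 or carbon_g_per_mol <= 0:
        raise ValidationError("rate constant must be >= 0 and carbon content > 0")
    return k_molar / (carbon_g_per_mol * 1000.0)


@dataclass(frozen=True)
class RateConstantSet:
    # --- NO2 radical / N2O4 core ------------------------------------------
    #: NO2- + OH -> NO2 radical + OH-
    k2_OH_nitrite: float = 1e10
    #: 2 NO2 <-> N2O4 dimerization (forward / reverse)
    k3_dimerization: float = 4.5e8
    k_minus3: float = 6.9e3
    #: N2O4 + H2O -> NO3- + NO2- + 2 H+
    k5_hydrolysis: float = 1e3
    #: NO2 radical + DOM, per mg_C (from phenol k ~ 1e4 M^-1 s^-1 / 72 g_C mol^-1)
    k4_NO2_DOM: float = 0.14

    # --- OH radical scavengers --------------------------------------------
    #: OH + DOM; literature range (2-5)e4 L mg_C^-1 s^-1
    k_OH_DOM: float = 5.0e4
    k_OH_HCO3: float = 8.5e6
    k_OH_CO3: float = 3.9e8
    k_OH_Br: float = 1.1e10

    # --- dibromide radical (Br2 radical anion) -----------------------------
    k_Br2_NO2: float = 2e7          # Br2- + NO2- -> NO2 radical
    k_Br2_dimer: float = 1.8e9      # 2 Br2- -> Br2 + 2 Br-
    k_Br2_DOM: float = 3e2          # Br2- + DOM, per mg_C

    # --- carbonate radical --------------------------------------------------
    k_CO3_DOM: float = 1e2          # CO3- + DOM, per mg_C (literature order)
    k_3CDOM_CO3: float = 1e5        # 3CDOM* + CO3^2- -> CO3- (literature order)

    # --- triplet pathway to NO2 radical (upper limit, off by default) -------
    k_3CDOM_NO2_upper: float = 1e9

    # --- photophysics of the photochemical core ----------------------------
    #: OH (and NO2 radical, 1:1) quantum yield of nitrate photolysis at zero
    #: inorganic carbon; multiplied by the solvent-cage enhancement factor.
    #: Literature 0.009-0.017; warm-surface-water end of the range.
    phi_OH_nitrate: float = 0.015
    #: solvent-cage enhancement: f = 1 + delta * c_IC / (c_half + c_IC)
    cage_delta: float = 1.0
    cage_half_M: float = 1e-3
    #: OH quantum yield of nitrite photolysis (literature 0.025-0.065)
    phi_OH_nitrite: float = 0.025
    #: apparent OH yield of CDOM per absorbed photon (literature ~1e-6..1e-4)
    phi_OH_CDOM: float = 5e-6
    #: intersystem-crossing yield of CDOM triplets and their total loss rate
    phi_ISC: float = 0.01
    k_triplet_loss: float = 1e6
    #: fraction of triplet decays transferring to O2 -> singlet oxygen, and
    #: the solvent-collision loss constant of singlet oxygen in water
    f_delta: float = 0.5
    k_singlet_loss: float = 2.5e5

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 0:
                raise ValidationError(f"{field.name} must be >= 0")

    def with_overrides(self, overrides: Mapping[str, float] | None = None,
                       **kwargs: float) -> "RateConstantSet":
        """Return a copy with the given constants replaced.

        Unknown names raise ``ValidationError`` (catching config typos beats
        silently running with a default).
        """
        merged = dict(overrides or {})
        merged.update(kwargs)
        valid = {f.name for f in dataclasses.fields(self)}
        unknown = set(merged) - valid
        if unknown:
            raise ValidationError(
                f"unknown rate constant(s): {sorted(unknown)}; valid names: {sorted(valid)}")
        # YAML 1.1 parses bare exponents like 2.5e4 as strings; coerce here
        try:
            merged = {name: float(value) for name, value in merged.items()}
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"rate constant overrides must be numeric: {exc}") from exc
        return dataclasses.replace(self, **merged)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)
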