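"""Water-chemistry scenarios.

A :class:`WaterScenario` is the full physical/chemical state of one well-mixed
water body: photoactive anions (nitrate, nitrite), dissolved organic carbon,
the inorganic-carbon pair, bromide, the water-column depth and the incident
UV (290-400 nm) irradiance. Internally everything is SI-molar (mol L^-1)
except DOC (mg_C L^-1), depth (m) and irradiance (W m^-2); the
:meth:`WaterScenario.from_user_units` constructor accepts the field-customary
units (uM for nitrate/nitrite/carbonate, mM for bicarbonate/bromide).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["WaterScenario"]


@dataclass(frozen=True)
class WaterScenario:
    """Chemical and physical state of one sunlit water column.

    Parameters
    ----------
    nitrate, nitrite : float
        Concentrations in M.
    doc : float
        Dissolved organic carbon in mg_C L^-1.
    bicarbonate, carbonate, bromide : float
        Concentrations in M.
    depth : float
        Well-mixed water-column depth in m (> 0).
    uv_irradiance : float
        Incident UV irradiance integrated over 290-400 nm, W m^-2.
    """

    nitrate: float = 0.0
    nitrite: float = 0.0
    doc: float = 1.0
    bicarbonate: float = 0.0
    carbonate: float = 0.0
    bromide: float = 0.0
    depth: float = 5.0
    uv_irradiance: float = 22.0

    def __post_init__(self) -> None:
        for name in ("nitrate", "nitrite", "doc", "bicarbonate", "carbonate",
                     "bromide", "uv_irradiance"):
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")
        if self.depth <= 0:
            raise ValidationError(f"depth must be > 0 m, got {self.depth!r}")

    @classmethod
    def from_user_units(cls, *, nitrate_uM: float = 0.0, nitrite_uM: float = 0.0,
                        doc_mgC_L: float = 1.0, bicarbonate_mM: float = 0.0,
                        carbonate_uM: float = 0.0, bromide_mM: float = 0.0,
                        depth_m: float = 5.0,
                        uv_irradiance_W_m2: float = 22.0) -> "WaterScenario":
        """Build a scenario from the units concentrations are usually quoted in."""
        return cls(
            nitrate=nitrate_uM * 1e-6,
            nitrite=nitrite_uM * 1e-6,
            doc=doc_mgC_L,
            bicarbonate=bicarbonate_mM * 1e-3,
            carbonate=carbonate_uM * 1e-6,
            bromide=bromide_mM * 1e-3,
            depth=depth_m,
            uv_irradiance=uv_irradiance_W_m2,
        )

    def replace(self, **changes: float) -> "WaterScenario":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_user_units(self) -> dict[str, float]:
        """Echo the scenario in user-facing units (for logs and metadata)."""
        return {
            "nitrate_uM": self.nitrate * 1e6,
            "nitrite_uM": self.nitrite * 1e6,
            "doc_mgC_L": self.doc,
            "bicarbonate_mM": self.bicarbonate * 1e3,
            "carbonate_uM": self.carbonate * 1e6,
            "bromide_mM": self.bromide * 1e3,
            "depth_m": self.depth,
            "uv_irradiance_W_m2": self.uv_irradiance,
        }
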