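"""Wavelength-resolved photon field and depth-averaged photon absorption.

The photochemical core needs, for every light-absorbing species (nitrate,
nitrite, CDOM), the volumetric rate at which it absorbs photons in a
well-mixed column of given depth. The treatment is single-beam Lambert-Beer
competition: at each wavelength the column absorbs a fraction
``1 - 10^-A(lambda)`` of the incident photon flux, and each absorber takes a
share proportional to its decadic absorption coefficient. Integrating over
290-400 nm and dividing by depth gives einstein L^-1 s^-1 per species.

The default solar spectrum is a clear-sky mid-latitude summer surface UV
spectrum on a 1 nm grid, generated from a documented parameterization
(extraterrestrial baseline x ozone Huggins-band, Rayleigh and aerosol
attenuation) and always rescaled so its 290-400 nm integral matches the
requested irradiance — only its shape matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import RateConstantSet
from .errors import ValidationError
from .scenario import WaterScenario

__all__ = [
    "SpectrumTable",
    "AbsorberSpectrum",
    "PhotonField",
    "WAVELENGTH_GRID_NM",
    "build_default_solar_spectrum",
    "load_spectrum_csv",
    "cdom_absorption",
    "nitrate_molar_absorption",
    "nitrite_molar_absorption",
    "default_absorber_spectra",
    "depth_averaged_absorbed_photons",
]

PLANCK_J_S = 6.62607015e-34
C_LIGHT_M_S = 2.99792458e8
AVOGADRO = 6.02214076e23

#: native wavelength grid, 290-400 nm at 1 nm
WAVELENGTH_GRID_NM = np.arange(290.0, 401.0, 1.0)

# CDOM absorption parameterization: a(lambda) = A450 * DOC * exp(-S*(lambda-450))
# in m^-1, a widely used natural-water form (exponential spectral slope
# referenced to 450 nm, linear in DOC).
CDOM_A450_PER_M = 0.45
CDOM_SLOPE_PER_NM = 0.015

# Gaussian band fits to the standard literature absorption spectra:
# nitrate n->pi* band (peak 302 nm, eps ~ 7.2 M^-1 cm^-1), nitrite band
# (peak 354 nm, eps ~ 22.7 M^-1 cm^-1).
_NITRATE_PEAK_NM, _NITRATE_EPS_MAX, _NITRATE_WIDTH_NM = 302.0, 7.2, 20.0
_NITRITE_PEAK_NM, _NITRITE_EPS_MAX, _NITRITE_WIDTH_NM = 354.0, 22.7, 26.0


def _photon_flux_from_irradiance(wavelength_nm: np.ndarray,
                                 irradiance_W_m2_nm: np.ndarray) -> np.ndarray:
    """einstein cm^-2 s^-1 nm^-1 from W m^-2 nm^-1 via E_photon = hc/lambda."""
    energy_per_einstein = PLANCK_J_S * C_LIGHT_M_S * AVOGADRO / (wavelength_nm * 1e-9)
    return irradiance_W_m2_nm / energy_per_einstein / 1e4


@dataclass(frozen=True)
class SpectrumTable:
    """Spectral irradiance and the matching photon flux on the native grid."""

    wavelength_nm: np.ndarray
    spectral_irradiance: np.ndarray       # W m^-2 nm^-1
    spectral_photon_flux: np.ndarray      # einstein cm^-2 s^-1 nm^-1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be 1-D and strictly increasing")
        if np.any(self.spectral_irradiance < 0) or np.any(self.spectral_photon_flux < 0):
            raise ValidationError("spectral values must be >= 0")

    @classmethod
    def from_irradiance(cls, wavelength_nm: np.ndarray,
                        irradiance_W_m2_nm: np.ndarray) -> "SpectrumTable":
        wl = np.asarray(wavelength_nm, dtype=float)
        irr = np.asarray(irradiance_W_m2_nm, dtype=float)
        return cls(wl, irr, _photon_flux_from_irradiance(wl, irr))

    @property
    def integrated_irradiance(self) -> float:
        """Trapezoid integral of the irradiance over the grid, W m^-2."""
        return float(np.trapezoid(self.spectral_irradiance, self.wavelength_nm))

    def scaled(self, factor: float) -> "SpectrumTable":
        return SpectrumTable(self.wavelength_nm,
                             self.spectral_irradiance * factor,
                             self.spectral_photon_flux * factor)


@dataclass(frozen=True)
class AbsorberSpectrum:
    """Absorption (and optionally quantum-yield) spectrum of one species.

    ``molar_absorption`` is the decadic coefficient in M^-1 cm^-1 for the
    dissolved anions; for CDOM it is instead a *specific* absorption in
    (mg_C L^-1)^-1 cm^-1 (DOM has no molar mass). Exactly one of the two
    conventions applies per species and ``is_specific`` records which.
    """

    species_id: str
    wavelength_nm: np.ndarray
    molar_absorption: np.ndarray
    is_specific: bool = False
    quantum_yield: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.molar_absorption < 0):
            raise ValidationError(f"{self.species_id}: absorption must be >= 0")
        if self.quantum_yield is not None:
            qy = np.asarray(self.quantum_yield)
            if np.any(qy < 0) or np.any(qy > 1):
                raise ValidationError(f"{self.species_id}: quantum yield must lie in [0,1]")

    def absorbance_per_cm(self, concentration: float) -> np.ndarray:
        """Decadic absorbance per cm at the given concentration (M or mg_C/L)."""
        return self.molar_absorption * concentration


@dataclass(frozen=True)
class PhotonField:
    """Depth-averaged volumetric photon absorption, per species and total."""

    rates: Mapping[str, float]            # einstein L^-1 s^-1
    total: float                          # einstein L^-1 s^-1
    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total < 0 or any(v < 0 for v in self.rates.values()):
            raise ValidationError("absorbed-photon rates must be >= 0")


# ---------------------------------------------------------------------------
# Default solar spectrum
# ---------------------------------------------------------------------------

# Extraterrestrial spectral-irradiance anchors (W m^-2 nm^-1), interpolated.
_ET_WL = np.array([290.0, 300, 310, 320, 330, 340, 350, 360, 370, 380, 390, 400])
_ET_E = np.array([0.48, 0.51, 0.69, 0.83, 1.06, 1.07, 1.10, 1.07, 1.18, 1.12, 1.10, 1.43])

_OZONE_SIGMA_290_CM2 = 1.5e-18   # Huggins-band cross-section at 290 nm
_OZONE_DECAY_NM = 6.6            # exponential decay length of the cross-section
_OZONE_COLUMN_CM2 = 8.1e18       # 300 Dobson units
_AIRMASS = 1.2                   # high summer sun
_AEROSOL_TAU_400 = 0.15          # moderate continental aerosol, vertical


def _reference_shape(wavelength_nm: np.ndarray) -> np.ndarray:
    """Clear-sky surface spectral irradiance shape (arbitrary absolute scale)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    et = np.interp(wl, _ET_WL, _ET_E)
    tau_ozone = (_OZONE_SIGMA_290_CM2 * np.exp(-(wl - 290.0) / _OZONE_DECAY_NM)
                 * _OZONE_COLUMN_CM2 * _AIRMASS)
    tau_rayleigh = 0.008735 * (wl / 1e3) ** -4.08 * _AIRMASS
    tau_aerosol = _AEROSOL_TAU_400 * (wl / 400.0) ** -1.3 * _AIRMASS
    return et * np.exp(-(tau_ozone + tau_rayleigh + tau_aerosol))


def build_default_solar_spectrum(uv_irradiance_target: float = 22.0) -> SpectrumTable:
    """Default surface solar spectrum rescaled to the requested UV irradiance.

    Parameters
    ----------
    uv_irradiance_target : float
        Integral of the returned spectral irradiance over 290-400 nm, W m^-2.
        22 W m^-2 corresponds to fair-weather mid-July at 45 deg N, mid-morning
        or mid-afternoon.
    """
    if uv_irradiance_target < 0:
        raise ValidationError("uv_irradiance_target must be >= 0")
    shape = _reference_shape(WAVELENGTH_GRID_NM)
    integral = np.trapezoid(shape, WAVELENGTH_GRID_NM)
    scaled = shape * (uv_irradiance_target / integral)
    return SpectrumTable.from_irradiance(WAVELENGTH_GRID_NM, scaled)


def load_spectrum_csv(path: str, uv_irradiance_target: float | None = None) -> SpectrumTable:
    """Load a spectral-irradiance table and resample it onto the native grid.

    The file must have a header with columns ``wavelength_nm`` and
    ``irradiance_W_m2_nm`` (extra columns, e.g. ``quantum_yield``, are
    ignored here). If ``uv_irradiance_target`` is given the spectrum is
    rescaled to that 290-400 nm integral.
    """
    table = pd.read_csv(path)
    required = {"wavelength_nm", "irradiance_W_m2_nm"}
    if not required.issubset(table.columns):
        raise ValidationError(f"spectrum file needs columns {sorted(required)}, "
                              f"found {list(table.columns)}")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValidationError("spectrum wavelengths must be strictly increasing")
    irr = np.interp(WAVELENGTH_GRID_NM, wl, table["irradiance_W_m2_nm"].to_numpy(dtype=float),
                    left=0.0, right=0.0)
    if uv_irradiance_target is not None:
        if uv_irradiance_target < 0:
            raise ValidationError("uv_irradiance_target must be >= 0")
        integral = np.trapezoid(irr, WAVELENGTH_GRID_NM)
        if integral > 0:
            irr = irr * (uv_irradiance_target / integral)
    return SpectrumTable.from_irradiance(WAVELENGTH_GRID_NM, irr)


# ---------------------------------------------------------------------------
# Absorbers
# ---------------------------------------------------------------------------

def cdom_absorption(doc: float, wavelength_nm: np.ndarray | float,
                    a450_per_m: float = CDOM_A450_PER_M,
                    slope_per_nm: float = CDOM_SLOPE_PER_NM) -> np.ndarray | float:
    """CDOM decadic absorbance per cm: ``a450 * DOC * exp(-S (lambda-450)) / 100``.

    Linear in DOC, exponentially decreasing in wavelength (spectral slope S,
    default 0.015 nm^-1, referenced to 450 nm).
    """
    if doc < 0:
        raise ValidationError("DOC must be >= 0")
    wl = np.asarray(wavelength_nm, dtype=float)
    out = a450_per_m * doc * np.exp(-slope_per_nm * (wl - 450.0)) / 100.0
    return out if out.ndim else float(out)


def nitrate_molar_absorption(wavelength_nm: np.ndarray) -> np.ndarray:
    """Nitrate n->pi* band, Gaussian fit to the literature spectrum (M^-1 cm^-1)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    return _NITRATE_EPS_MAX * np.exp(-(((wl - _NITRATE_PEAK_NM) / _NITRATE_WIDTH_NM) ** 2))


def nitrite_molar_absorption(wavelength_nm: np.ndarray) -> np.ndarray:
    """Nitrite absorption band, Gaussian fit to the literature spectrum (M^-1 cm^-1)."""
    wl = np.asarray(wavelength_nm, dtype=float)
    return _NITRITE_EPS_MAX * np.exp(-(((wl - _NITRITE_PEAK_NM) / _NITRITE_WIDTH_NM) ** 2))


def default_absorber_spectra(constants: RateConstantSet | None = None
                             ) -> dict[str, AbsorberSpectrum]:
    """The three light absorbers of the model on the native grid."""
    del constants  # quantum yields are wavelength-independent, kept in RateConstantSet
    wl = WAVELENGTH_GRID_NM
    return {
        "nitrate": AbsorberSpectrum("nitrate", wl, nitrate_molar_absorption(wl)),
        "nitrite": AbsorberSpectrum("nitrite", wl, nitrite_molar_absorption(wl)),
        "cdom": AbsorberSpectrum("cdom", wl, cdom_absorption(1.0, wl), is_specific=True),
    }


# ---------------------------------------------------------------------------
# Depth-averaged absorption
# ---------------------------------------------------------------------------

def depth_averaged_absorbed_photons(scenario: WaterScenario,
                                    spectra: Mapping[str, AbsorberSpectrum] | None = None,
                                    solar: SpectrumTable | None = None) -> PhotonField:
    """Volumetric photon absorption rate of each species in the mixed column.

    At each wavelength the column of depth ``d`` absorbs a fraction
    ``1 - 10^-(a_tot d)`` of the incident photon flux ``p0``; species ``i``
    takes the share ``a_i / a_tot``. The volumetric rate is

        rate_i = integral p0 (1 - 10^-A) (a_i/a_tot) dlambda / d_cm * 1000

    in einstein L^-1 s^-1 (1000 cm^3 per litre). The per-species rates
    partition the total exactly.
    """
    if spectra is None:
        spectra = default_absorber_spectra()
    if solar is None:
        solar = build_default_solar_spectrum(scenario.uv_irradiance)

    wl = solar.wavelength_nm
    concentrations = {
        "nitrate": scenario.nitrate,
        "nitrite": scenario.nitrite,
        "cdom": scenario.doc,
    }
    absorbance = {}
    for name, spectrum in spectra.items():
        conc = concentrations.get(name, 0.0)
        if spectrum.wavelength_nm.shape != wl.shape or np.any(spectrum.wavelength_nm != wl):
            raise ValidationError(f"absorber {name!r} is not on the solar grid; "
                                  "resample it when loading")
        absorbance[name] = spectrum.absorbance_per_cm(conc)

    depth_cm = scenario.depth * 100.0
    a_total = np.sum(list(absorbance.values()), axis=0)
    column_absorbance = a_total * depth_cm
    absorbed_fraction = -np.expm1(-np.log(10.0) * column_absorbance)  # 1 - 10^-A

    p0 = solar.spectral_photon_flux
    rates: dict[str, float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, a_i in absorbance.items():
            share = np.where(a_total > 0, a_i / np.where(a_total > 0, a_total, 1.0), 0.0)
            integrand = p0 * absorbed_fraction * share
            rates[name] = float(np.trapezoid(integrand, wl) / depth_cm * 1000.0)
    total = float(sum(rates.values()))
    fractions = {name: (r / total if total > 0 else 0.0) for name, r in rates.items()}
    return PhotonField(rates=rates, total=total, fractions=fractions)
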