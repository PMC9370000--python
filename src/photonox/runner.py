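"""Scenario presets, single runs, grid sweeps and figure-style tables.

The presets encode the scenario studies the model was built around: a
freshwater base case (5 m column, 1 mM bicarbonate, 10 uM carbonate,
1 mg_C L^-1 DOC, 22 W m^-2 UV), the nitrate/nitrite equal-contribution point
(11 uM / 0.85 uM), a seawater case (0.8 mM bromide), a brackish Rhone-delta
lagoon (~50 uM nitrate, DOC 4.5), and a flooded rice field (DOC ~ 12).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import __version__
from .constants import RateConstantSet
from .errors import ValidationError
from .nox import NOxSourceOptions, NOxState, solve_nox
from .ppri import PPRIState, compute_ppri
from .probes import GSH, Apportionment, ProbeReactivity, apportion
from .scenario import WaterScenario

__all__ = [
    "PRESETS", "preset", "evaluate", "GridSpec", "run_grid",
    "source_crossover", "figure_table",
]

_U = WaterScenario.from_user_units

PRESETS: dict[str, WaterScenario] = {
    # nitrate/nitrite grid base: 5 m, 1 mM HCO3-, 10 uM CO3^2-, DOC 1, 22 W/m2
    "fig3_base": _U(nitrate_uM=100.0, nitrite_uM=1.0, doc_mgC_L=1.0,
                    bicarbonate_mM=1.0, carbonate_uM=10.0),
    # equal nitrate/nitrite contribution point for the inorganic-carbon sweep
    "fig5_base": _U(nitrate_uM=11.0, nitrite_uM=0.85, doc_mgC_L=1.0,
                    bicarbonate_mM=1.0, carbonate_uM=10.0),
    # bromide sweep base
    "fig7_base": _U(nitrate_uM=100.0, nitrite_uM=1.0, doc_mgC_L=1.0,
                    bicarbonate_mM=1.0, carbonate_uM=10.0),
    "freshwater": _U(nitrate_uM=100.0, nitrite_uM=1.0, doc_mgC_L=1.0,
                     bicarbonate_mM=1.0, carbonate_uM=10.0),
    # brackish Rhone-delta lagoon: ~50 uM nitrate, DOC 4-5 (midpoint),
    # nitrite at the common 1% of nitrate, bromide at half-seawater salinity
    "rhone_lagoon": _U(nitrate_uM=50.0, nitrite_uM=0.5, doc_mgC_L=4.5,
                       bicarbonate_mM=1.0, carbonate_uM=10.0, bromide_mM=0.4),
    # flooded rice field: DOC ~ 12, no marine bromide
    "rice_field": _U(nitrate_uM=50.0, nitrite_uM=0.5, doc_mgC_L=12.0,
                     bicarbonate_mM=1.0, carbonate_uM=10.0),
    # seawater: [Br-] = 0.8 mM
    "seawater": _U(nitrate_uM=100.0, nitrite_uM=1.0, doc_mgC_L=1.0,
                   bicarbonate_mM=1.0, carbonate_uM=10.0, bromide_mM=0.8),
}


def preset(name: str) -> WaterScenario:
    """Look up a named scenario preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}") from None


def evaluate(scenario: WaterScenario,
             options: NOxSourceOptions | None = None,
             constants: RateConstantSet | None = None,
             probe: ProbeReactivity | None = None
             ) -> tuple[PPRIState, NOxState, Apportionment]:
    """Full pipeline on one scenario: PPRI budget, NOx steady state, probe."""
    constants = constants or RateConstantSet()
    ppri = compute_ppri(scenario, constants)
    nox = solve_nox(ppri, scenario, options, constants)
    app = apportion(probe or GSH, ppri, nox)
    return ppri, nox, app


def _result_row(scenario: WaterScenario, ppri: PPRIState, nox: NOxState,
                app: Apportionment) -> dict[str, float]:
    row: dict[str, float] = dict(scenario.to_user_units())
    row.update({
        "OH_M": ppri.oh,
        "CO3_radical_M": ppri.co3_radical,
        "triplet_CDOM_M": ppri.triplet,
        "singlet_O2_M": ppri.singlet_oxygen,
        "Br2_radical_M": ppri.br2_radical,
        "R_OH_total_M_s": ppri.oh_budget.total_formation,
        "OH_scavenging_s": ppri.oh_budget.scavenging_capacity,
        "R_photolysis": nox.r_photolysis,
        "R_OH_pathway": nox.r_oh_pathway,
        "R_Br2_pathway": nox.r_br2_pathway,
        "R_triplet_pathway": nox.r_triplet_pathway,
        "R_total": nox.r_total,
        "NO2_exact_M": nox.no2_exact,
        "NO2_simplified_M": nox.no2_simplified,
        "N2O4_M": nox.n2o4,
        "deviation_permil": nox.deviation_permil,
        "log10_ratio_NO2_N2O4": nox.log10_ratio_no2_n2o4,
        "probe_k_total_s": app.total,
        "probe_half_life_s": app.half_life_s,
    })
    for pathway, k in app.rate_constants.items():
        row[f"probe_k_{pathway}_s"] = k
    for pathway, frac in app.fractions.items():
        row[f"probe_frac_{pathway}"] = frac
    return row


@dataclass(frozen=True)
class GridSpec:
    """One- or two-parameter sweep over WaterScenario fields.

    ``sweeps`` maps field names (internal units: M, mg_C/L, m, W/m2) to value
    lists; the cartesian product is evaluated outer x inner in the given
    order (deterministic row order).
    """

    base: WaterScenario
    sweeps: dict[str, list[float]]
    options: NOxSourceOptions = field(default_factory=NOxSourceOptions)
    probe: ProbeReactivity = GSH

    def __post_init__(self) -> None:
        if not 1 <= len(self.sweeps) <= 2:
            raise ValidationError("GridSpec supports one or two swept parameters")
        valid = set(WaterScenario().__dataclass_fields__)
        for name, values in self.sweeps.items():
            if name not in valid:
                raise ValidationError(f"{name!r} is not a WaterScenario field")
            if len(values) == 0:
                raise ValidationError(f"sweep over {name!r} has no values")


def run_grid(spec: GridSpec,
             constants: RateConstantSet | None = None) -> pd.DataFrame:
    """Evaluate every grid point; one flattened result row per point.

    Run metadata (constants, package version, sweep definition) is attached
    as ``DataFrame.attrs['metadata']``.
    """
    constants = constants or RateConstantSet()
    names = list(spec.sweeps)
    rows = []
    for combo in itertools.product(*(spec.sweeps[n] for n in names)):
        changes = dict(zip(names, combo))
        try:
            scenario = spec.base.replace(**changes)
            ppri, nox, app = evaluate(scenario, spec.options, constants, spec.probe)
        except ValidationError as exc:
            raise ValidationError(f"grid point {changes!r}: {exc}") from exc
        rows.append(_result_row(scenario, ppri, nox, app))
    table = pd.DataFrame(rows)
    table.attrs["metadata"] = {
        "photonox_version": __version__,
        "constants": constants.as_dict(),
        "sweeps": {n: list(map(float, v)) for n, v in spec.sweeps.items()},
        "base_scenario": spec.base.to_user_units(),
        "sources": {
            "nitrate_photolysis": spec.options.include_nitrate_photolysis,
            "nitrite_oh": spec.options.include_nitrite_oh,
            "nitrite_br2": spec.options.include_nitrite_br2,
            "nitrite_triplet_upper_limit":
                spec.options.include_nitrite_triplet_upper_limit,
        },
        "probe": spec.probe.probe_id,
    }
    return table


def source_crossover(base: WaterScenario,
                     nitrite_range: tuple[float, float] = (1e-9, 1e-4),
                     constants: RateConstantSet | None = None,
                     tol: float = 1e-6) -> dict[str, float]:
    """Nitrite level at which both baseline NO2 sources contribute equally.

    Bisects on nitrite until |log10(R_photolysis / R_OH_pathway)| < tol,
    re-running the full photochemical core at each trial (nitrite screens
    light and scavenges OH, so the photolysis term also shifts). Returns the
    crossover nitrite and the nitrate:nitrite ratio there.
    """
    if base.nitrate <= 0:
        raise ValidationError("source_crossover needs nitrate > 0 in the base scenario")
    constants = constants or RateConstantSet()

    def log_ratio(nitrite: float) -> float:
        scenario = base.replace(nitrite=nitrite)
        ppri = compute_ppri(scenario, constants)
        nox = solve_nox(ppri, scenario, NOxSourceOptions(), constants)
        if nox.r_oh_pathway == 0:
            return np.inf
        return np.log10(nox.r_photolysis / nox.r_oh_pathway)

    lo, hi = nitrite_range
    f_lo, f_hi = log_ratio(lo), log_ratio(hi)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi > 0:
        raise ValidationError(
            f"no sign change of log10(R_photolysis/R_OH) over nitrite range "
            f"{nitrite_range}: endpoints {f_lo:.3g}, {f_hi:.3g}")
    crossing = brentq(log_ratio, lo, hi, xtol=lo * 1e-6, rtol=8.9e-16)
    residual = abs(log_ratio(crossing))
    if residual >= tol:
        raise RuntimeError(f"crossover root not converged: |log-ratio| = {residual:.3g}")
    return {"nitrite_M": float(crossing),
            "nitrite_uM": float(crossing) * 1e6,
            "nitrate_to_nitrite_ratio": base.nitrate / float(crossing)}


# ---------------------------------------------------------------------------
# Figure-style tables
# ---------------------------------------------------------------------------

def _log_space(lo: float, hi: float, n: int) -> list[float]:
    return list(np.logspace(np.log10(lo), np.log10(hi), n))


def figure_table(name: str, n: int = 10,
                 constants: RateConstantSet | None = None) -> pd.DataFrame:
    """Emit one of the canonical scenario-study grids as a table.

    ``fig3``: nitrate (1-100 uM) x nitrite (0.01-1 uM) at the freshwater base.
    ``fig5``: bicarbonate (0.01-10 mM) x carbonate (0.1-100 uM) at the
    equal-contribution base. ``fig6``: DOC (0.5-20) x nitrate, nitrite locked
    to 1% of nitrate, with and without the upper-limit triplet source.
    ``fig7``: bromide (0.001-1 mM) at DOC 1 and 2, with and without the
    dibromide source. ``fig9``: GSH apportionment vs DOC (freshwater) and vs
    bromide (dibromide source on).
    """
    constants = constants or RateConstantSet()
    if name == "fig3":
        spec = GridSpec(preset("fig3_base"),
                        {"nitrate": _log_space(1e-6, 1e-4, n),
                         "nitrite": _log_space(1e-8, 1e-6, n)})
        return run_grid(spec, constants)
    if name == "fig5":
        spec = GridSpec(preset("fig5_base"),
                        {"bicarbonate": _log_space(1e-5, 1e-2, n),
                         "carbonate": _log_space(1e-7, 1e-4, n)})
        return run_grid(spec, constants)
    if name == "fig6":
        base = preset("fig3_base")
        frames = []
        for triplet_on in (False, True):
            options = NOxSourceOptions(include_nitrite_triplet_upper_limit=triplet_on)
            rows = []
            for nitrate in _log_space(1e-6, 1e-4, n):
                for doc in _log_space(0.5, 20.0, n):
                    scen = base.replace(nitrate=nitrate, nitrite=0.01 * nitrate,
                                        doc=doc)
                    ppri, nox, app = evaluate(scen, options, constants)
                    row = _result_row(scen, ppri, nox, app)
                    row["triplet_source_upper_limit"] = triplet_on
                    rows.append(row)
            frames.append(pd.DataFrame(rows))
        return pd.concat(frames, ignore_index=True)
    if name == "fig7":
        base = preset("fig7_base")
        frames = []
        for doc, br2_on in ((1.0, False), (1.0, True), (2.0, False)):
            spec = GridSpec(base.replace(doc=doc),
                            {"bromide": _log_space(1e-6, 1e-3, n)},
                            options=NOxSourceOptions(include_nitrite_br2=br2_on))
            table = run_grid(spec, constants)
            table["br2_source_enabled"] = br2_on
            frames.append(table)
        return pd.concat(frames, ignore_index=True)
    if name == "fig9":
        base = preset("fig7_base")
        doc_spec = GridSpec(base, {"doc": _log_space(0.5, 20.0, n)})
        br_spec = GridSpec(base, {"bromide": _log_space(1e-6, 1e-3, n)},
                           options=NOxSourceOptions(include_nitrite_br2=True))
        doc_table = run_grid(doc_spec, constants)
        doc_table["sweep"] = "doc"
        br_table = run_grid(br_spec, constants)
        br_table["sweep"] = "bromide"
        return pd.concat([doc_table, br_table], ignore_index=True)
    raise ValidationError(
        f"unknown figure table {name!r}; valid: fig3, fig5, fig6, fig7, fig9")
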