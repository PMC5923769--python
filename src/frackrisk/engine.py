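"""Deterministic exposure/risk core for the two residential scenarios.

Implements complete-mix dilution of a flowback spill into a reservoir,
chronic daily intakes for the ingestion / inhalation / dermal pathways,
chemical excess-lifetime cancer risk (linear low-dose, truncated at 1) and
hazard quotients, linear intake-based radionuclide risk, and the partitioned
totals.  Chemical and radionuclide results are never combined: they use
different slope-factor machinery and are reported separately throughout.

All dose/risk functions are plain arithmetic on scalars or numpy arrays, so
the Monte Carlo driver can push whole trial vectors through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .distributions import DistributionSpec, from_quantiles
from .registry import Contaminant, is_volatile

__all__ = [
    "ExposureFactors",
    "ScenarioConfig",
    "PathwayResult",
    "TrialResult",
    "PATHWAYS",
    "drinking_water_factors",
    "swimming_factors",
    "drinking_water_scenario",
    "swimming_scenario",
    "default_spill_distribution",
    "dilute",
    "ingestion_dose",
    "air_concentration",
    "inhalation_dose",
    "dermal_event_dose",
    "dermal_dose",
    "inhalation_slope_factor",
    "chemical_metrics",
    "radionuclide_metrics",
    "assess_contaminant",
    "totals",
]

PATHWAYS = ("ingestion", "inhalation", "dermal")

#: Spill-volume distribution fitted to the 194 reported spills that reached
#: water: lognormal with median 128 L and 95th percentile 114,900 L.
SPILL_MEDIAN_L = 128.0
SPILL_P95_L = 114_900.0
#: Largest spill volume in the source records; the synthetic generator
#: truncates at this ceiling.
SPILL_MAX_L = 350_000.0


def default_spill_distribution() -> DistributionSpec:
    return from_quantiles("lognormal", SPILL_MEDIAN_L, SPILL_P95_L)


@dataclass(frozen=True)
class ExposureFactors:
    """Scenario exposure factors (RAGS / Exposure Factors Handbook defaults).

    Units: body_weight kg; water_ingestion_rate L/day; air_inhalation_rate
    m3/day; exposure_frequency days/year; exposure_duration years; averaging
    times days; event times hours; skin_surface_area cm2; swim_ingestion_rate
    L/h; volatilization_factor L/m3; immersion_time_fraction dimensionless
    (fraction of the day spent immersed).
    """

    body_weight: float = 70.0
    water_ingestion_rate: float = 2.5
    air_inhalation_rate: float = 15.0
    exposure_frequency: float = 350.0
    exposure_duration: float = 30.0
    averaging_time_cancer: float = 70.0 * 365.0
    averaging_time_noncancer: float = 30.0 * 365.0
    shower_event_time: float = 43.0 / 60.0
    events_per_day: float = 1.0
    skin_surface_area: float = 20_900.0
    swim_event_time: float = 1.0
    swim_ingestion_rate: float = 0.05
    volatilization_factor: float = 0.5
    immersion_time_fraction: float = 43.0 / (60.0 * 24.0)

    def __post_init__(self) -> None:
        for f_ in (
            "body_weight",
            "water_ingestion_rate",
            "air_inhalation_rate",
            "exposure_frequency",
            "exposure_duration",
            "averaging_time_cancer",
            "averaging_time_noncancer",
            "skin_surface_area",
            "volatilization_factor",
        ):
            if not getattr(self, f_) > 0:
                raise ValueError(f"{f_} must be strictly positive")
        if self.exposure_frequency > 365:
            raise ValueError("exposure_frequency cannot exceed 365 days/year")


@dataclass(frozen=True)
class ScenarioConfig:
    """Which exposure setting applies and the receiving-water geometry."""

    scenario: str = "drinking_water"
    pond_volume: float = 44_000_000.0
    flowback_volume: float = 0.0
    target_cancer_risk: float = 1e-6
    target_hazard_index: float = 1.0
    spill_dist: DistributionSpec = field(default_factory=default_spill_distribution)

    def __post_init__(self) -> None:
        if self.scenario not in ("drinking_water", "swimming"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.pond_volume > 0:
            raise ValueError("pond_volume must be positive")
        if self.flowback_volume < 0:
            raise ValueError("flowback_volume cannot be negative")
        if not (self.target_cancer_risk > 0 and self.target_hazard_index > 0):
            raise ValueError("targets must be positive")


def drinking_water_factors() -> ExposureFactors:
    """Chronic residential tap-water defaults: 2.5 L/day ingestion, 15 m3/day
    inhalation of household air, 43-min daily full-body bathing contact."""
    return ExposureFactors()


def swimming_factors() -> ExposureFactors:
    """Daily 1-h swim: incidental ingestion 0.05 L/h, near-surface inhalation
    prorated from the daily rate over the event hour, full-body immersion."""
    return ExposureFactors(
        exposure_frequency=365.0,
        immersion_time_fraction=1.0 / 24.0,
    )


def drinking_water_scenario(**kw) -> ScenarioConfig:
    return ScenarioConfig(scenario="drinking_water", **kw)


def swimming_scenario(**kw) -> ScenarioConfig:
    return ScenarioConfig(scenario="swimming", **kw)


# ---------------------------------------------------------------------------
# dilution and pathway intakes
# ---------------------------------------------------------------------------


def dilute(c_flowback, v_flowback, v_pond):
    """Complete-mix concentration in the receiving water.

    C_w = C_flowback * V_flowback / V_pond; linear in both the flowback
    concentration and the spilled volume.
    """
    if np.any(np.asarray(v_pond) <= 0):
        raise ValueError("pond volume must be positive")
    if np.any(np.asarray(v_flowback) < 0) or np.any(np.asarray(c_flowback) < 0):
        raise ValueError("concentration and spill volume cannot be negative")
    return c_flowback * v_flowback / v_pond


def _water_intake_rate(f: ExposureFactors, scenario: ScenarioConfig) -> float:
    """Effective L/day ingested: direct tap-water intake, or incidental
    ingestion over the swim event."""
    if scenario.scenario == "swimming":
        return f.swim_ingestion_rate * f.swim_event_time
    return f.water_ingestion_rate


def _air_intake_rate(f: ExposureFactors, scenario: ScenarioConfig) -> float:
    """Effective m3/day inhaled in contact with the contaminated air."""
    if scenario.scenario == "swimming":
        return f.air_inhalation_rate * f.swim_event_time / 24.0
    return f.air_inhalation_rate


def _event_time(f: ExposureFactors, scenario: ScenarioConfig) -> float:
    return f.swim_event_time if scenario.scenario == "swimming" else f.shower_event_time


def _chronic_factor(
    f: ExposureFactors, *, cancer: bool, ed_years: float | None = None
) -> float:
    """EF*ED/(BW*AT): converts a per-exposure-day intake into a chronic daily
    intake per kg body weight.  Averaging times are fixed windows (lifetime
    for cancer; the scenario's reference window for noncancer), so every dose
    is linear in the exposure duration."""
    ed = f.exposure_duration if ed_years is None else ed_years
    at = f.averaging_time_cancer if cancer else f.averaging_time_noncancer
    return f.exposure_frequency * ed / (f.body_weight * at)


def ingestion_dose(c_w, f: ExposureFactors, scenario: ScenarioConfig, *,
                   cancer: bool = True, ed_years: float | None = None):
    """Chronic daily intake from water ingestion, mg/kg-day."""
    return c_w * _water_intake_rate(f, scenario) * _chronic_factor(f, cancer=cancer, ed_years=ed_years)


def air_concentration(c_w, f: ExposureFactors):
    """Average air concentration above/around the water, mg/m3 (or pCi/m3).

    Uses the fixed volatilization factor K = 0.0005 x 1000 L/m3 = 0.5 L/m3
    relating a volatile chemical's water concentration to its mean air
    concentration during household water use.
    """
    return c_w * f.volatilization_factor


def inhalation_dose(c_air, f: ExposureFactors, scenario: ScenarioConfig, *,
                    cancer: bool = True, ed_years: float | None = None):
    """Chronic daily intake from inhaled volatiles, mg/kg-day."""
    return c_air * _air_intake_rate(f, scenario) * _chronic_factor(f, cancer=cancer, ed_years=ed_years)


def dermal_event_dose(c_w, permeability: float, event_time_h: float):
    """Per-event absorbed dose per skin area, mg/cm2-event.

    DA_event = Kp [cm/h] x C_w [mg/cm3] x t_event [h]; the 1e-3 converts
    mg/L to mg/cm3.
    """
    return permeability * c_w * 1e-3 * event_time_h


def dermal_dose(c_w, c: Contaminant, f: ExposureFactors, scenario: ScenarioConfig, *,
                cancer: bool = True, ed_years: float | None = None):
    """Dermally absorbed dose, mg/kg-day; None if no permeability on record."""
    if c.dermal_permeability is None:
        return None
    da_event = dermal_event_dose(c_w, c.dermal_permeability, _event_time(f, scenario))
    return (
        da_event
        * f.skin_surface_area
        * f.events_per_day
        * _chronic_factor(f, cancer=cancer, ed_years=ed_years)
    )


def inhalation_slope_factor(c: Contaminant, f: ExposureFactors) -> float | None:
    """Inhalation slope factor derived from the inhalation unit risk:

    SF_inh = IUR [(ug/m3)^-1] x (BW / IR_air) x 1000 [ug/mg], (mg/kg-day)^-1.
    """
    if c.inhalation_unit_risk is None:
        return None
    return c.inhalation_unit_risk * (f.body_weight / f.air_inhalation_rate) * 1e3


# ---------------------------------------------------------------------------
# per-contaminant metrics
# ---------------------------------------------------------------------------


@dataclass
class PathwayResult:
    """One analyte-pathway outcome: the dose and whichever of risk/HQ applies."""

    analyte: str
    pathway: str
    dose: float | np.ndarray
    cancer_risk: float | np.ndarray | None = None
    hazard_quotient: float | np.ndarray | None = None


def _clip_risk(risk, clip: bool):
    return np.minimum(risk, 1.0) if clip else risk


def chemical_metrics(
    doses: Mapping[str, object],
    c: Contaminant,
    mode: str,
    f: ExposureFactors | None = None,
    *,
    clip: bool = True,
) -> list[PathwayResult]:
    """Turn per-pathway doses into risks (cancer) or hazard quotients.

    Cancer: risk = dose x SF_route, with SF_dermal = SF_oral / ABS_GI and
    SF_inh derived from the IUR; risks truncated at 1.  Noncancer:
    HQ = dose / RfD_route with RfD_dermal = RfD_oral x ABS_GI.  Pathways
    whose toxicity factor is absent are skipped.
    """
    if mode not in ("cancer", "noncancer"):
        raise ValueError("mode must be 'cancer' or 'noncancer'")
    f = f or ExposureFactors()
    gi = c.gi_absorption_fraction if c.gi_absorption_fraction is not None else 1.0
    out: list[PathwayResult] = []
    for pathway, dose in doses.items():
        if dose is None:
            continue
        if mode == "cancer":
            if pathway == "ingestion":
                sf = c.oral_slope_factor
            elif pathway == "dermal":
                sf = None if c.oral_slope_factor is None else c.oral_slope_factor / gi
            else:
                sf = inhalation_slope_factor(c, f)
            if sf is None:
                continue
            out.append(
                PathwayResult(c.name, pathway, dose, cancer_risk=_clip_risk(dose * sf, clip))
            )
        else:
            if c.oral_reference_dose is None:
                continue
            if pathway == "ingestion":
                rfd = c.oral_reference_dose
            elif pathway == "dermal":
                rfd = c.oral_reference_dose * gi
            else:
                # no inhalation reference concentrations on record for the
                # study's non-carcinogens; the pathway contributes no HQ
                continue
            out.append(PathwayResult(c.name, pathway, dose, hazard_quotient=dose / rfd))
    return out


def radionuclide_metrics(
    c_w,
    c: Contaminant,
    f: ExposureFactors,
    scenario: ScenarioConfig,
    *,
    ed_years: float | None = None,
    clip: bool = True,
) -> list[PathwayResult]:
    """Lifetime radionuclide cancer risk from linear intake equations.

    Ingestion/inhalation: lifetime activity intake (pCi) x slope factor
    (risk/pCi).  The dermal analogue is immersion: water concentration x the
    fraction of the day immersed x years of exposure x an immersion risk
    coefficient (risk/year per pCi/L).  Results carry cancer risk only and
    are never merged into chemical totals.
    """
    if not c.is_radionuclide:
        raise ValueError(f"{c.name} is not a radionuclide")
    ed = f.exposure_duration if ed_years is None else ed_years
    out: list[PathwayResult] = []
    if c.rad_ingestion_sf is not None:
        intake = c_w * _water_intake_rate(f, scenario) * f.exposure_frequency * ed
        out.append(
            PathwayResult(
                c.name, "ingestion", intake,
                cancer_risk=_clip_risk(intake * c.rad_ingestion_sf, clip),
            )
        )
    if c.rad_inhalation_sf is not None:
        c_air = air_concentration(c_w, f)
        intake = c_air * _air_intake_rate(f, scenario) * f.exposure_frequency * ed
        out.append(
            PathwayResult(
                c.name, "inhalation", intake,
                cancer_risk=_clip_risk(intake * c.rad_inhalation_sf, clip),
            )
        )
    if c.rad_immersion_sf is not None:
        exposure = c_w * f.immersion_time_fraction * ed
        out.append(
            PathwayResult(
                c.name, "dermal", exposure,
                cancer_risk=_clip_risk(exposure * c.rad_immersion_sf, clip),
            )
        )
    return out


def assess_contaminant(
    c: Contaminant,
    c_w,
    f: ExposureFactors,
    scenario: ScenarioConfig,
    *,
    ed_years: float | None = None,
    clip: bool = True,
) -> list[PathwayResult]:
    """All applicable pathway results for one analyte at water concentration
    ``c_w`` (registry units; scalar or trial vector)."""
    if c.is_radionuclide:
        return radionuclide_metrics(c_w, c, f, scenario, ed_years=ed_years, clip=clip)

    mode = "cancer" if c.analyte_class == "carcinogen" else "noncancer"
    cancer = mode == "cancer"
    doses: dict[str, object] = {
        "ingestion": ingestion_dose(c_w, f, scenario, cancer=cancer, ed_years=ed_years),
        "dermal": dermal_dose(c_w, c, f, scenario, cancer=cancer, ed_years=ed_years),
    }
    if is_volatile(c):
        doses["inhalation"] = inhalation_dose(
            air_concentration(c_w, f), f, scenario, cancer=cancer, ed_years=ed_years
        )
    return chemical_metrics(doses, c, mode, f, clip=clip)


@dataclass
class TrialResult:
    """One realization: sampled inputs plus all pathway results and totals."""

    spill_volume: float
    concentrations: dict[str, float]
    pathway_results: list[PathwayResult]
    total_cancer_risk: float
    total_hazard_index: float
    total_radionuclide_risk: float


def totals(
    results: Iterable[PathwayResult],
    radionuclide_names: Iterable[str] = (),
) -> tuple:
    """(total chemical cancer risk, total hazard index, total radionuclide risk).

    The radionuclide sum is kept outside the chemical cancer total; pathway
    membership is decided by which metric each result carries and whether its
    analyte is in ``radionuclide_names``.
    """
    rad = set(radionuclide_names)
    t_cancer = 0.0
    t_hi = 0.0
    t_rad = 0.0
    for r in results:
        if r.cancer_risk is not None:
            if r.analyte in rad:
                t_rad = t_rad + r.cancer_risk
            else:
                t_cancer = t_cancer + r.cancer_risk
        if r.hazard_quotient is not None:
            t_hi = t_hi + r.hazard_quotient
    return t_cancer, t_hi, t_rad
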