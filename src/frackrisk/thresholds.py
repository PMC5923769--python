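"""Invert the linear risk model for decision quantities: the longest safe
exposure duration and the largest safe spill volume.

Every metric in the engine is linear in exposure duration (averaging times
are fixed windows) and in spill volume (complete-mix dilution), so the
inversions are closed-form:

    D_max = D_ref * target / metric(D_ref)
    V_max = V_ref * target / metric(V_ref)

"Maximum possible" inputs are operationalised as a fixed percentile
(default the 95th) of the spill-volume and concentration distributions;
risks are evaluated unclipped so linearity holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import (
    ExposureFactors,
    ScenarioConfig,
    assess_contaminant,
    dilute,
    drinking_water_factors,
    swimming_factors,
)
from .registry import ContaminantRegistry

__all__ = [
    "ThresholdQuery",
    "Duration",
    "UNBOUNDED",
    "METRICS",
    "metric_value",
    "fixed_percentile_inputs",
    "max_exposure_duration",
    "max_spill_volume",
    "chemical_spill_threshold",
    "dilution_equivalence",
    "default_factors",
]

METRICS = (
    "total_cancer",
    "total_hazard_index",
    "total_radionuclide",
    "ingestion_cancer",
    "dermal_cancer",
    "inhalation_cancer",
    "ingestion_hazard",
    "dermal_hazard",
    "inhalation_hazard",
    "ingestion_radionuclide",
    "dermal_radionuclide",
    "inhalation_radionuclide",
)

_DEFAULT_TARGETS = {"cancer": 1e-6, "hazard": 1.0, "radionuclide": 1e-6}


def default_factors(scenario: str) -> ExposureFactors:
    return swimming_factors() if scenario == "swimming" else drinking_water_factors()


@dataclass(frozen=True)
class ThresholdQuery:
    """What to invert: scenario, metric, input percentile, and target level."""

    scenario: str = "drinking_water"
    metric: str = "total_cancer"
    input_level: float = 0.95
    target: float | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if not 0.0 < self.input_level <= 1.0:
            raise ValueError("input_level must be a percentile in (0, 1]")
        if self.target is not None and not self.target > 0:
            raise ValueError("target must be positive")

    @property
    def resolved_target(self) -> float:
        if self.target is not None:
            return self.target
        kind = "hazard" if "hazard" in self.metric else (
            "radionuclide" if "radionuclide" in self.metric else "cancer"
        )
        return _DEFAULT_TARGETS[kind]


@dataclass(frozen=True)
class Duration:
    """An exposure duration in days; ``math.inf`` means unbounded."""

    days: float

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.days)

    @property
    def hours(self) -> float:
        return self.days * 24.0

    @property
    def weeks(self) -> float:
        return self.days / 7.0

    @property
    def years(self) -> float:
        return self.days / 365.0

    def __str__(self) -> str:
        if self.unbounded:
            return ">100 years"
        if self.days < 2.0:
            return f"{self.hours:.1f} h"
        if self.days < 90.0:
            return f"{self.days:.1f} days"
        if self.days < 2 * 365.0:
            return f"{self.weeks:.1f} weeks"
        return f"{self.years:.1f} years"


UNBOUNDED = Duration(math.inf)


def fixed_percentile_inputs(
    registry: ContaminantRegistry,
    scenario: ScenarioConfig,
    input_level: float,
) -> tuple[float, dict[str, float]]:
    """Spill volume and per-analyte flowback concentrations fixed at the
    given percentile of their distributions (negative quantile values of
    unbounded families are floored at zero)."""
    spill = float(scenario.spill_dist.quantile(input_level))
    conc = {
        c.name: max(float(c.concentration_dist.quantile(input_level)), 0.0)
        for c in registry
    }
    return spill, conc


def _metric_filter(metric: str):
    parts = metric.split("_", 1)
    if parts[0] in ("ingestion", "dermal", "inhalation"):
        pathway = parts[0]
        kind = parts[1]
    else:
        pathway = None
        kind = {"total_cancer": "cancer", "total_hazard_index": "hazard",
                "total_radionuclide": "radionuclide"}[metric]
    return pathway, kind


def metric_value(
    metric: str,
    registry: ContaminantRegistry,
    factors: ExposureFactors,
    scenario: ScenarioConfig,
    *,
    input_level: float = 0.95,
    ed_years: float | None = None,
    spill_volume: float | None = None,
) -> float:
    """Evaluate one aggregate metric at fixed-percentile inputs.

    Risks are not clipped at 1 here so the value stays exactly linear in
    spill volume, concentration, and exposure duration.
    """
    spill_q, conc = fixed_percentile_inputs(registry, scenario, input_level)
    v_spill = spill_q if spill_volume is None else spill_volume
    pathway, kind = _metric_filter(metric)
    total = 0.0
    for c in registry:
        if kind == "radionuclide" and not c.is_radionuclide:
            continue
        if kind in ("cancer", "hazard") and c.is_radionuclide:
            continue
        c_w = dilute(conc[c.name], v_spill, scenario.pond_volume)
        for pr in assess_contaminant(c, c_w, factors, scenario, ed_years=ed_years, clip=False):
            if pathway is not None and pr.pathway != pathway:
                continue
            if kind in ("cancer", "radionuclide") and pr.cancer_risk is not None:
                total += float(pr.cancer_risk)
            elif kind == "hazard" and pr.hazard_quotient is not None:
                total += float(pr.hazard_quotient)
    return total


def max_exposure_duration(
    q: ThresholdQuery,
    registry: ContaminantRegistry,
    factors: ExposureFactors | None = None,
    scenario: ScenarioConfig | None = None,
) -> Duration:
    """Largest exposure duration keeping the metric below its target.

    Exploits linearity of the metric in duration under the fixed-averaging-
    window convention; zero risk at the reference duration means the
    duration is unbounded (reported as a sentinel, not an error).
    """
    factors = factors or default_factors(q.scenario)
    scenario = scenario or ScenarioConfig(scenario=q.scenario)
    ref_years = factors.exposure_duration
    value = metric_value(
        q.metric, registry, factors, scenario, input_level=q.input_level, ed_years=ref_years
    )
    if value <= 0.0:
        return UNBOUNDED
    return Duration(days=ref_years * 365.0 * q.resolved_target / value)


def max_spill_volume(
    q: ThresholdQuery,
    registry: ContaminantRegistry,
    factors: ExposureFactors | None = None,
    scenario: ScenarioConfig | None = None,
    *,
    ed_years: float | None = None,
) -> float:
    """Spill volume at which the metric reaches its target, holding
    concentrations at the query percentile and duration at ``ed_years``
    (default: the scenario's exposure duration).  Infinite if the metric is
    identically zero."""
    factors = factors or default_factors(q.scenario)
    scenario = scenario or ScenarioConfig(scenario=q.scenario)
    v_ref, _ = fixed_percentile_inputs(registry, scenario, q.input_level)
    value = metric_value(
        q.metric, registry, factors, scenario,
        input_level=q.input_level, ed_years=ed_years, spill_volume=v_ref,
    )
    if value <= 0.0:
        return math.inf
    return v_ref * q.resolved_target / value


def chemical_spill_threshold(
    registry: ContaminantRegistry,
    factors: ExposureFactors | None = None,
    scenario: ScenarioConfig | None = None,
    *,
    input_level: float = 0.95,
    ed_years: float | None = None,
) -> float:
    """"No adverse chemical effect" spill volume: the binding (smaller) of the
    cancer-risk and hazard-index spill-volume thresholds."""
    kw = dict(input_level=input_level)
    v_cancer = max_spill_volume(
        ThresholdQuery(metric="total_cancer", **kw), registry, factors, scenario,
        ed_years=ed_years,
    )
    v_hi = max_spill_volume(
        ThresholdQuery(metric="total_hazard_index", **kw), registry, factors, scenario,
        ed_years=ed_years,
    )
    return min(v_cancer, v_hi)


def dilution_equivalence(v_spill: float, v_pond: float) -> float:
    """Dilution ratio v_pond / v_spill for generalizing a spill-volume
    threshold to other receiving waters."""
    if v_spill <= 0 or v_pond <= 0:
        raise ValueError("volumes must be positive")
    return v_pond / v_spill
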