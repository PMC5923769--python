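"""Per-analyte contaminant registry: toxicity factors, physical properties,
concentration-distribution anchors, and the volatility gate.

The default registry packaged under ``frackrisk/data/contaminants.csv`` holds
the 22 study analytes (20 chemicals + radium-226/228).  Toxicity values come
from standard EPA sources (IRIS/PPRTV/HEAST, RAGS Part E dermal tables,
HEAST radionuclide slope-factor tables); the ``notes`` column records
provenance and the documented data-quality corrections to the distribution
anchors.  The engine never hard-codes a toxicity number: swap the CSV (or a
JSON file with the same keys) to run an alternate registry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .distributions import DistributionSpec, from_quantiles

__all__ = [
    "Contaminant",
    "ContaminantRegistry",
    "RegistryValidationError",
    "load_registry",
    "write_registry",
    "load_default_registry",
    "load_mcl_table",
    "is_volatile",
    "HENRY_VOLATILITY_CUTOFF",
    "MW_VOLATILITY_CUTOFF",
]

#: Henry's-law constant above which (with MW below the cutoff) a chemical is
#: treated as volatilizing from household water into indoor air.
HENRY_VOLATILITY_CUTOFF = 1e-5  # atm m3 / mol
MW_VOLATILITY_CUTOFF = 200.0  # g/mol

ANALYTE_CLASSES = ("carcinogen", "noncarcinogen", "radionuclide")

_OPTIONAL_POSITIVE = (
    "oral_slope_factor",
    "inhalation_unit_risk",
    "oral_reference_dose",
    "gi_absorption_fraction",
    "dermal_permeability",
    "henry_constant",
    "molecular_weight",
    "rad_ingestion_sf",
    "rad_inhalation_sf",
    "rad_immersion_sf",
)


class RegistryValidationError(ValueError):
    """A registry row violates a class or positivity invariant."""


@dataclass(frozen=True)
class Contaminant:
    """One analyte: identity, class, toxicity factors and properties.

    Units: oral_slope_factor (mg/kg-day)^-1; inhalation_unit_risk (ug/m3)^-1;
    oral_reference_dose mg/kg-day; dermal_permeability cm/h; henry_constant
    atm m3/mol; molecular_weight g/mol; rad_*_sf risk/pCi (immersion:
    risk/year per pCi/L).  Missing optional properties disable the
    corresponding pathway rather than erroring.
    """

    name: str
    analyte_class: str
    concentration_dist: DistributionSpec
    concentration_units: str = "mg/L"
    n_samples: int = 100
    oral_slope_factor: float | None = None
    inhalation_unit_risk: float | None = None
    oral_reference_dose: float | None = None
    gi_absorption_fraction: float | None = None
    dermal_permeability: float | None = None
    henry_constant: float | None = None
    molecular_weight: float | None = None
    rad_ingestion_sf: float | None = None
    rad_inhalation_sf: float | None = None
    rad_immersion_sf: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.analyte_class not in ANALYTE_CLASSES:
            raise RegistryValidationError(
                f"{self.name}: analyte_class must be one of {ANALYTE_CLASSES}, "
                f"got {self.analyte_class!r}"
            )
        for attr in _OPTIONAL_POSITIVE:
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise RegistryValidationError(f"{self.name}: {attr} must be positive, got {v}")
        gi = self.gi_absorption_fraction
        if gi is not None and gi > 1:
            raise RegistryValidationError(f"{self.name}: gi_absorption_fraction must be <= 1")
        if self.analyte_class == "carcinogen":
            if self.oral_slope_factor is None and self.inhalation_unit_risk is None:
                raise RegistryValidationError(
                    f"{self.name}: a carcinogen needs an oral slope factor or an "
                    "inhalation unit risk"
                )
        elif self.analyte_class == "noncarcinogen":
            if self.oral_reference_dose is None:
                raise RegistryValidationError(
                    f"{self.name}: a noncarcinogen needs an oral reference dose"
                )
        else:  # radionuclide
            if not any(
                (self.rad_ingestion_sf, self.rad_inhalation_sf, self.rad_immersion_sf)
            ):
                raise RegistryValidationError(
                    f"{self.name}: a radionuclide needs at least one rad_* slope factor"
                )
            if self.concentration_units != "pCi/L":
                raise RegistryValidationError(
                    f"{self.name}: radionuclide concentrations must be in pCi/L"
                )

    @property
    def is_radionuclide(self) -> bool:
        return self.analyte_class == "radionuclide"


def is_volatile(c: Contaminant) -> bool:
    """Volatilization gate for the household inhalation pathway.

    True iff Henry's constant > 1e-5 atm m3/mol and molecular weight
    < 200 g/mol.  Radionuclides bypass this gate (they are treated as
    inhalation-eligible through aerosolization); missing properties mean
    non-volatile.
    """
    if c.is_radionuclide:
        return True
    if c.henry_constant is None or c.molecular_weight is None:
        return False
    return c.henry_constant > HENRY_VOLATILITY_CUTOFF and c.molecular_weight < MW_VOLATILITY_CUTOFF


@dataclass
class ContaminantRegistry:
    """Ordered collection of contaminants with unique names.

    Chemical (carcinogen + noncarcinogen) and radionuclide analytes form a
    hard partition: totals are never combined across it.
    """

    contaminants: list[Contaminant] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contaminants]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryValidationError(f"duplicate contaminant names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.contaminants)

    def __iter__(self) -> Iterator[Contaminant]:
        return iter(self.contaminants)

    def __getitem__(self, name: str) -> Contaminant:
        for c in self.contaminants:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def chemicals(self) -> list[Contaminant]:
        return [c for c in self.contaminants if not c.is_radionuclide]

    @property
    def carcinogens(self) -> list[Contaminant]:
        return [c for c in self.contaminants if c.analyte_class == "carcinogen"]

    @property
    def noncarcinogens(self) -> list[Contaminant]:
        return [c for c in self.contaminants if c.analyte_class == "noncarcinogen"]

    @property
    def radionuclides(self) -> list[Contaminant]:
        return [c for c in self.contaminants if c.is_radionuclide]

    def names(self) -> list[str]:
        return [c.name for c in self.contaminants]


_CSV_COLUMNS = [
    "name",
    "analyte_class",
    "oral_slope_factor",
    "inhalation_unit_risk",
    "oral_reference_dose",
    "gi_absorption_fraction",
    "dermal_permeability",
    "henry_constant",
    "molecular_weight",
    "rad_ingestion_sf",
    "rad_inhalation_sf",
    "rad_immersion_sf",
    "dist_family",
    "dist_median",
    "dist_p95",
    "n_samples",
    "concentration_units",
    "notes",
]


def _row_to_contaminant(row: Mapping, origin: str) -> Contaminant:
    def opt(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    try:
        spec = from_quantiles(
            str(row["dist_family"]).strip(),
            float(row["dist_median"]),
            float(row["dist_p95"]),
        )
        return Contaminant(
            name=str(row["name"]).strip(),
            analyte_class=str(row["analyte_class"]).strip(),
            concentration_dist=spec,
            concentration_units=str(row["concentration_units"]).strip(),
            n_samples=int(row["n_samples"]),
            oral_slope_factor=opt("oral_slope_factor"),
            inhalation_unit_risk=opt("inhalation_unit_risk"),
            oral_reference_dose=opt("oral_reference_dose"),
            gi_absorption_fraction=opt("gi_absorption_fraction"),
            dermal_permeability=opt("dermal_permeability"),
            henry_constant=opt("henry_constant"),
            molecular_weight=opt("molecular_weight"),
            rad_ingestion_sf=opt("rad_ingestion_sf"),
            rad_inhalation_sf=opt("rad_inhalation_sf"),
            rad_immersion_sf=opt("rad_immersion_sf"),
            notes="" if pd.isna(row.get("notes")) else str(row.get("notes")),
        )
    except (ValueError, KeyError) as exc:
        raise RegistryValidationError(f"{origin}: {exc}") from exc


def load_registry(path: str | Path) -> ContaminantRegistry:
    """Load and validate a registry from CSV (or a JSON list of row dicts)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise RegistryValidationError(f"{path}: JSON registry must be a list of objects")
    else:
        df = pd.read_csv(path)
        missing = {"name", "analyte_class", "dist_family", "dist_median", "dist_p95"} - set(
            df.columns
        )
        if missing:
            raise RegistryValidationError(f"{path}: missing required columns {sorted(missing)}")
        if "concentration_units" not in df.columns:
            df["concentration_units"] = "mg/L"
        if "n_samples" not in df.columns:
            df["n_samples"] = 100
        rows = df.to_dict(orient="records")
    contaminants = [
        _row_to_contaminant(row, f"{path.name} row {i + 1} ({row.get('name', '?')})")
        for i, row in enumerate(rows)
    ]
    return ContaminantRegistry(contaminants)


def write_registry(registry: ContaminantRegistry, path: str | Path) -> None:
    """Write a registry to CSV; numeric fields round-trip bit-identically."""
    path = Path(path)
    rows = []
    for c in registry:
        med, p95 = c.concentration_dist.anchors or (
            c.concentration_dist.median,
            c.concentration_dist.p95,
        )
        row = {
            "name": c.name,
            "analyte_class": c.analyte_class,
            "dist_family": c.concentration_dist.family,
            "dist_median": repr(float(med)),
            "dist_p95": repr(float(p95)),
            "n_samples": c.n_samples,
            "concentration_units": c.concentration_units,
            "notes": c.notes,
        }
        for attr in _OPTIONAL_POSITIVE:
            v = getattr(c, attr)
            row[attr] = "" if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _data_path(name: str) -> Path:
    return Path(resources.files("frackrisk").joinpath("data", name))


def load_default_registry() -> ContaminantRegistry:
    """The packaged 22-analyte study registry."""
    return load_registry(_data_path("contaminants.csv"))


def load_mcl_table() -> dict[str, float]:
    """Packaged drinking-water limits (MCL or action/secondary level), in the
    registry's concentration units, used by the prioritization comparison."""
    df = pd.read_csv(_data_path("mcl.csv"))
    return dict(zip(df["name"], df["mcl"].astype(float)))
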