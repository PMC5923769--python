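"""Synthetic stand-ins for the study's two raw inputs.

The original spill records (national spill-report database, 2008-2016) and
the 92-well flowback concentration dataset are not publicly deposited, so
this module generates tables with the same statistical structure: spill
volumes following the fitted lognormal (median 128 L, 95th percentile
114,900 L, right-truncated at the observed 350,000 L maximum), and
per-analyte concentration samples drawn from each analyte's registry
distribution, with optional non-detect censoring.

Non-detects are reported at the detection limit and flagged, the common lab
convention; fitting uses detected values only.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, sample
from .engine import SPILL_MAX_L, default_spill_distribution
from .registry import ContaminantRegistry

__all__ = [
    "SpillRecord",
    "ConcentrationSample",
    "generate_spill_records",
    "generate_flowback_samples",
    "spills_to_frame",
    "samples_to_frame",
    "frame_to_spills",
    "frame_to_samples",
    "write_demo_dataset",
]

_DATE_LO = dt.date(2008, 1, 1)
_DATE_HI = dt.date(2016, 12, 31)


@dataclass(frozen=True)
class SpillRecord:
    record_id: int
    date: dt.date
    total_volume: float
    volume_reached_water: float

    def __post_init__(self) -> None:
        if not 0 <= self.volume_reached_water <= self.total_volume:
            raise ValueError("volume_reached_water must lie in [0, total_volume]")

    @property
    def reached_water(self) -> bool:
        return self.volume_reached_water > 0


@dataclass(frozen=True)
class ConcentrationSample:
    analyte: str
    well_id: int
    value: float
    detected: bool = True
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentration cannot be negative")
        if not self.detected:
            if self.detection_limit is None or self.value != self.detection_limit:
                raise ValueError("non-detects are reported at the detection limit")


def generate_spill_records(
    n: int,
    spec: DistributionSpec | None = None,
    seed: int = 0,
) -> list[SpillRecord]:
    """``n`` spill records that reached water, volumes from ``spec`` truncated
    at the 350,000 L ceiling; seeded and reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or default_spill_distribution()
    rng = np.random.default_rng(seed)
    volumes = sample(spec, n, rng, nonnegative=True, upper=SPILL_MAX_L)
    # the reported total includes any volume that did not reach water
    excess = 1.0 + rng.exponential(scale=0.5, size=n)
    days = rng.integers(0, (_DATE_HI - _DATE_LO).days + 1, size=n)
    return [
        SpillRecord(
            record_id=i + 1,
            date=_DATE_LO + dt.timedelta(days=int(d)),
            total_volume=float(v * e),
            volume_reached_water=float(v),
        )
        for i, (v, e, d) in enumerate(zip(volumes, excess, days))
    ]


def generate_flowback_samples(
    registry: ContaminantRegistry,
    seed: int = 0,
    detect_fraction_overrides: Mapping[str, float] | None = None,
) -> list[ConcentrationSample]:
    """Per-analyte concentration samples sized by the registry's sample counts.

    Analytes with a detect-fraction override have (1 - fraction) of their
    samples censored: marked non-detect and reported at a detection limit set
    to the analyte's 5th-percentile concentration.
    """
    overrides = dict(detect_fraction_overrides or {})
    for name, frac in overrides.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"detect fraction for {name} must be in [0, 1], got {frac}")
    ss = np.random.SeedSequence(seed)
    out: list[ConcentrationSample] = []
    for c, child in zip(registry, ss.spawn(len(registry))):
        rng = np.random.default_rng(child)
        values = sample(c.concentration_dist, c.n_samples, rng, nonnegative=True)
        frac = overrides.get(c.name)
        if frac is None:
            detected = np.ones(c.n_samples, dtype=bool)
        else:
            detected = rng.random(c.n_samples) < frac
        dl = max(float(c.concentration_dist.quantile(0.05)), 0.0)
        for well, (v, det) in enumerate(zip(values, detected), start=1):
            out.append(
                ConcentrationSample(
                    analyte=c.name,
                    well_id=well,
                    value=float(v) if det else dl,
                    detected=bool(det),
                    detection_limit=dl,
                )
            )
    return out


# ---------------------------------------------------------------------------
# tabular round-trips
# ---------------------------------------------------------------------------


def spills_to_frame(records: list[SpillRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "total_volume": [repr(r.total_volume) for r in records],
            "volume_reached_water": [repr(r.volume_reached_water) for r in records],
        }
    )


def frame_to_spills(df: pd.DataFrame) -> list[SpillRecord]:
    return [
        SpillRecord(
            record_id=int(row.record_id),
            date=dt.date.fromisoformat(str(row.date)),
            total_volume=float(row.total_volume),
            volume_reached_water=float(row.volume_reached_water),
        )
        for row in df.itertuples()
    ]


def samples_to_frame(samples: list[ConcentrationSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "analyte": [s.analyte for s in samples],
            "well_id": [s.well_id for s in samples],
            "value": [repr(s.value) for s in samples],
            "detected": [s.detected for s in samples],
            "detection_limit": [
                "" if s.detection_limit is None else repr(s.detection_limit) for s in samples
            ],
        }
    )


def frame_to_samples(df: pd.DataFrame) -> list[ConcentrationSample]:
    out = []
    for row in df.itertuples():
        dl = row.detection_limit
        dl = None if (dl == "" or pd.isna(dl)) else float(dl)
        out.append(
            ConcentrationSample(
                analyte=str(row.analyte),
                well_id=int(row.well_id),
                value=float(row.value),
                detected=bool(row.detected),
                detection_limit=dl,
            )
        )
    return out


def write_demo_dataset(
    outdir: str | Path,
    registry: ContaminantRegistry,
    n_spills: int = 194,
    seed: int = 0,
    detect_fraction_overrides: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write a complete demo dataset (spills + concentrations) as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spills = generate_spill_records(n_spills, seed=seed)
    samples = generate_flowback_samples(
        registry, seed=seed + 1, detect_fraction_overrides=detect_fraction_overrides
    )
    paths = {
        "spills": outdir / "spill_records.csv",
        "concentrations": outdir / "flowback_concentrations.csv",
    }
    spills_to_frame(spills).to_csv(paths["spills"], index=False)
    samples_to_frame(samples).to_csv(paths["concentrations"], index=False)
    return paths
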