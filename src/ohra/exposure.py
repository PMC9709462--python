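"""Exposure records and the two shared quantities EC and CR.

EC (exposure concentration, μg/m³) time-averages the airborne concentration
over the full averaging period::

    EC = (CA × ET × EF × ED) / AT,   AT = ED × 365 d/y × 24 h/d

with CA the airborne concentration (μg/m³), ET hours/day, EF days/year and
ED years of exposure.  ED cancels against AT, so EC depends only on CA and
the within-year exposure pattern.

CR (concentration ratio) is CA divided by the occupational exposure limit;
CR > 1 means the measured exposure exceeds the limit.

At the API boundary concentrations are mg/m³ (the unit of workplace
monitoring tables); μg/m³ appears only inside the EPA hazard-quotient math.
"""

from __future__ import annotations

import logging
from enum import IntEnum
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from .registry import HazardProfile

log = logging.getLogger(__name__)

HOURS_PER_YEAR = 365.0 * 24.0

#: full-shift occupational defaults used when a record omits the pattern
DEFAULT_ET = 8.0    # h/day
DEFAULT_EF = 250.0  # days/year
DEFAULT_ED = 25.0   # years


class ExposureRecord(BaseModel):
    """One job/location measurement of one hazard."""

    industry: str
    location: str
    hazard: str
    ca: float = Field(ge=0, description="airborne concentration, mg/m³ TWA")
    et: float = Field(default=DEFAULT_ET, gt=0, le=24, description="exposure time, h/day")
    ef: float = Field(default=DEFAULT_EF, gt=0, le=365, description="exposure frequency, days/year")
    ed: float = Field(default=DEFAULT_ED, gt=0, description="exposure duration, years")
    n_workers: int = Field(default=1, ge=0)


class IRTier(IntEnum):
    """Catalog-assigned inherent-risk tier of an industry; rank 1 = highest."""

    severe = 1
    medium = 2
    low = 3


class InherentRisk(BaseModel):
    tier: str
    rank: int

    @classmethod
    def from_tier(cls, tier: str) -> "InherentRisk":
        return cls(tier=tier, rank=int(IRTier[tier]))


def compute_ec(record: ExposureRecord) -> float:
    """Exposure concentration in μg/m³ (input CA is mg/m³).

    ED cancels against AT = ED×365×24, so the result is CA×1000×ET×EF/8760.
    """
    return record.ca * 1000.0 * record.et * record.ef / HOURS_PER_YEAR


def compute_cr(
    record: ExposureRecord, profile: HazardProfile, limit: str = "china"
) -> float:
    """Concentration ratio CA/OEL (both mg/m³) against the selected limit."""
    return record.ca / profile.get_oel(limit)


_COLUMNS = {
    "industry": "industry",
    "location": "location",
    "hazard": "hazard",
    "ca_mg_m3": "ca",
    "et_h_d": "et",
    "ef_d_y": "ef",
    "ed_y": "ed",
    "n_workers": "n_workers",
}


def load_exposure(path: str | Path) -> list[ExposureRecord]:
    """Read exposure records from a comma-separated file.

    Missing ``et``/``ef``/``ed`` cells fall back to the full-shift defaults
    (8 h/d, 250 d/y, 25 y) with a logged notice.
    """
    frame = pd.read_csv(path, comment="#")
    missing = set(("industry", "location", "hazard", "ca_mg_m3")) - set(frame.columns)
    if missing:
        raise ValueError(f"exposure file {path} lacks columns: {sorted(missing)}")
    records = []
    defaulted = 0
    for row in frame.to_dict("records"):
        data = {}
        for col, field in _COLUMNS.items():
            value = row.get(col)
            if value is None or (isinstance(value, float) and pd.isna(value)):
                if field in ("et", "ef", "ed"):
                    defaulted += 1
                continue
            data[field] = value
        records.append(ExposureRecord(**data))
    if defaulted:
        log.info(
            "%d exposure-pattern cells missing in %s; full-shift defaults applied "
            "(ET=%g h/d, EF=%g d/y, ED=%g y)", defaulted, path,
            DEFAULT_ET, DEFAULT_EF, DEFAULT_ED,
        )
    return records


def exposure_frame(records: list[ExposureRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the exposure-file column layout."""
    rows = [
        {
            "industry": r.industry, "location": r.location, "hazard": r.hazard,
            "ca_mg_m3": r.ca, "et_h_d": r.et, "ef_d_y": r.ef, "ed_y": r.ed,
            "n_workers": r.n_workers,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def write_exposure(records: list[ExposureRecord], path: str | Path) -> None:
    exposure_frame(records).to_csv(path, index=False)
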