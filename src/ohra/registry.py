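"""Per-chemical hazard registry.

Every scoring engine consumes a :class:`HazardProfile`: the EPA engine needs
the reference concentration (RfC, stored in μg/m³ as toxicological databases
print it), the concentration ratio needs an occupational exposure limit (OEL,
stored in mg/m³ as workplace monitoring reports print it), COSHH needs risk
phrases and a dustiness/volatility band, and the Singaporean hazard rating
derives from carcinogenicity class or acute-toxicity data unless overridden.

The registry file is a comma-separated table with one chemical per row and a
header naming exactly the profile fields; ``risk_phrases`` is
semicolon-joined.  A JSON list of objects with the same field names is also
accepted.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import DuplicateChemicalError, MissingParameterError, RegistryError

log = logging.getLogger(__name__)

Carcinogenicity = Literal["IARC-1", "IARC-2A", "IARC-2B", "IARC-3", "none"]
PhysicalForm = Literal["solid", "liquid", "gas"]
Band = Literal["low", "medium", "high"]

#: fields that make a chemical scoreable by at least one engine
_SCOREABLE = (
    "rfc",
    "oel_china_twa",
    "oel_acgih_twa",
    "risk_phrases",
    "ld50_oral",
    "lc50_inhal",
)


class HazardProfile(BaseModel):
    """Toxicology and exposure-limit data for one chemical hazard."""

    name: str
    cas: Optional[str] = None
    rfc: Optional[float] = Field(default=None, gt=0, description="reference concentration, μg/m³")
    iur: Optional[float] = Field(default=None, gt=0, description="inhalation unit risk, per μg/m³ (stored, unused)")
    oel_china_twa: Optional[float] = Field(default=None, gt=0, description="China PC-TWA, mg/m³")
    oel_acgih_twa: Optional[float] = Field(default=None, gt=0, description="ACGIH TLV-TWA, mg/m³")
    carcinogenicity: Carcinogenicity = "none"
    ld50_oral: Optional[float] = Field(default=None, gt=0, description="oral LD50, mg/kg")
    lc50_inhal: Optional[float] = Field(default=None, gt=0, description="inhalation LC50, mg/m³")
    risk_phrases: list[str] = Field(default_factory=list)
    physical_form: PhysicalForm = "solid"
    dustiness_band: Optional[Band] = None
    volatility_band: Optional[Band] = None
    hr_override: Optional[int] = Field(default=None, ge=1, le=5)
    notes: Optional[str] = None

    @model_validator(mode="after")
    def _scoreable(self) -> "HazardProfile":
        has_carc = self.carcinogenicity != "none"
        if not has_carc and not any(getattr(self, f) for f in _SCOREABLE):
            raise ValueError(
                f"profile {self.name!r} carries no RfC, OEL, risk phrase, "
                "carcinogenicity class or acute-toxicity datum: no engine can score it"
            )
        return self

    def get_rfc(self) -> float:
        """RfC in μg/m³; the EPA engine cannot score a chemical without one."""
        if self.rfc is None:
            raise MissingParameterError(
                f"{self.name!r} has no RfC: not assessable by the EPA method"
            )
        return self.rfc

    def get_oel(self, source: str = "china") -> float:
        """Selected OEL in mg/m³ (``china`` PC-TWA or ``acgih`` TLV-TWA)."""
        if source not in ("china", "acgih"):
            raise ValueError(f"unknown OEL source {source!r}")
        value = self.oel_china_twa if source == "china" else self.oel_acgih_twa
        if value is None:
            raise MissingParameterError(f"{self.name!r} has no {source} OEL")
        return value


_CSV_FIELDS = [
    "name", "cas", "rfc", "iur", "oel_china_twa", "oel_acgih_twa",
    "carcinogenicity", "ld50_oral", "lc50_inhal", "risk_phrases",
    "physical_form", "dustiness_band", "volatility_band", "hr_override", "notes",
]
_FLOATS = {"rfc", "iur", "oel_china_twa", "oel_acgih_twa", "ld50_oral", "lc50_inhal"}


def _row_to_profile(row: dict, lineno: int) -> HazardProfile:
    data: dict = {}
    for key, raw in row.items():
        if raw is None or (isinstance(raw, str) and raw.strip() == ""):
            continue
        if key == "risk_phrases" and isinstance(raw, str):
            data[key] = [p.strip() for p in raw.split(";") if p.strip()]
        elif key in _FLOATS and isinstance(raw, str):
            data[key] = float(raw)
        elif key == "hr_override" and isinstance(raw, str):
            data[key] = int(raw)
        else:
            data[key] = raw
    try:
        return HazardProfile(**data)
    except (ValidationError, ValueError) as exc:
        raise RegistryError(f"registry line {lineno}: {exc}") from exc


def load_registry(path: str | Path) -> dict[str, HazardProfile]:
    """Load and validate a hazard registry, keyed by chemical name.

    Duplicate chemical names are rejected; profiles whose ``notes`` flag
    placeholder values are reported once at load so users confirm them
    against an authoritative OEL/toxicity source.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    profiles: dict[str, HazardProfile] = {}
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        items = [(_row_to_profile(row, i + 1), i + 1) for i, row in enumerate(rows)]
    else:
        with path.open(newline="") as fh:
            lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
        reader = csv.DictReader(lines)
        items = []
        if reader.fieldnames:
            unknown = set(reader.fieldnames) - set(_CSV_FIELDS)
            if unknown:
                raise RegistryError(f"unknown registry columns: {sorted(unknown)}")
            for i, row in enumerate(reader, start=2):
                items.append((_row_to_profile(row, i), i))
    placeholders = []
    for profile, lineno in items:
        if profile.name in profiles:
            raise DuplicateChemicalError(
                f"duplicate chemical {profile.name!r} at registry line {lineno}"
            )
        profiles[profile.name] = profile
        if profile.notes and "placeholder" in profile.notes.lower():
            placeholders.append(profile.name)
    if not profiles:
        log.warning("registry %s is empty", path)
    if placeholders:
        log.warning(
            "registry %s ships unconfirmed placeholder values for: %s "
            "(confirm against GBZ 2.1 / ACGIH before regulatory use)",
            path, ", ".join(placeholders),
        )
    return profiles


def write_registry(profiles: dict[str, HazardProfile], path: str | Path) -> None:
    """Persist a registry as CSV; inverse of :func:`load_registry`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for profile in profiles.values():
            row = profile.model_dump()
            row["risk_phrases"] = ";".join(row["risk_phrases"])
            writer.writerow({k: ("" if row[k] is None else row[k]) for k in _CSV_FIELDS})


def default_registry_path() -> Path:
    """Path of the registry shipped with the package."""
    return Path(__file__).parent / "data" / "registry.csv"


def default_registry() -> dict[str, HazardProfile]:
    """The shipped registry covering the five-industry study hazards."""
    return load_registry(default_registry_path())
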