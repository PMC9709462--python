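"""The six occupational-health risk assessment engines.

Each engine maps an exposure record (plus the chemical's hazard profile) to a
raw score and an ordinal risk level on its own scale:

* **EPA** — quantitative: hazard quotient HQ = EC/RfC (both μg/m³), banded to
  five levels on the exposure-concentration classification.
* **COSHH** — control banding: risk phrases give a hazard band A–E, the
  dustiness/volatility and quantity of use give an exposure potential, and a
  matrix returns a control strategy CS1–CS4 (levels 2–5).
* **Singaporean** — semi-quantitative: Risk = √(HR × ER) with the hazard
  rating from carcinogenicity/acute toxicity and the exposure rating from the
  concentration ratio; the square root is rounded up (conservative).
* **ICMM** — consequence × likelihood matrix, exposure-time weight shifting
  the likelihood column.
* **Australian** — calculator-style nomogram over likelihood, exposure
  frequency and severity; fractional levels allowed.
* **Romanian** — severity (1–7) × probability (1–6) grid, seven levels.

``assess_all`` orchestrates the engines over a record set, deriving the
evaluator ratings the qualitative methods need (exposure probability from CR
bands, frequency from EF, severity from the hazard rating) so the pipeline
runs unattended, and skipping — with a logged reason — every (record, method)
pair a method cannot score, e.g. EPA on a hazard without an RfC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import MethodConfig, band_lookup
from .errors import MissingParameterError, ParameterError, UnknownPhraseError
from .exposure import ExposureRecord, compute_cr, compute_ec
from .harmonize import level_to_rr
from .registry import HazardProfile
from .scales import METHODS, default_scales

log = logging.getLogger(__name__)

HAZARD_BANDS = ("A", "B", "C", "D", "E")
QUANTITY_BANDS = ("small", "medium", "large")


@dataclass(frozen=True)
class AssessmentResult:
    """One (record, method) outcome."""

    record_id: int
    industry: str
    location: str
    hazard: str
    method: str
    raw_score: float
    level: float
    rr: float
    rr_display: float


# ---------------------------------------------------------------- EPA

def epa_hq(ec: float, rfc: float) -> float:
    """Hazard quotient EC/RfC, both in μg/m³."""
    if rfc <= 0:
        raise ParameterError(f"RfC must be positive, got {rfc}")
    if ec < 0:
        raise ParameterError(f"EC must be nonnegative, got {ec}")
    return ec / rfc


def epa_level(hq: float, config: MethodConfig | None = None) -> int:
    """Five-level banding of the hazard quotient (left-closed bands)."""
    config = config or MethodConfig.default()
    return band_lookup(config.hq_bands, hq)


# ---------------------------------------------------------------- Singaporean

def _rating_from_bands(value: float, spec: dict) -> int:
    thresholds, ratings = spec["thresholds"], spec["ratings"]
    idx = 0
    for t in thresholds:
        if value >= t:
            idx += 1
    return ratings[idx]


def singapore_hr(profile: HazardProfile, config: MethodConfig | None = None) -> int:
    """Hazard rating 1–5: override, else carcinogenicity, else acute toxicity."""
    config = config or MethodConfig.default()
    if profile.hr_override is not None:
        return profile.hr_override
    table = config.hr_table
    if profile.carcinogenicity != "none":
        return table["carcinogenicity"][profile.carcinogenicity]
    ratings = []
    if profile.ld50_oral is not None:
        ratings.append(_rating_from_bands(profile.ld50_oral, table["ld50_oral"]))
    if profile.lc50_inhal is not None:
        ratings.append(_rating_from_bands(profile.lc50_inhal, table["lc50_inhal"]))
    if not ratings:
        raise MissingParameterError(
            f"{profile.name!r} has no hazard-rating basis "
            "(no override, carcinogenicity class or acute-toxicity datum)"
        )
    return max(ratings)


def singapore_er(cr: float, config: MethodConfig | None = None) -> int:
    """Exposure rating 1–5 from the concentration ratio (left-closed bands)."""
    config = config or MethodConfig.default()
    return band_lookup(config.er_bands, cr)


def singapore_risk(hr: int, er: int) -> int:
    """Risk = √(HR×ER), rounded up, capped at 5."""
    for name, v in (("HR", hr), ("ER", er)):
        if v not in (1, 2, 3, 4, 5):
            raise ParameterError(f"{name} must be in 1..5, got {v}")
    return min(5, math.ceil(math.sqrt(hr * er)))


# ---------------------------------------------------------------- COSHH

def coshh_hazard_band(risk_phrases: Sequence[str], config: MethodConfig) -> str:
    """Worst hazard band A–E over the phrases; no phrases defaults to A.

    Compound codes (R48/20) are keyed by their first token.
    """
    mapping = config.coshh["phrase_bands"]
    band = "A"
    for phrase in risk_phrases:
        key = phrase.split("/")[0].strip().upper()
        if key not in mapping:
            raise UnknownPhraseError(f"risk phrase {phrase!r} has no hazard-band mapping")
        if HAZARD_BANDS.index(mapping[key]) > HAZARD_BANDS.index(band):
            band = mapping[key]
    return band


def coshh_exposure_potential(profile: HazardProfile, quantity_band: str, config: MethodConfig) -> int:
    """Exposure potential EP1–EP4 from quantity × dustiness/volatility."""
    if quantity_band not in QUANTITY_BANDS:
        raise ParameterError(f"quantity band must be one of {QUANTITY_BANDS}, got {quantity_band!r}")
    if profile.physical_form == "solid":
        release = profile.dustiness_band
    elif profile.physical_form == "liquid":
        release = profile.volatility_band
    else:  # a gas is always fully airborne
        release = "high"
    if release is None:
        raise MissingParameterError(
            f"{profile.name!r} ({profile.physical_form}) lacks a dustiness/volatility band"
        )
    return config.coshh["ep_table"][quantity_band][release]


def coshh_assess(
    profile: HazardProfile,
    quantity_band: str = "medium",
    config: MethodConfig | None = None,
) -> tuple[str, int]:
    """Control strategy and common risk level; concentration is not used."""
    config = config or MethodConfig.default()
    band = coshh_hazard_band(profile.risk_phrases, config)
    ep = coshh_exposure_potential(profile, quantity_band, config)
    cs = config.coshh["matrix"][band][ep - 1]
    from .harmonize import coshh_cs_to_level

    return f"CS{cs}", coshh_cs_to_level(cs)


# ---------------------------------------------------------------- ICMM

def icmm_assess(
    consequence: int,
    exposure_probability: int,
    exposure_time_weight: int = 2,
    config: MethodConfig | None = None,
) -> int:
    """5×5 consequence × likelihood grid; the time weight shifts likelihood."""
    config = config or MethodConfig.default()
    if consequence not in range(1, 6) or exposure_probability not in range(1, 6):
        raise ParameterError("consequence and probability must be in 1..5")
    if exposure_time_weight not in (1, 2, 3):
        raise ParameterError("exposure time weight must be in 1..3")
    likelihood = min(5, max(1, exposure_probability + (exposure_time_weight - 2)))
    return config.icmm["matrix"][consequence - 1][likelihood - 1]


def icmm_probability(cr: float, config: MethodConfig) -> int:
    return band_lookup(config.icmm["probability_bands"], cr)


# ---------------------------------------------------------------- Australian

def australian_assess(
    likelihood: int,
    exposure_frequency: int,
    severity: int,
    config: MethodConfig | None = None,
) -> float:
    """Nomogram-table lookup; returns a possibly fractional level in [1, 5]."""
    config = config or MethodConfig.default()
    for name, v in (("likelihood", likelihood), ("exposure frequency", exposure_frequency), ("severity", severity)):
        if v not in range(1, 6):
            raise ParameterError(f"{name} must be in 1..5, got {v}")
    return config.australian["table"][likelihood - 1][exposure_frequency - 1][severity - 1]


def australian_frequency(ef_days_per_year: float, config: MethodConfig) -> int:
    return band_lookup(config.australian["frequency_bands"], ef_days_per_year)


# ---------------------------------------------------------------- Romanian

def romanian_assess(severity: int, probability: int, config: MethodConfig | None = None) -> int:
    """7×6 severity × probability grid -> level 1..7."""
    config = config or MethodConfig.default()
    if severity not in range(1, 8):
        raise ParameterError(f"severity must be in 1..7, got {severity}")
    if probability not in range(1, 7):
        raise ParameterError(f"probability must be in 1..6, got {probability}")
    return config.romanian["matrix"][severity - 1][probability - 1]


def romanian_severity(hr: int, config: MethodConfig) -> int:
    return config.romanian["severity_from_hr"][hr - 1]


def romanian_probability(cr: float, config: MethodConfig) -> int:
    return band_lookup(config.romanian["probability_bands"], cr)


# ---------------------------------------------------------------- orchestration

@dataclass(frozen=True)
class SkipReason:
    industry: str
    location: str
    hazard: str
    method: str
    reason: str


def assess_all(
    records: Iterable[ExposureRecord],
    registry: dict[str, HazardProfile],
    methods: Sequence[str] = METHODS,
    config: MethodConfig | None = None,
    oel_source: str = "china",
    romanian_denominator: float = 10.0,
    quantity_band: str = "medium",
) -> tuple[list[AssessmentResult], list[SkipReason]]:
    """Score every record with every applicable method.

    Pairs a method cannot score are skipped with a recorded reason rather
    than failing the run; the skip log mirrors real campaigns where e.g. the
    EPA method only covers RfC-bearing chemicals.
    """
    config = config or MethodConfig.default()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ParameterError(f"unknown methods: {sorted(unknown)}")
    scales = default_scales(romanian_denominator)
    results: list[AssessmentResult] = []
    skips: list[SkipReason] = []
    records = list(records)
    if not records:
        log.warning("assess_all called with an empty record set")
        return results, skips

    def skip(rec: ExposureRecord, method: str, reason: str) -> None:
        skips.append(SkipReason(rec.industry, rec.location, rec.hazard, method, reason))

    def make_emit(record_id: int, rec: ExposureRecord):
        def emit(method: str, raw: float, level: float) -> None:
            rrv = level_to_rr(method, level, scales[method])
            results.append(
                AssessmentResult(
                    record_id=record_id,
                    industry=rec.industry, location=rec.location, hazard=rec.hazard,
                    method=method, raw_score=raw, level=level, rr=rrv.rr,
                    rr_display=rrv.rr_display,
                )
            )
        return emit

    for record_id, rec in enumerate(records):
        emit = make_emit(record_id, rec)
        profile = registry.get(rec.hazard)
        if profile is None:
            for method in methods:
                skip(rec, method, "hazard not in registry")
            continue
        try:
            cr: Optional[float] = compute_cr(rec, profile, oel_source)
        except MissingParameterError:
            cr = None
        try:
            hr: Optional[int] = singapore_hr(profile, config)
        except MissingParameterError:
            hr = None

        for method in methods:
            try:
                if method == "EPA":
                    hq = epa_hq(compute_ec(rec), profile.get_rfc())
                    emit(method, hq, epa_level(hq, config))
                elif method == "COSHH":
                    cs, level = coshh_assess(profile, quantity_band, config)
                    emit(method, float(cs[2:]), level)
                elif method == "Singaporean":
                    if hr is None:
                        raise MissingParameterError("no hazard-rating basis")
                    if cr is None:
                        raise MissingParameterError(f"no {oel_source} OEL for exposure rating")
                    er = singapore_er(cr, config)
                    emit(method, math.sqrt(hr * er), singapore_risk(hr, er))
                elif method == "ICMM":
                    if hr is None:
                        raise MissingParameterError("no consequence rating basis")
                    if cr is None:
                        raise MissingParameterError(f"no {oel_source} OEL for probability rating")
                    level = icmm_assess(hr, icmm_probability(cr, config), 2, config)
                    emit(method, level, level)
                elif method == "Australian":
                    if hr is None:
                        raise MissingParameterError("no severity rating basis")
                    if cr is None:
                        raise MissingParameterError(f"no {oel_source} OEL for likelihood rating")
                    level = australian_assess(
                        band_lookup(config.er_bands, cr),
                        australian_frequency(rec.ef, config),
                        hr,
                        config,
                    )
                    emit(method, level, level)
                elif method == "Romanian":
                    if hr is None:
                        raise MissingParameterError("no severity rating basis")
                    if cr is None:
                        raise MissingParameterError(f"no {oel_source} OEL for probability rating")
                    level = romanian_assess(
                        romanian_severity(hr, config), romanian_probability(cr, config), config
                    )
                    emit(method, level, level)
            except (MissingParameterError, UnknownPhraseError) as exc:
                skip(rec, method, str(exc))

    if skips:
        from collections import Counter

        counts = Counter((s.method, s.hazard, s.reason) for s in skips)
        for (method, hazard, reason), n in sorted(counts.items()):
            log.warning("skipped %d %s assessments of %r: %s", n, method, hazard, reason)
    return results, skips


def results_frame(results: Sequence[AssessmentResult], config_checksum: str | None = None):
    """Assessment results as a DataFrame in the results-file column layout."""
    import pandas as pd

    rows = [
        {
            "record_id": r.record_id, "industry": r.industry, "location": r.location,
            "hazard": r.hazard, "method": r.method, "raw_score": r.raw_score,
            "level": r.level, "rr": r.rr, "rr_display": r.rr_display,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=[
        "record_id", "industry", "location", "hazard", "method",
        "raw_score", "level", "rr", "rr_display",
    ])
    if config_checksum is not None:
        frame["config_checksum"] = config_checksum
    return frame


def cr_series(records: Sequence[ExposureRecord], registry: dict[str, HazardProfile],
              oel_source: str = "china"):
    """Concentration ratio per record (indexed by record id; NaN where no OEL)."""
    import pandas as pd

    values = []
    for rec in records:
        profile = registry.get(rec.hazard)
        try:
            values.append(compute_cr(rec, profile, oel_source) if profile else float("nan"))
        except MissingParameterError:
            values.append(float("nan"))
    return pd.Series(values, index=range(len(values)), name="CR")
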