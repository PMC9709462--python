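"""Method configuration: band tables and matrices for the six engines.

The published descriptions of the ICMM, Australian and Romanian methods leave
the rating grids to the evaluator's judgment, so reproducibility requires
freezing them: the grids ship as an editable YAML document and every result
is tagged with a checksum of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError


def band_lookup(thresholds: list[float], x: float, base: int = 1) -> int:
    """Rating from a left-closed/right-open breakpoint list.

    ``x`` below the first breakpoint maps to ``base``; each breakpoint starts
    the next rating; the top band is closed above.
    """
    if x < 0:
        raise ParameterError(f"band lookup requires a nonnegative value, got {x}")
    rating = base
    for t in thresholds:
        if x >= t:
            rating += 1
    return rating


@dataclass(frozen=True)
class MethodConfig:
    """Validated, checksummed engine configuration."""

    raw: dict[str, Any] = field(repr=False)

    def __post_init__(self) -> None:
        required = {"hq_bands", "er_bands", "hr_table", "coshh", "icmm", "australian", "romanian", "industry_ir"}
        missing = required - set(self.raw)
        if missing:
            raise ParameterError(f"method config lacks sections: {sorted(missing)}")
        icmm = self.raw["icmm"]["matrix"]
        if len(icmm) != 5 or any(len(row) != 5 for row in icmm):
            raise ParameterError("ICMM matrix must be 5x5")
        aus = self.raw["australian"]["table"]
        if len(aus) != 5 or any(len(p) != 5 or any(len(r) != 5 for r in p) for p in aus):
            raise ParameterError("Australian table must be 5x5x5")
        rom = self.raw["romanian"]["matrix"]
        if len(rom) != 7 or any(len(row) != 6 for row in rom):
            raise ParameterError("Romanian matrix must be 7x6")

    @property
    def hq_bands(self) -> list[float]:
        return list(self.raw["hq_bands"])

    @property
    def er_bands(self) -> list[float]:
        return list(self.raw["er_bands"])

    @property
    def hr_table(self) -> dict[str, Any]:
        return self.raw["hr_table"]

    @property
    def coshh(self) -> dict[str, Any]:
        return self.raw["coshh"]

    @property
    def icmm(self) -> dict[str, Any]:
        return self.raw["icmm"]

    @property
    def australian(self) -> dict[str, Any]:
        return self.raw["australian"]

    @property
    def romanian(self) -> dict[str, Any]:
        return self.raw["romanian"]

    @property
    def industry_ir(self) -> dict[str, str]:
        return self.raw["industry_ir"]

    @property
    def checksum(self) -> str:
        """First 12 hex digits of the SHA-256 of the canonical config JSON."""
        canon = json.dumps(self.raw, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MethodConfig":
        with Path(path).open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "MethodConfig":
        return cls.from_yaml(default_config_path())


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "method_config.yaml"
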