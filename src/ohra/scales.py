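"""Ordinal risk scales of the six assessment methods.

Four of the methods (EPA after hazard-quotient banding, Singaporean, ICMM,
Australian) grade risk on five levels.  COSHH Essentials emits four control
strategies which map onto levels 2-5, so only four levels are attainable.
The Romanian grid has seven levels; its risk-ratio denominator is kept
separate from the number of levels because the two are configured
independently (see :mod:`ohra.harmonize`).
"""

from __future__ import annotations

from dataclasses import dataclass

METHODS = ("EPA", "COSHH", "Singaporean", "ICMM", "Australian", "Romanian")


@dataclass(frozen=True)
class MethodScale:
    """The ordered level set of one method and its RR denominator."""

    method: str
    levels: tuple[int, ...]
    max_level: float
    allows_fractional: bool = False

    def contains(self, level: float) -> bool:
        if self.allows_fractional:
            return self.levels[0] <= level <= self.levels[-1]
        return level in self.levels


def default_scales(romanian_denominator: float = 10.0) -> dict[str, MethodScale]:
    """Scales for the six methods.

    ``romanian_denominator`` is the RR denominator of the Romanian method:
    10 reproduces the published level->RR conversion, 7 matches the stated
    "highest level of the model" definition.
    """
    return {
        "EPA": MethodScale("EPA", (1, 2, 3, 4, 5), 5.0),
        "COSHH": MethodScale("COSHH", (2, 3, 4, 5), 5.0),
        "Singaporean": MethodScale("Singaporean", (1, 2, 3, 4, 5), 5.0),
        "ICMM": MethodScale("ICMM", (1, 2, 3, 4, 5), 5.0),
        "Australian": MethodScale("Australian", (1, 2, 3, 4, 5), 5.0, allows_fractional=True),
        "Romanian": MethodScale("Romanian", (1, 2, 3, 4, 5, 6, 7), romanian_denominator),
    }
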