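"""Risk-scale harmonization: ordinal levels -> risk ratios (RR).

The six methods grade risk on different ordinal scales, so their outputs are
converted to a common dimensionless RR = level / denominator before any
cross-method comparison.  For the five-level methods the denominator is the
top level (5), so the attainable RRs are exactly {0.2, 0.4, 0.6, 0.8, 1.0}.
The Romanian denominator defaults to 10 — the conversion consistent with the
published level->RR tables — and can be set to the seven-level maximum via
``romanian_denominator=7``.

RR is kept at full precision internally; the one-decimal display value
(rounded half-up, as the published tables print) exists only for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError, ScaleError
from .scales import MethodScale


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with halves away from zero (0.25 -> 0.3 at 1 digit)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class RRValue:
    method: str
    level: float
    rr: float
    rr_display: float


def level_to_rr(method: str, level: float, scale: MethodScale) -> RRValue:
    """RR = level / scale.max_level, with a one-decimal display companion."""
    if scale.method != method:
        raise ScaleError(f"scale belongs to {scale.method}, not {method}")
    if not scale.contains(level):
        raise ScaleError(f"level {level} outside the {method} scale {scale.levels}")
    rr = level / scale.max_level
    return RRValue(method=method, level=level, rr=rr, rr_display=round_half_up(rr, 1))


_CS_TO_LEVEL = {1: 2, 2: 3, 3: 4, 4: 5}


def coshh_cs_to_level(cs: str | int) -> int:
    """COSHH control strategy CS1-CS4 -> common risk level 2-5."""
    if isinstance(cs, str):
        if not (cs.upper().startswith("CS") and cs[2:].isdigit()):
            raise ParameterError(f"unknown control strategy {cs!r}")
        cs = int(cs[2:])
    if cs not in _CS_TO_LEVEL:
        raise ParameterError(f"unknown control strategy CS{cs}")
    return _CS_TO_LEVEL[cs]


def format_median_range(median: float, lo: float, hi: float) -> str:
    """``median (lo–hi)`` with one-decimal half-up rounding, as reports print."""
    return f"{round_half_up(median, 1):.1f} ({round_half_up(lo, 1):.1f}–{round_half_up(hi, 1):.1f})"


def summarize_rr(results: pd.DataFrame, group_by: list[str]) -> pd.DataFrame:
    """Median and min–max RR per group, display-rounded.

    ``results`` must carry an ``rr`` column plus the grouping keys.  Empty
    groups cannot arise from a groupby; an empty input yields an empty table.
    """
    if results.empty:
        return pd.DataFrame(columns=group_by + ["n", "rr_median", "rr_min", "rr_max", "display"])
    grouped = results.groupby(group_by, sort=False)["rr"]
    out = grouped.agg(n="size", rr_median="median", rr_min="min", rr_max="max").reset_index()
    for col in ("rr_median", "rr_min", "rr_max"):
        out[col] = out[col].map(lambda v: round_half_up(v, 1))
    out["display"] = [
        format_median_range(m, lo, hi)
        for m, lo, hi in zip(out["rr_median"], out["rr_min"], out["rr_max"])
    ]
    return out
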