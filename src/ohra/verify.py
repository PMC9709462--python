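"""Relative-accuracy verification against inherent risk (IR).

A method is judged by whether the ordering of its harmonized risk ratios
across groups (industries, or focal chemicals) reproduces the groups' inherent
risk — the catalog-assigned tier of an industry, or the toxicity/exposure
rank of a chemical — and by whether it can statistically separate the groups
at all.

Because "consistent with the IR sequence" admits stricter and looser
readings, the report carries both components separately: the weak ordering of
group medians along IR ranks, and the significance of each adjacent-tier
separation.  The headline ``consistent`` flag requires both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import MethodConfig
from .errors import OhraError, ParameterError
from .exposure import InherentRisk
from .registry import HazardProfile


def ir_rank_industries(
    industries: Sequence[str], catalog: Optional[Mapping[str, str]] = None
) -> dict[str, InherentRisk]:
    """Catalog inherent-risk tier and rank per industry (severe=1 … low=3)."""
    catalog = dict(catalog) if catalog is not None else MethodConfig.default().industry_ir
    out = {}
    for industry in industries:
        if industry not in catalog:
            raise OhraError(f"industry {industry!r} not in the IR catalog")
        out[industry] = InherentRisk.from_tier(catalog[industry])
    return out


def ir_rank_hazards(
    profiles: Sequence[HazardProfile],
    cr_ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    rfc_tie_factor: float = 5.0,
) -> list[tuple[str, int]]:
    """Rank chemicals by inherent risk: smaller RfC = more severe, rank 1 first.

    Chemicals whose RfCs lie within ``rfc_tie_factor`` of each other are tied
    when their concentration-ratio ranges overlap (similar exposure
    probability); hazards without an RfC are excluded with a warning.
    Competition ranking: ties share a rank, the next rank skips.
    """
    import logging

    ranked = []
    for p in profiles:
        if p.rfc is None:
            logging.getLogger(__name__).warning(
                "hazard %r has no RfC and is excluded from IR ranking", p.name
            )
            continue
        ranked.append((p.name, p.rfc))
    ranked.sort(key=lambda t: t[1])

    def tied(a: tuple[str, float], b: tuple[str, float]) -> bool:
        if a[1] <= 0 or b[1] <= 0:
            return False
        if max(a[1], b[1]) / min(a[1], b[1]) > rfc_tie_factor:
            return False
        if cr_ranges is None:
            return True
        if a[0] not in cr_ranges or b[0] not in cr_ranges:
            return True
        (alo, ahi), (blo, bhi) = cr_ranges[a[0]], cr_ranges[b[0]]
        return alo <= bhi and blo <= ahi  # overlapping CR ranges

    out: list[tuple[str, int]] = []
    for i, item in enumerate(ranked):
        if i > 0 and tied(ranked[i - 1], item):
            out.append((item[0], out[-1][1]))
        else:
            out.append((item[0], i + 1))
    return out


@dataclass
class ConsistencyReport:
    """Per-method verdict of IR consistency and group separability."""

    method: str
    alpha: float
    group_medians: dict[str, float]
    ir_ranks: dict[str, int]
    ordering_ok: bool
    adjacent_separation: dict[str, bool]
    consistent: bool
    distinguishes_all: bool

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "group_medians": self.group_medians,
            "ir_ranks": self.ir_ranks,
            "ordering_ok": self.ordering_ok,
            "adjacent_separation": self.adjacent_separation,
            "consistent": self.consistent,
            "distinguishes_all": self.distinguishes_all,
        }

    def to_text(self) -> str:
        order = sorted(self.group_medians, key=lambda g: (self.ir_ranks[g], -self.group_medians[g]))
        lines = [f"[{self.method}] alpha = {self.alpha}"]
        for g in order:
            lines.append(f"  IR rank {self.ir_ranks[g]}: {g}: median RR {self.group_medians[g]:.2f}")
        lines.append(f"  median ordering follows IR: {self.ordering_ok}")
        for boundary, ok in self.adjacent_separation.items():
            lines.append(f"  separation {boundary}: {'significant' if ok else 'not significant'}")
        lines.append(f"  consistent with IR sequence: {self.consistent}")
        lines.append(f"  distinguishes all groups: {self.distinguishes_all}")
        return "\n".join(lines) + "\n"


def check_consistency(
    rr_summary: pd.DataFrame,
    ir_ranks: Mapping[str, int],
    pairwise_p: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "",
) -> ConsistencyReport:
    """Judge one method's RR ordering against inherent-risk ranks.

    ``rr_summary`` holds one row per group with columns ``group`` and
    ``rr_median``; ``pairwise_p`` is the square Mann–Whitney p table over the
    same groups.  Consistency = weakly decreasing medians along increasing IR
    rank (ties allowed within a rank) and, at every adjacent-rank boundary, at
    least one significant cross-boundary pair.
    """
    groups = list(rr_summary["group"])
    if set(groups) != set(ir_ranks) or set(groups) != set(pairwise_p.columns):
        raise OhraError("group sets of summaries, IR ranks and p-matrix differ")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    medians = dict(zip(rr_summary["group"], rr_summary["rr_median"]))

    # weak ordering: every group at a higher-IR (smaller) rank has a median
    # >= every group at a lower-IR rank
    ranks = sorted(set(ir_ranks.values()))
    by_rank = {r: [g for g in groups if ir_ranks[g] == r] for r in ranks}
    ordering_ok = True
    for hi, lo in zip(ranks, ranks[1:]):
        if min(medians[g] for g in by_rank[hi]) < max(medians[g] for g in by_rank[lo]):
            ordering_ok = False

    adjacent = {}
    for hi, lo in zip(ranks, ranks[1:]):
        pvals = [pairwise_p.loc[a, b] for a in by_rank[hi] for b in by_rank[lo]]
        adjacent[f"rank{hi}-rank{lo}"] = any(pd.notna(p) and p < alpha for p in pvals)

    offdiag = [
        pairwise_p.loc[a, b] for i, a in enumerate(groups) for b in groups[i + 1:]
    ]
    distinguishes_all = all(pd.notna(p) and p < alpha for p in offdiag) and len(offdiag) > 0

    consistent = ordering_ok and all(adjacent.values()) and len(adjacent) > 0
    return ConsistencyReport(
        method=method, alpha=alpha, group_medians=medians, ir_ranks=dict(ir_ranks),
        ordering_ok=ordering_ok, adjacent_separation=adjacent,
        consistent=consistent, distinguishes_all=distinguishes_all,
    )
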