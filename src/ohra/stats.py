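"""Nonparametric comparison of RR/CR distributions.

Risk ratios take at most seven distinct values, so ties are massive and every
procedure here is rank-based with midrank tie handling: Kruskal–Wallis across
groups, Mann–Whitney between pairs (exact permutation enumeration when both
samples have at most 8 observations, tie-corrected normal approximation
otherwise), and Spearman correlation between methods and against CR with
pairwise-complete deletion (the EPA column is missing wherever no RfC
exists).

Tests are two-sided and raw p-values are reported at α = 0.05 by default; an
optional Holm step-down adjustment is available but off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

EXACT_MW_MAX_N = 8


def kruskal_wallis_rr(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with midrank tie correction and chi-square p."""
    if len(groups) < 2:
        raise ParameterError("Kruskal–Wallis requires at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ParameterError("Kruskal–Wallis groups must be nonempty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if np.ptp(np.concatenate(arrays)) == 0:
        # every observation identical: H is 0 by definition, scipy raises
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney_rr(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for the first sample.

    Exact permutation enumeration when both n ≤ 8 (valid under ties),
    otherwise the tie-corrected normal approximation.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("Mann–Whitney requires two nonempty samples")
    if min(len(a), len(b)) >= 2 and len(a) <= EXACT_MW_MAX_N and len(b) <= EXACT_MW_MAX_N:
        # full enumeration: comb(16, 8) = 12,870 splits at most
        method = sps.PermutationMethod(n_resamples=20_000)
    elif len(set(a) | set(b)) == len(a) + len(b) and len(a) <= EXACT_MW_MAX_N and len(b) <= EXACT_MW_MAX_N:
        method = "exact"  # singleton samples: tie-free exact distribution
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def pairwise_mann_whitney(groups: Mapping[str, Sequence[float]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """U and two-sided p for every unordered group pair, as square tables."""
    names = list(groups)
    u = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for x, y in combinations(names, 2):
        stat, pval = mann_whitney_rr(groups[x], groups[y])
        u.loc[x, y] = u.loc[y, x] = stat
        p.loc[x, y] = p.loc[y, x] = pval
    return u, p


MIN_SPEARMAN_PAIRS = 3


def spearman_matrix(
    rr_table: pd.DataFrame, cr: Optional[pd.Series] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Midrank Spearman rho and p over method columns, plus a CR row.

    Pairwise-complete deletion per cell; cells with fewer than three complete
    pairs are reported as NaN (not computable), never as zero.
    """
    table = rr_table.copy()
    if cr is not None:
        table["CR"] = cr
    cols = list(table.columns)
    rho = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    p = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, x in enumerate(cols):
        for y in cols[i:]:
            pair = table[[x, y]].dropna()
            if len(pair) < MIN_SPEARMAN_PAIRS:
                continue
            if x == y:
                rho.loc[x, y] = 1.0
                p.loc[x, y] = 0.0
                continue
            r, pv = sps.spearmanr(pair[x], pair[y])
            rho.loc[x, y] = rho.loc[y, x] = float(r)
            p.loc[x, y] = p.loc[y, x] = float(pv)
    return rho, p


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; reports are raw by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


@dataclass
class ComparisonReport:
    """Omnibus, pairwise and correlation comparison of harmonized RRs."""

    alpha: float
    omnibus: dict[str, dict[str, float]]
    pairwise_u: pd.DataFrame
    pairwise_p: pd.DataFrame
    rho: pd.DataFrame
    rho_p: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "omnibus": self.omnibus,
            "pairwise_u": json.loads(self.pairwise_u.to_json()),
            "pairwise_p": json.loads(self.pairwise_p.to_json()),
            "spearman_rho": json.loads(self.rho.to_json()),
            "spearman_p": json.loads(self.rho_p.to_json()),
        }
        return json.dumps(payload, indent=2)

    def significance_marks(self) -> dict[str, str]:
        """Letter marks per group: one letter for each other group it differs
        from at α, in the style of published table footnotes."""
        names = list(self.pairwise_p.columns)
        letters = {name: chr(ord("a") + i) for i, name in enumerate(names)}
        marks = {}
        for name in names:
            sig = [
                letters[other]
                for other in names
                if other != name and self.pairwise_p.loc[name, other] < self.alpha
            ]
            marks[name] = "".join(sig)
        return marks

    def to_text(self) -> str:
        lines = [f"alpha = {self.alpha}"]
        for key, entry in self.omnibus.items():
            lines.append(f"Kruskal–Wallis [{key}]: H = {entry['H']:.3f}, p = {entry['p']:.4g}")
        lines.append("")
        lines.append("Pairwise Mann–Whitney p (two-sided):")
        lines.append(self.pairwise_p.round(4).to_string())
        marks = self.significance_marks()
        lines.append("significance marks: " + "; ".join(f"{k}: {v or '-'}" for k, v in marks.items()))
        lines.append("")
        lines.append("Spearman rho:")
        lines.append(self.rho.round(3).to_string())
        lines.append("Spearman p:")
        lines.append(self.rho_p.round(4).to_string())
        return "\n".join(lines) + "\n"


def compare_methods(
    results: pd.DataFrame,
    cr: Optional[pd.Series] = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Full comparison across the ``method`` column of a results table.

    ``results`` needs ``record_id``, ``method`` and ``rr`` columns; records
    are aligned across methods by ``record_id``.  ``cr`` is an optional
    concentration-ratio series indexed by ``record_id``.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    groups = {m: g["rr"].to_numpy() for m, g in results.groupby("method", sort=False)}
    omnibus = {}
    if len(groups) >= 2:
        h, p = kruskal_wallis_rr(list(groups.values()))
        omnibus["method"] = {"H": h, "p": p}
    u, pmat = pairwise_mann_whitney(groups)
    wide = results.pivot(index="record_id", columns="method", values="rr")
    wide.columns.name = None
    if cr is not None:
        cr = cr.reindex(wide.index)
    rho, rho_p = spearman_matrix(wide, cr)
    return ComparisonReport(alpha=alpha, omnibus=omnibus, pairwise_u=u,
                            pairwise_p=pmat, rho=rho, rho_p=rho_p)
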