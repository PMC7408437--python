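"""Marker-association tests: expression vs binary status or ordinal levels.

Binary groupings (e.g. MYCN amplified vs not) use the two-sided two-sample
t-test; ordinal groupings (tumor stage, genetic-alteration categories) use
one-way ANOVA with the level order preserved in the summaries. P-values map
onto the significance tiers *, **, ***, >*** at the 0.05 / 0.01 / 0.001 /
0.0001 boundaries, each boundary belonging to the more significant tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .selection import welch_t

__all__ = [
    "AssociationResult",
    "binary_association",
    "ordinal_association",
    "significance_tier",
]

_TIERS = ((1e-4, ">***"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_tier(p: float) -> str:
    """Map a p-value to the figure-annotation tier (boundaries inclusive)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value out of [0, 1]: {p}")
    for cut, tier in _TIERS:
        if p <= cut:
            return tier
    return "ns"


@dataclass
class AssociationResult:
    """One gene x one grouping covariate test with per-level summaries."""

    gene: str
    grouping: str
    test: str  # "t_test" | "anova"
    statistic: float
    p: float
    tier: str
    levels: list
    group_means: list[float] = field(default_factory=list)
    group_sds: list[float] = field(default_factory=list)
    group_ns: list[int] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "mean": self.group_means,
             "sd": self.group_sds, "n": self.group_ns}
        )


def _summaries(groups: list[np.ndarray]) -> tuple[list[float], list[float], list[int]]:
    means = [float(g.mean()) for g in groups]
    sds = [float(g.std(ddof=1)) for g in groups]
    ns = [int(g.size) for g in groups]
    return means, sds, ns


def binary_association(values, status, gene: str = "", grouping: str = "",
                       pooled: bool = False) -> AssociationResult:
    """Two-group expression test against a binary status vector.

    Delegates to :func:`biclustsurv.selection.welch_t` (pooled variant on
    request) and records mean / sd / n per level for error-bar reporting.
    """
    x = np.asarray(values, dtype=float)
    s = np.asarray(status)
    levels = pd.unique(s)
    if levels.size != 2:
        raise DegenerateInputError(f"binary grouping must have 2 levels, got {levels.size}")
    levels = sorted(levels.tolist())
    groups = [x[s == lv] for lv in levels]
    if any(g.size < 2 for g in groups):
        raise DegenerateInputError("each level needs >= 2 observations")
    # statistic sign: level-1 (e.g. amplified) minus level-0
    stat, p = welch_t(groups[1], groups[0], pooled=pooled)
    means, sds, ns = _summaries(groups)
    return AssociationResult(
        gene=gene, grouping=grouping, test="t_test",
        statistic=stat, p=p, tier=significance_tier(p),
        levels=levels, group_means=means, group_sds=sds, group_ns=ns,
    )


def ordinal_association(values, level, gene: str = "", grouping: str = "",
                        small_level_policy: str = "error") -> AssociationResult:
    """One-way ANOVA of expression across ordered levels.

    Levels are kept in their sorted (ordinal) order in the summaries. A level
    with fewer than 2 observations triggers an error, or is merged into the
    adjacent lower level when ``small_level_policy="merge"``.
    """
    if small_level_policy not in ("error", "merge"):
        raise ValidationError(f"unknown small_level_policy {small_level_policy!r}")
    x = np.asarray(values, dtype=float)
    lv = pd.Series(np.asarray(level))
    levels = sorted(lv.unique().tolist())
    if len(levels) < 2:
        raise DegenerateInputError("need >= 2 levels")

    groups = {l: x[(lv == l).to_numpy()] for l in levels}
    small = [l for l in levels if groups[l].size < 2]
    if small:
        if small_level_policy == "error":
            raise DegenerateInputError(f"level(s) {small} have < 2 observations")
        for l in small:
            idx = levels.index(l)
            neighbor = levels[idx - 1] if idx > 0 else levels[idx + 1]
            groups[neighbor] = np.concatenate([groups[neighbor], groups.pop(l)])
            levels.remove(l)
        if len(levels) < 2:
            raise DegenerateInputError("fewer than 2 levels after merging")

    arrays = [groups[l] for l in levels]
    total_var = np.concatenate(arrays).var()
    if total_var == 0:
        f, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*arrays)
        f, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # within-group variance zero, means differ
            f, p = float("inf"), 0.0
    means, sds, ns = _summaries(arrays)
    return AssociationResult(
        gene=gene, grouping=grouping, test="anova",
        statistic=f, p=p, tier=significance_tier(p),
        levels=levels, group_means=means, group_sds=sds, group_ns=ns,
    )
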