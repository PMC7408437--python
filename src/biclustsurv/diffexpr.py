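"""Subtype differential-expression panels and cross-cohort overlap statistics.

Genes are called up- or down-regulated in the UHR subtype by a two-sample
t-test plus a linear fold-change gate (fold > ``min_fold`` in the respective
direction and raw p < ``max_p``, no multiplicity correction). Panel agreement
between independently analysed cohorts is scored with the Jaccard index
``|A∩B| / (|A|+|B|-|A∩B|)`` and with the combinatorial probability
``1 / (C(n1,p) * C(n2,p))`` of drawing two specific subsets that share ``p``
genes — a lower bound on the chance-overlap probability, kept exactly as
printed; the hypergeometric tail is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateInputError, ValidationError
from .selection import GenePanel, _welch_t_rows, benjamini_hochberg
from .subtypes import HR_LABEL, UHR_LABEL

__all__ = [
    "DECriteria",
    "OverlapResult",
    "differential_genes",
    "cross_cohort_overlap",
    "random_overlap_probability",
    "hypergeom_overlap_pvalue",
]


@dataclass(frozen=True)
class DECriteria:
    """Fold / p thresholds for a differential panel.

    Defaults reflect the subtype panel (fold > 1.5, p < 1e-3); the
    genome-wide immune variant uses ``max_p=1e-4``.
    """

    min_fold: float = 1.5
    max_p: float = 1.0e-3
    scale: str = "log2"
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValidationError(f"min_fold must be > 1, got {self.min_fold}")
        if not 0 < self.max_p < 1:
            raise ValidationError(f"max_p must be in (0, 1), got {self.max_p}")
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"scale must be 'log2' or 'linear', got {self.scale!r}")


@dataclass
class OverlapResult:
    """Agreement of two gene panels derived in independent cohorts."""

    common: list[str]
    jaccard: float | None
    n1: int
    n2: int
    n_common: int
    random_prob: float
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "n_common": self.n_common,
            "jaccard": self.jaccard,
            "random_prob": self.random_prob,
            "common": self.common,
        }


def differential_genes(
    expr: pd.DataFrame,
    subtype_labels,
    criteria: DECriteria | None = None,
    case_label: str = UHR_LABEL,
    control_label: str = HR_LABEL,
) -> tuple[GenePanel, GenePanel]:
    """Split genes into UHR-up and UHR-down panels.

    ``expr`` is genes x samples; ``subtype_labels`` assigns each column to the
    case (UHR) or control (HR) subtype. Returns ``(up_panel, down_panel)``;
    the up panel holds genes with case/control fold > ``min_fold``, the down
    panel control/case fold > ``min_fold``, both at p < ``max_p``. The panels
    are disjoint by construction and each is ordered by descending fold, ties
    by symbol.
    """
    criteria = criteria or DECriteria()
    labels = pd.Series(np.asarray(subtype_labels), index=expr.columns)
    case = expr.loc[:, (labels == case_label).to_numpy()]
    control = expr.loc[:, (labels == control_label).to_numpy()]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise DegenerateInputError(
            f"each subtype needs >= 2 samples, got {case.shape[1]} and {control.shape[1]}"
        )

    missing = expr.isna().any(axis=1)
    if missing.any():
        case, control = case.loc[~missing], control.loc[~missing]

    A, B = case.to_numpy(dtype=float), control.to_numpy(dtype=float)
    t, p = _welch_t_rows(A, B, pooled=criteria.pooled)
    delta = A.mean(axis=1) - B.mean(axis=1)
    if criteria.scale == "log2":
        log2fc = delta
        fold = 2.0**delta
    else:
        with np.errstate(divide="ignore"):
            fold = A.mean(axis=1) / B.mean(axis=1)
            log2fc = np.log2(fold)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold": fold,
            "t": t,
            "p": p,
            "bh_q": benjamini_hochberg(p),
        },
        index=case.index,
    )
    sig = table["p"] < criteria.max_p
    up_mask = sig & (table["fold"] > criteria.min_fold)
    down_mask = sig & (1.0 / table["fold"] > criteria.min_fold)

    def _panel(mask: pd.Series, direction: str) -> GenePanel:
        sub = table.loc[mask].copy()
        sub["direction"] = direction
        key = sub["fold"] if direction == "up" else 1.0 / sub["fold"]
        sub = sub.assign(_key=key).reset_index(names="gene")
        sub = sub.sort_values(["_key", "gene"], ascending=[False, True]).drop(columns="_key")
        return GenePanel(genes=list(sub["gene"]), stats=sub.set_index("gene"),
                         criteria=criteria, meta={"direction": direction})

    return _panel(up_mask, "up"), _panel(down_mask, "down")


def cross_cohort_overlap(panel_a, panel_b) -> OverlapResult:
    """Jaccard index and combinatorial overlap probability of two panels."""
    a = panel_a.as_set() if isinstance(panel_a, GenePanel) else set(panel_a)
    b = panel_b.as_set() if isinstance(panel_b, GenePanel) else set(panel_b)
    inter = a & b
    union = a | b
    undefined = not union
    jac = None if undefined else len(inter) / len(union)
    prob = random_overlap_probability(len(a), len(b), len(inter)) if not undefined else 1.0
    return OverlapResult(
        common=sorted(inter),
        jaccard=jac,
        n1=len(a),
        n2=len(b),
        n_common=len(inter),
        random_prob=prob,
        undefined=undefined,
    )


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def random_overlap_probability(n1: int, n2: int, p: int) -> float:
    """``1 / (C(n1, p) * C(n2, p))`` computed in log space.

    The probability that two specific p-subsets drawn from sets of sizes n1
    and n2 are exactly the observed common genes; a lower bound on the chance
    of the observed overlap, not a hypergeometric tail.
    """
    if p < 0 or p > min(n1, n2):
        raise ValidationError(f"p={p} must be in [0, min(n1={n1}, n2={n2})]")
    return float(np.exp(-(_log_comb(n1, p) + _log_comb(n2, p))))


def hypergeom_overlap_pvalue(universe: int, n1: int, n2: int, n_common: int) -> float:
    """P(overlap >= n_common) for random n1-, n2-subsets of a gene universe.

    Offered separately from :func:`random_overlap_probability`; this is the
    proper tail probability under the hypergeometric null.
    """
    if n_common > min(n1, n2) or max(n1, n2) > universe:
        raise ValidationError("inconsistent set sizes")
    return float(stats.hypergeom.sf(n_common - 1, universe, n1, n2))
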