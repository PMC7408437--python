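"""Tumor-specificity gene filter.

A gene is *specific* to the target tumor type when, against **every** other
tumor type, its fold change exceeds ``min_fold`` and its two-sided t-test
p-value is below ``max_p``. P-values are raw — no multiplicity correction is
applied to the selection, although a Benjamini-Hochberg column is emitted for
transparency. A one-way ANOVA p across all types is reported per gene but is
not part of the selection predicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "SpecificityCriteria",
    "GenePanel",
    "welch_t",
    "select_specific_genes",
    "benjamini_hochberg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecificityCriteria:
    """Thresholds for the specificity filter.

    ``min_fold`` is a linear fold-change floor applied against every other
    tumor type; ``max_p`` is a per-comparison raw p ceiling. ``scale`` tells
    the filter whether the matrix is ``"log2"`` (fold computed as
    ``2 ** mean difference``) or ``"linear"`` (ratio of means).
    """

    min_fold: float = 2.0
    max_p: float = 1.0e-5
    scale: str = "log2"
    pooled: bool = False  # True restores the classical equal-variance t-test

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValidationError(f"min_fold must be > 1, got {self.min_fold}")
        if not 0 < self.max_p < 1:
            raise ValidationError(f"max_p must be in (0, 1), got {self.max_p}")
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"scale must be 'log2' or 'linear', got {self.scale!r}")


@dataclass
class GenePanel:
    """An ordered gene list together with the per-gene statistics behind it."""

    genes: list[str]
    stats: pd.DataFrame
    criteria: object | None = None
    n_excluded_missing: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


def welch_t(group_a, group_b, pooled: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch by default, pooled on request.

    Zero-variance conventions (limits of the t statistic): if both groups are
    constant and equal, the statistic is 0 and p = 1; if constant and unequal,
    the statistic is signed infinity and p = 0.

    Returns ``(statistic, two_sided_p)`` with the statistic's sign equal to
    the sign of ``mean(group_a) - mean(group_b)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError(
            f"each group needs >= 2 values, got {a.size} and {b.size}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateInputError("groups must contain only finite values")

    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size

    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    else:
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = na + nb - 2  # unused: degenerate branch below

    if se2 == 0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0

    t = (ma - mb) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def _welch_t_rows(A: np.ndarray, B: np.ndarray, pooled: bool = False
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test. A, B: genes x samples arrays.

    Vectorized twin of :func:`welch_t`; the unit tests assert row-by-row
    equality against the scalar implementation.
    """
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    if pooled:
        df = np.full(A.shape[0], na + nb - 2, dtype=float)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)

    zero = se2 == 0
    if zero.any():
        eq = zero & (ma == mb)
        ne = zero & (ma != mb)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.copysign(np.inf, (ma - mb)[ne])
        p[ne] = 0.0
    return t, p


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (emitted for transparency, never used to select)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _fold_from_delta(delta_mean: np.ndarray, scale: str,
                     mean_target=None, mean_other=None) -> np.ndarray:
    if scale == "log2":
        return 2.0 ** np.asarray(delta_mean, dtype=float)
    return np.asarray(mean_target, dtype=float) / np.asarray(mean_other, dtype=float)


def select_specific_genes(
    expr: pd.DataFrame,
    tumor_labels: pd.Series | np.ndarray,
    target_type: str,
    criteria: SpecificityCriteria | None = None,
    gene_list: list[str] | None = None,
) -> GenePanel:
    """Select genes upregulated in ``target_type`` versus every other type.

    Parameters
    ----------
    expr
        Genes x samples matrix (rows indexed by gene symbol).
    tumor_labels
        Tumor-type label per sample, aligned with ``expr``'s columns.
    target_type
        The type the panel must be specific to.
    criteria
        Fold / p thresholds; defaults to fold > 2, p < 1e-5 on log2 data.
    gene_list
        Optional symbol whitelist (e.g. an immune-gene list); selection is
        restricted to listed genes when provided.

    Returns a :class:`GenePanel` whose ``stats`` frame holds one row per
    evaluated gene (columns ``min_fold``, ``max_p_across_comparisons``,
    ``anova_p``, ``selected``, ``bh_q`` plus per-type folds and p-values);
    ``genes`` lists the selected symbols ordered by descending minimum fold,
    ties broken by symbol.
    """
    criteria = criteria or SpecificityCriteria()
    labels = pd.Series(np.asarray(tumor_labels), index=expr.columns)
    types = labels.unique()
    if len(types) < 2:
        raise ValidationError("need >= 2 tumor types")
    if target_type not in set(types):
        raise ValidationError(f"target type {target_type!r} absent from labels")
    if labels.isna().any():
        raise ValidationError("every sample must carry a tumor-type label")

    if gene_list is not None:
        keep = expr.index.intersection(pd.Index(gene_list))
        expr = expr.loc[keep]

    missing = expr.isna().any(axis=1)
    n_missing = int(missing.sum())
    if n_missing:
        log.warning("excluding %d gene(s) with missing values", n_missing)
        expr = expr.loc[~missing]

    values = expr.to_numpy(dtype=float)
    target_block = values[:, (labels == target_type).to_numpy()]
    others = [t for t in types if t != target_type]

    stats_cols: dict[str, np.ndarray] = {}
    fold_mat = np.empty((values.shape[0], len(others)))
    p_mat = np.empty_like(fold_mat)
    mean_t = target_block.mean(axis=1)
    for j, other in enumerate(others):
        block = values[:, (labels == other).to_numpy()]
        if target_block.shape[1] < 2 or block.shape[1] < 2:
            raise DegenerateInputError(f"type {other!r} or target has < 2 samples")
        _, p = _welch_t_rows(target_block, block, pooled=criteria.pooled)
        mean_o = block.mean(axis=1)
        fold = _fold_from_delta(mean_t - mean_o, criteria.scale, mean_t, mean_o)
        fold_mat[:, j] = fold
        p_mat[:, j] = p
        stats_cols[f"fold_vs_{other}"] = fold
        stats_cols[f"p_vs_{other}"] = p

    groups = [values[:, (labels == t).to_numpy()] for t in types]
    anova = stats_f_oneway_rows(groups)

    min_fold = fold_mat.min(axis=1)
    max_p = p_mat.max(axis=1)
    selected = (min_fold > criteria.min_fold) & (max_p < criteria.max_p)

    table = pd.DataFrame(
        {
            "min_fold": min_fold,
            "max_p_across_comparisons": max_p,
            "anova_p": anova,
            "selected": selected,
            "bh_q": benjamini_hochberg(max_p),
            **stats_cols,
        },
        index=expr.index,
    )
    # descending min_fold, ties by symbol ascending
    chosen = table.loc[selected].reset_index(names="gene")
    chosen = chosen.sort_values(["min_fold", "gene"], ascending=[False, True])
    return GenePanel(
        genes=list(chosen["gene"]),
        stats=table,
        criteria=criteria,
        n_excluded_missing=n_missing,
    )


def stats_f_oneway_rows(groups: list[np.ndarray]) -> np.ndarray:
    """Row-wise one-way ANOVA p across the given genes x samples blocks."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # constant rows in every group yield nan; by the zero-variance convention
    # equal means -> p 1, unequal -> p 0
    if np.isnan(p).any():
        means = np.stack([g.mean(axis=1) for g in groups])
        allvar = np.stack([g.var(axis=1) for g in groups]).sum(axis=0)
        nan = np.isnan(p)
        equal = np.all(means == means[0], axis=0)
        p[nan & (allvar == 0) & equal] = 1.0
        p[nan & (allvar == 0) & ~equal] = 0.0
    return p
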