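"""Synthetic expression cohorts with planted structure.

Two generators cover the structures the analysis stages assume:

* :func:`simulate_pan_cancer` — a multi-tumor-type expression matrix with a
  block of genes upregulated in exactly one designated tumor type, used to
  exercise the tumor-specificity filter.
* :func:`simulate_cohort` — a single high-risk cohort with a planted
  ``k_row x k_col`` checkerboard bicluster structure, exponential survival
  whose hazard depends on the planted sample cluster, independent exponential
  censoring with an administrative follow-up cap, and a per-cluster binary
  MYCN-amplification status.

Expression is simulated on the log2 scale. All randomness flows through
named streams derived from a single integer seed (see :mod:`biclustsurv._rng`),
so outputs are byte-reproducible and adding a stream never shifts the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .errors import ValidationError

__all__ = [
    "PanCancerSpec",
    "CohortSpec",
    "GroundTruth",
    "checkerboard_means",
    "simulate_pan_cancer",
    "simulate_cohort",
]

DEFAULT_BASE_MEAN = 6.0


@dataclass(frozen=True)
class PanCancerSpec:
    """Design of a pan-cancer matrix with one tumor type carrying specific genes.

    ``n_specific`` genes get a mean shift of ``effect_log2fc`` log2 units in the
    target tumor type only; every other gene/type mean equals ``base_mean``.
    """

    n_tumor_types: int = 4
    samples_per_type: int = 30
    n_genes: int = 500
    n_specific: int = 50
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    base_mean: float = DEFAULT_BASE_MEAN
    target_type: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specific > self.n_genes:
            raise ValidationError(
                f"n_specific ({self.n_specific}) must be <= n_genes ({self.n_genes})"
            )
        if self.effect_log2fc <= 0:
            raise ValidationError(f"effect_log2fc must be > 0, got {self.effect_log2fc}")
        if self.samples_per_type < 3:
            raise ValidationError(
                f"samples_per_type must be >= 3, got {self.samples_per_type}"
            )
        if self.n_tumor_types < 2:
            raise ValidationError(f"n_tumor_types must be >= 2, got {self.n_tumor_types}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.target_type < self.n_tumor_types:
            raise ValidationError(
                f"target_type must index a tumor type, got {self.target_type}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Design of one high-risk cohort with a planted checkerboard.

    Expression for sample i, gene j is drawn from
    ``Normal(block_means[row_cluster(i), col_cluster(j)], noise_sd)``.
    Event times are exponential with the per-cluster rate in ``hazards``
    (events per month); censoring is an independent exponential at
    ``censor_rate`` plus the administrative cap ``followup_cap``.
    """

    n_samples: int = 150
    n_genes: int = 283
    k_row: int = 3
    k_col: int = 3
    block_means: np.ndarray | None = None
    noise_sd: float = 0.3
    hazards: tuple[float, ...] = (0.05, 0.05, 0.12)
    censor_rate: float = 0.01
    followup_cap: float = 120.0
    mycn_prob: tuple[float, ...] | None = None
    block_sep: float = 1.5
    base_mean: float = DEFAULT_BASE_MEAN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < self.k_row or self.n_genes < self.k_col:
            raise ValidationError("need at least one sample/gene per planted cluster")
        if len(self.hazards) != self.k_row:
            raise ValidationError(
                f"hazards has length {len(self.hazards)}, expected k_row={self.k_row}"
            )
        if any(h <= 0 for h in self.hazards):
            raise ValidationError(f"all hazards must be > 0, got {self.hazards}")
        if self.censor_rate < 0:
            raise ValidationError(f"censor_rate must be >= 0, got {self.censor_rate}")
        if self.followup_cap <= 0:
            raise ValidationError(f"followup_cap must be > 0, got {self.followup_cap}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        bm = self.resolved_block_means()
        if bm.shape != (self.k_row, self.k_col):
            raise ValidationError(
                f"block_means shape {bm.shape} != (k_row, k_col)="
                f"({self.k_row}, {self.k_col})"
            )
        mp = self.resolved_mycn_prob()
        if len(mp) != self.k_row or any(not 0 <= p <= 1 for p in mp):
            raise ValidationError("mycn_prob must give one probability in [0,1] per cluster")

    def resolved_block_means(self) -> np.ndarray:
        if self.block_means is None:
            return checkerboard_means(
                self.k_row, self.k_col, base=self.base_mean, sep=self.block_sep
            )
        return np.asarray(self.block_means, dtype=float)

    def resolved_mycn_prob(self) -> tuple[float, ...]:
        if self.mycn_prob is None:
            # worst-hazard cluster enriched for amplification, mirroring known biology
            worst = int(np.argmax(self.hazards))
            return tuple(0.5 if c == worst else 0.2 for c in range(self.k_row))
        return tuple(self.mycn_prob)


@dataclass
class GroundTruth:
    """Planted labels plus the analytically known worst-vs-rest hazard ratio."""

    sample_labels: np.ndarray
    gene_labels: np.ndarray | None = None
    true_hr: float | None = None
    worst_cluster: int | None = None
    specific_genes: list[str] = field(default_factory=list)


def checkerboard_means(k_row: int, k_col: int, base: float = DEFAULT_BASE_MEAN,
                       sep: float = 1.5) -> np.ndarray:
    """Diagonal-dominant block-mean matrix: ``base + sep`` on the diagonal blocks."""
    means = np.full((k_row, k_col), base, dtype=float)
    for r in range(min(k_row, k_col)):
        means[r, r] += sep
    return means


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(np.arange(k), math.ceil(n / k))[:n]
    rng.shuffle(labels)
    return labels


def simulate_pan_cancer(spec: PanCancerSpec) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a genes x samples pan-cancer matrix with planted specific genes.

    Returns the expression matrix (rows = genes, columns = samples), a Series
    mapping sample id to tumor-type label, and the ground truth listing the
    planted gene symbols.
    """
    n_total = spec.n_tumor_types * spec.samples_per_type
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    samples = np.array([f"S{i:04d}" for i in range(n_total)])
    type_names = np.array([f"type_{t}" for t in range(spec.n_tumor_types)])
    tumor_idx = np.repeat(np.arange(spec.n_tumor_types), spec.samples_per_type)

    rng_genes = stream(spec.seed, "pan_cancer_genes")
    specific_idx = np.sort(rng_genes.choice(spec.n_genes, spec.n_specific, replace=False))

    means = np.full((spec.n_genes, n_total), spec.base_mean)
    target_cols = tumor_idx == spec.target_type
    means[np.ix_(specific_idx, np.flatnonzero(target_cols))] += spec.effect_log2fc

    rng_expr = stream(spec.seed, "pan_cancer_expression")
    values = means + rng_expr.normal(0.0, spec.noise_sd, size=means.shape)

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    labels = pd.Series(type_names[tumor_idx], index=samples, name="tumor_type")
    gene_labels = np.zeros(spec.n_genes, dtype=int)
    gene_labels[specific_idx] = 1
    truth = GroundTruth(
        sample_labels=tumor_idx.copy(),
        gene_labels=gene_labels,
        specific_genes=list(genes[specific_idx]),
    )
    return expr, labels, truth


def _true_hazard_ratio(hazards: np.ndarray, counts: np.ndarray, worst: int) -> float:
    """Worst-cluster rate over the pooled-MLE rate of the remaining clusters.

    Pooling exponential groups gives rate = total events / total exposure,
    i.e. a size-weighted harmonic mean of the per-cluster rates.
    """
    rest = np.array([c for c in range(len(hazards)) if c != worst])
    n_rest = counts[rest].sum()
    pooled_rest = n_rest / np.sum(counts[rest] / hazards[rest])
    return float(hazards[worst] / pooled_rest)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort: expression matrix, clinical table, ground truth.

    Expression is returned genes x samples (matching the on-disk layout); the
    clinical table has one row per sample with columns ``sample_id``,
    ``cluster_true``, ``age_months``, ``mycn_amplified``, ``os_months`` and
    ``os_event``.
    """
    block_means = spec.resolved_block_means()
    mycn_prob = np.asarray(spec.resolved_mycn_prob())
    hazards = np.asarray(spec.hazards, dtype=float)

    rng_labels = stream(spec.seed, "cohort_labels")
    row_labels = _balanced_labels(spec.n_samples, spec.k_row, rng_labels)
    col_labels = _balanced_labels(spec.n_genes, spec.k_col, rng_labels)

    means = block_means[np.ix_(row_labels, col_labels)]  # samples x genes
    rng_expr = stream(spec.seed, "cohort_expression")
    values = means + rng_expr.normal(0.0, spec.noise_sd, size=means.shape)

    samples = np.array([f"S{i:04d}" for i in range(spec.n_samples)])
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)])
    expr = pd.DataFrame(values.T, index=pd.Index(genes, name="gene"), columns=samples)

    rng_surv = stream(spec.seed, "cohort_survival")
    event_times = rng_surv.exponential(1.0 / hazards[row_labels])
    rng_cens = stream(spec.seed, "cohort_censoring")
    if spec.censor_rate > 0:
        censor_times = rng_cens.exponential(1.0 / spec.censor_rate, size=spec.n_samples)
    else:
        censor_times = np.full(spec.n_samples, np.inf)
    cutoff = np.minimum(censor_times, spec.followup_cap)
    os_months = np.minimum(event_times, cutoff)
    os_event = (event_times <= cutoff).astype(int)

    rng_mycn = stream(spec.seed, "cohort_mycn")
    mycn = (rng_mycn.random(spec.n_samples) < mycn_prob[row_labels]).astype(int)
    rng_age = stream(spec.seed, "cohort_age")
    age_months = np.round(rng_age.uniform(18.0, 120.0, size=spec.n_samples), 1)

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "cluster_true": row_labels,
            "age_months": age_months,
            "mycn_amplified": mycn,
            "os_months": os_months,
            "os_event": os_event,
        }
    )

    worst = int(np.argmax(hazards))
    counts = np.bincount(row_labels, minlength=spec.k_row)
    truth = GroundTruth(
        sample_labels=row_labels,
        gene_labels=col_labels,
        true_hr=_true_hazard_ratio(hazards, counts, worst),
        worst_cluster=worst,
    )
    return expr, clinical, truth
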