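"""End-to-end driver: gene selection -> co-clustering -> UHR definition ->
differential panels -> cross-cohort overlap.

A :class:`PipelineConfig` (loadable from YAML) names the input tables per
cohort and carries every threshold actually applied; the run writes all
artifacts plus a JSON manifest whose ``results_hash`` is reproducible for an
identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bicluster import spectral_cocluster
from .diffexpr import DECriteria, cross_cohort_overlap, differential_genes
from .errors import ValidationError
from .io import (
    read_clinical,
    read_expression,
    read_gene_list,
    read_sample_labels,
    write_panel,
)
from .selection import SpecificityCriteria, select_specific_genes
from .subtypes import define_uhr

__all__ = ["CohortPaths", "PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class CohortPaths:
    name: str
    expression: str
    clinical: str


@dataclass
class PipelineConfig:
    cohorts: list[CohortPaths]
    out_dir: str
    k: int = 3
    seed: int = 0
    horizon: float = 24.0
    gene_list: str | None = None
    pan_cancer_expression: str | None = None
    pan_cancer_labels: str | None = None
    pan_cancer_target: str | None = None
    specificity: dict = field(default_factory=dict)
    de_subtype: dict = field(default_factory=lambda: {"min_fold": 1.5, "max_p": 1e-3})
    de_genomewide: dict = field(default_factory=lambda: {"min_fold": 1.5, "max_p": 1e-4})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        raw["cohorts"] = [CohortPaths(**c) for c in raw.get("cohorts", [])]
        return cls(**raw)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValidationError("config lists no cohorts")
        paths = []
        for c in self.cohorts:
            paths += [c.expression, c.clinical]
        for p in (self.gene_list, self.pan_cancer_expression, self.pan_cancer_labels):
            if p:
                paths.append(p)
        for p in paths:
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        SpecificityCriteria(**self.specificity)
        DECriteria(**self.de_subtype)
        DECriteria(**self.de_genomewide)

    def canonical(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    results_hash: str | None = None
    started: float | None = None
    finished: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "results_hash": self.results_hash,
                "started": self.started,
                "finished": self.finished,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage the config enables and write artifacts + manifest.

    Stage order: optional pan-cancer specificity filter (otherwise the gene
    list / full matrix is used), per-cohort spectral co-clustering, UHR
    definition by worst 24-month KM survival, per-cohort differential panels,
    and cross-cohort overlap of the up and down panels. Any stage error aborts
    the run but the partial manifest is still written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=_sha(config.canonical()),
        seed=config.seed,
        started=time.time(),
    )
    hasher = hashlib.sha256()

    def _record(text: str) -> None:
        hasher.update(text.encode("utf-8"))

    stage = "init"
    try:
        gene_list = read_gene_list(config.gene_list) if config.gene_list else None

        panel_genes: list[str] | None = None
        if config.pan_cancer_expression:
            stage = "gene_selection"
            expr, report = read_expression(config.pan_cancer_expression)
            labels = read_sample_labels(config.pan_cancer_labels)
            crit = SpecificityCriteria(**config.specificity)
            panel = select_specific_genes(
                expr, labels.loc[expr.columns], config.pan_cancer_target,
                criteria=crit, gene_list=gene_list,
            )
            log.info("specificity filter: fold > %g, p < %g -> %d genes",
                     crit.min_fold, crit.max_p, len(panel))
            write_panel(panel, out / "specific_genes.tsv")
            panel_genes = panel.genes
            manifest.stages["gene_selection"] = {
                "genes_read": report.n_genes,
                "genes_excluded_missing": panel.n_excluded_missing,
                "panel_size": len(panel),
            }
            _record(",".join(panel.genes))
        elif gene_list:
            panel_genes = gene_list

        cohort_results = {}
        for cohort in config.cohorts:
            stage = f"cocluster[{cohort.name}]"
            expr, report = read_expression(cohort.expression)
            clinical = read_clinical(cohort.clinical)
            clinical = (clinical.set_index("sample_id").loc[expr.columns]
                        .rename_axis("sample_id").reset_index())
            if panel_genes is not None:
                keep = expr.index.intersection(pd.Index(panel_genes))
                expr = expr.loc[keep]
            if report.genes_with_missing:
                expr = expr.drop(index=[g for g in report.genes_with_missing
                                        if g in expr.index])
                log.info("%s: excluded %d gene(s) with missing values",
                         cohort.name, len(report.genes_with_missing))

            model = spectral_cocluster(expr.T, k=config.k, seed=config.seed)
            pd.DataFrame({"sample_id": expr.columns,
                          "cluster": model.sample_labels}).to_csv(
                out / f"{cohort.name}_sample_labels.tsv", sep="\t", index=False)
            pd.DataFrame({"gene": expr.index,
                          "cluster": model.gene_labels}).to_csv(
                out / f"{cohort.name}_gene_labels.tsv", sep="\t", index=False)

            stage = f"stratify[{cohort.name}]"
            surv_ok = clinical["os_months"].notna() & clinical["os_event"].notna()
            n_dropped = int((~surv_ok).sum())
            if n_dropped:
                log.info("%s: dropped %d sample(s) missing survival", cohort.name, n_dropped)
            result = define_uhr(
                model.sample_labels[surv_ok.to_numpy()],
                clinical.loc[surv_ok],
                horizon=config.horizon,
            )
            subtypes = pd.Series("HR", index=expr.columns, name="subtype")
            subtypes.loc[clinical.loc[surv_ok, "sample_id"].to_numpy()] = (
                result.labels.to_numpy())
            subtypes.rename_axis("sample_id").to_frame().to_csv(
                out / f"{cohort.name}_subtypes.tsv", sep="\t")

            stage = f"de[{cohort.name}]"
            de_crit = DECriteria(**config.de_subtype)
            up, down = differential_genes(expr, subtypes.to_numpy(), criteria=de_crit)
            log.info("%s DE panels (fold > %g, p < %g): %d up, %d down",
                     cohort.name, de_crit.min_fold, de_crit.max_p, len(up), len(down))
            write_panel(up, out / f"{cohort.name}_up_panel.tsv")
            write_panel(down, out / f"{cohort.name}_down_panel.tsv")

            hr, ci, p = (None, (None, None), None)
            if result.fit is not None:
                _, hr, ci, p = result.fit.single()
            cohort_results[cohort.name] = {"up": up, "down": down, "result": result}
            manifest.stages[f"cohort[{cohort.name}]"] = {
                "samples_clustered": int(expr.shape[1]),
                "genes_used": int(expr.shape[0]),
                "genes_excluded_missing": len(report.genes_with_missing),
                "samples_dropped_missing_survival": n_dropped,
                "uhr_cluster": result.uhr_cluster,
                "logrank_p": result.logrank_p,
                "hazard_ratio": hr,
                "hr_ci95": list(ci),
                "km_at_horizon": result.km_at,
                "up_panel": len(up),
                "down_panel": len(down),
            }
            _record(json.dumps(
                [sorted(up.genes), sorted(down.genes), result.uhr_cluster,
                 model.sample_labels.tolist()], default=str))

        if len(cohort_results) >= 2:
            stage = "overlap"
            names = list(cohort_results)
            overlaps = {}
            for direction in ("up", "down"):
                ov = cross_cohort_overlap(
                    cohort_results[names[0]][direction],
                    cohort_results[names[1]][direction],
                )
                overlaps[direction] = ov.to_dict()
            (out / "overlap.json").write_text(json.dumps(overlaps, indent=2))
            manifest.stages["overlap"] = {
                d: {k: v for k, v in o.items() if k != "common"}
                for d, o in overlaps.items()
            }
            _record(json.dumps(overlaps, sort_keys=True))

        manifest.results_hash = hasher.hexdigest()
    except Exception as exc:
        manifest.stages["error"] = {"stage": stage, "message": str(exc)}
        manifest.finished = time.time()
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
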