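"""End-to-end orchestration with a flat YAML config and a single seed.

The pipeline chains preprocess -> stage association -> differential
expression -> enrichment -> module refinement -> phenotype classification
over files in the io_formats formats, writing JSON reports and TSV
intermediates.  Every selection step is recorded as
(input count, thresholds, output count) so the gene bookkeeping of a run is
machine-checkable, and reruns on identical inputs and config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    differential_expression as de,
    enrichment as enr,
    io_formats as io,
    module_refinement as mr,
    phenotype_classifier as pc,
    preprocess as pp,
    stage_association as sa,
)

logger = logging.getLogger("hccpipe")

ALL_STAGES = (
    "preprocess",
    "stage_association",
    "differential_expression",
    "enrichment",
    "module_refinement",
    "phenotype_classifier",
)

#: fixed per-stage seed offsets so stages are individually reproducible
STAGE_SEED_OFFSETS = {name: i * 1000 for i, name in enumerate(ALL_STAGES)}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: str = ""
    annotation: str = ""
    gmt: str = ""  # optional; enrichment skipped when empty
    indication_datasets: list[str] = field(default_factory=list)
    out_dir: str = "hccpipe_out"
    seed: int = 0
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # preprocess
    min_total: int = 10
    # stage association
    stage_k: int = 3
    stage_fdr_max: float = 0.25
    log2_bmv_min: float = -3.0
    # differential expression
    deg_fdr_max: float = 0.125
    min_abs_log2fc: float = 1.0
    direction: str = "up_in_peri"
    welch: bool = False
    # enrichment
    enrich_fdr_max: float = 0.10
    # module refinement
    module_k: int = 2
    # classifier
    fit_cohort: str = "exploratory"
    eval_cohort: str = "validation"
    threshold_mode: str = "youden"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for name, value, lo, hi in (
            ("stage_fdr_max", self.stage_fdr_max, 0, 1),
            ("deg_fdr_max", self.deg_fdr_max, 0, 1),
            ("enrich_fdr_max", self.enrich_fdr_max, 0, 1),
        ):
            if not lo <= value <= hi:
                raise ConfigError(f"{name} must lie in [{lo}, {hi}]")
        if self.min_total < 0:
            raise ConfigError("min_total must be >= 0")
        if self.stage_k < 1 or self.module_k < 1:
            raise ConfigError("cluster counts must be >= 1")
        if self.direction not in ("up_in_peri", "none"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.threshold_mode not in ("youden", "cluster"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write reports under ``config.out_dir``.

    Returns the report bundle (also written as ``report.json``).  A failing
    stage raises :class:`StageError` naming the stage; outputs of earlier
    stages are retained on disk.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "selections": []}

    def record(step: str, n_in: int, thresholds: dict, n_out: int) -> None:
        entry = {"step": step, "input_count": n_in,
                 "thresholds": thresholds, "output_count": n_out}
        report["selections"].append(entry)
        logger.info("%s: %d -> %d (%s)", step, n_in, n_out, thresholds)

    counts = ann = expr = None
    stage_genes: list[str] = []
    ctl_ex: list[str] = []
    module1: list[str] = []

    def _stage(name: str) -> bool:
        return name in config.stages

    try:
        if _stage("preprocess"):
            counts = io.read_count_matrix(config.counts)
            ann = io.read_annotation(config.annotation)
            filtered = pp.filter_low_count(counts, config.min_total)
            record("filter_low_count", len(counts.gene_ids),
                   {"min_total": config.min_total}, len(filtered.gene_ids))
            expr = pp.normalize_median(pp.log_transform(filtered))
            io.write_expression_matrix(expr, out / "expression.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        if _stage("stage_association") and expr is not None:
            table = sa.anova_per_gene(expr, ann)
            stage_genes = sa.select_stage_genes(
                table, config.stage_fdr_max, config.log2_bmv_min
            )
            record("select_stage_genes", len(table.gene_ids),
                   {"fdr_max": config.stage_fdr_max,
                    "log2_bmv_min": config.log2_bmv_min}, len(stage_genes))
            clusters = sa.cluster_genes(expr, stage_genes, config.stage_k)
            cluster_report = {}
            for label, genes in clusters.clusters.items():
                score = sa.signature_score(expr, genes)
                means, verdict = sa.trend_summary(
                    score, ann, tuple(g for g in ("cirrhosis", "T1", "T2", "T3")
                                      if ann.samples_with(stage=g)
                                      or ann.samples_with(tissue_class=g))
                )
                cluster_report[str(label)] = {
                    "genes": genes,
                    "group_means": {k: float(v) for k, v in means.items()},
                    "trend": verdict,
                }
            report["stage_association"] = cluster_report
            io.write_json_report(cluster_report, out / "stage_clusters.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'stage_association' failed: {exc}") from exc

    try:
        if _stage("differential_expression") and expr is not None:
            table = de.ttest_per_gene(expr, ann, welch=config.welch)
            direction = None if config.direction == "none" else config.direction
            ctl_ex = de.select_ctl_ex(
                table, config.deg_fdr_max, config.min_abs_log2fc, direction
            )
            record("select_ctl_ex", len(table.gene_ids),
                   {"fdr_max": config.deg_fdr_max,
                    "min_abs_log2fc": config.min_abs_log2fc,
                    "direction": config.direction}, len(ctl_ex))
            report["ctl_ex"] = ctl_ex
            io.write_json_report({"genes": ctl_ex}, out / "ctl_ex.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'differential_expression' failed: {exc}") from exc

    try:
        if _stage("enrichment") and config.gmt and expr is not None and ctl_ex:
            sets = io.read_gmt(config.gmt)
            results = enr.fisher_enrichment(
                ctl_ex, expr.gene_ids, sets, fdr_max=config.enrich_fdr_max
            )
            record("fisher_enrichment", len(sets),
                   {"fdr_max": config.enrich_fdr_max},
                   sum(r.significant for r in results))
            report["enrichment"] = [dataclasses.asdict(r) for r in results]
            io.write_json_report(report["enrichment"], out / "enrichment.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'enrichment' failed: {exc}") from exc

    try:
        if _stage("module_refinement") and config.indication_datasets and ctl_ex:
            datasets = [io.read_expression_matrix(p)
                        for p in config.indication_datasets]
            usable = [
                [g for g in ctl_ex if g in d.data.index
                 and d.data.loc[g].std() > 0]
                for d in datasets
            ]
            mats = [mr.correlation_matrix(d, genes)
                    for d, genes in zip(datasets, usable)]
            ref = mr.min_reference_matrix(mats)
            assignment = mr.extract_modules(ref, config.module_k)
            module1 = assignment.genes("module1")
            record("extract_modules", len(ref.gene_ids),
                   {"k": config.module_k}, len(module1))
            per_dataset = {
                f"dataset{i + 1}": {
                    mod: mr.median_pairwise_correlation(d, assignment.genes(mod))
                    for mod in ("module1", "module2")
                    if len(assignment.genes(mod)) >= 2
                }
                for i, d in enumerate(datasets)
            }
            report["modules"] = {
                "module1": module1,
                "module2": assignment.genes("module2"),
                "internal_medians": assignment.internal_medians,
                "median_pairwise_correlation_per_dataset": per_dataset,
            }
            io.write_json_report(report["modules"], out / "modules.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'module_refinement' failed: {exc}") from exc

    try:
        if _stage("phenotype_classifier") and expr is not None:
            genes = module1 if module1 else ctl_ex
            if genes:
                score = sa.signature_score(expr, genes)
                labels = ann.data["phenotype"]
                labels = labels[labels != "unknown"]
                cohorts = ann.data["cohort"]
                fit_ids = [s for s in labels.index
                           if cohorts[s] == config.fit_cohort
                           and s in score.scores.index]
                eval_ids = [s for s in labels.index
                            if cohorts[s] == config.eval_cohort
                            and s in score.scores.index]
                if fit_ids:
                    fit_score = sa.SignatureScore(score.scores[fit_ids], score.genes)
                    thr = pc.fit_threshold(fit_score, labels[fit_ids],
                                           mode=config.threshold_mode)
                    metrics = {}
                    for name, ids in (("fit", fit_ids), ("validation", eval_ids)):
                        if not ids:
                            continue
                        sub = sa.SignatureScore(score.scores[ids], score.genes)
                        calls = pc.classify(sub, thr)
                        m = pc.evaluate(calls, labels[ids], thr)
                        metrics[name] = {
                            "threshold": thr, "tp": m.tp, "fn": m.fn,
                            "tn": m.tn, "fp": m.fp,
                            "sensitivity": m.sensitivity,
                            "specificity": m.specificity,
                        }
                    report["classification"] = metrics
                    io.write_json_report(metrics, out / "classification.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'phenotype_classifier' failed: {exc}") from exc

    io.write_json_report(report, out / "report.json")
    return report
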