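"""End-to-end orchestration: MI filter -> binary PSO -> LOOCV report.

The two-stage selection runs once through the filter, then repeats the
swarm search n_runs times with per-run child seeds derived from the base
seed (base_seed + run index), evaluating each run's subset by leave-one-out
cross-validation. The best run's subset is reported together with the
best/average/worst accuracy summary over runs, metrics, and ROC/PR curves.
An INFO-level log records the gene counts entering and leaving each stage
so the selection funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier_eval import (
    ClassifierConfig,
    EvaluationReport,
    build_report,
    loocv_accuracy,
)
from .expression_io import ExpressionDataset, GeneSubset
from .mi_filter import FilterConfig, MIRanking, rank_and_filter
from .pso_search import FitnessConfig, PSOConfig, optimize

logger = logging.getLogger("mipsa")


@dataclass
class RunConfig:
    """Full two-stage configuration, serializable to/from YAML."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_runs: int = 5
    base_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub_cls in (
            ("filter", FilterConfig),
            ("pso", PSOConfig),
            ("fitness", FitnessConfig),
            ("classifier", ClassifierConfig),
        ):
            if name in raw:
                section = dict(raw[name])
                if name == "fitness" and "classifier" in section:
                    section["classifier"] = ClassifierConfig(**section["classifier"])
                kwargs[name] = sub_cls(**section)
        for scalar in ("n_runs", "base_seed"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        cfg = cls(**kwargs)
        # the wrapped fitness uses the pipeline-level classifier unless the
        # file set one explicitly
        if "fitness" not in raw or "classifier" not in raw.get("fitness", {}):
            cfg.fitness.classifier = cfg.classifier
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "filter": dataclasses.asdict(self.filter),
            "pso": dataclasses.asdict(self.pso),
            "fitness": dataclasses.asdict(self.fitness),
            "classifier": dataclasses.asdict(self.classifier),
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class PipelineResult:
    """run_mipsa output bundle (subset and report plus audit extras)."""

    subset: GeneSubset
    report: EvaluationReport
    ranking: MIRanking
    per_run_subsets: list[GeneSubset]
    best_run: int
    trace: list[float]  # global-best fitness trace of the best run


def run_mipsa(dataset: ExpressionDataset, cfg: RunConfig) -> PipelineResult:
    """Execute filter -> repeated PSO -> LOOCV evaluation.

    Child seeds are base_seed + run index for both the swarm and the inner
    CV splits, so the whole run is reproducible and runs never share a
    seed. The best run is the one with the highest LOOCV accuracy (first
    such run on ties).
    """
    logger.info("stage 1: MI filter on %d genes (%d samples)",
                dataset.n_genes, dataset.n_samples)
    ranking = rank_and_filter(dataset, cfg.filter)
    pool = ranking.kept
    logger.info("stage 1 kept %d genes (%d dropped as redundant)",
                len(pool), len(ranking.dropped_redundant))

    fit_cfg = dataclasses.replace(cfg.fitness, classifier=cfg.classifier)
    per_run_acc: list[float] = []
    per_run_subsets: list[GeneSubset] = []
    traces: list[list[float]] = []
    for run in range(cfg.n_runs):
        child = cfg.base_seed + run
        pso_cfg = dataclasses.replace(cfg.pso, seed=child)
        run_fit = dataclasses.replace(fit_cfg, seed=child)
        subset, trace = optimize(pool, dataset, pso_cfg, run_fit)
        acc, _ = loocv_accuracy(dataset, subset, cfg.classifier)
        logger.info("run %d (seed %d): %d genes, LOOCV accuracy %.4f",
                    run, child, len(subset), acc)
        per_run_acc.append(acc)
        per_run_subsets.append(subset)
        traces.append(trace)

    best_run = max(range(cfg.n_runs), key=lambda i: (per_run_acc[i], -i))
    best_subset = per_run_subsets[best_run]
    report = build_report(dataset, best_subset, cfg.classifier, per_run_acc)
    logger.info("best run %d: %d genes, LOOCV accuracy %.4f",
                best_run, len(best_subset), per_run_acc[best_run])
    return PipelineResult(
        subset=best_subset,
        report=report,
        ranking=ranking,
        per_run_subsets=per_run_subsets,
        best_run=best_run,
        trace=traces[best_run],
    )
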