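"""Scaled-down simulation benchmark: inject, simulate, predict, score.

One replicate = one junction class, one seed: junctions of the class are
injected into every selected gene, tumor/normal reads are simulated with
truth alignments, the full pipeline is run through junction calling, and
predictions are scored against the derived ground-truth junction set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .io import Annotation, Genome
from .pipeline import run_pipeline
from .simulate import (
    JUNCTION_CLASSES,
    PerfReport,
    SimTruth,
    derive_truth_junctions,
    evaluate_predictions,
    make_fixture_genome,
    simulate_reads,
    simulate_variant_annotation,
)
from .splice_graph import extract_junction_support

log = logging.getLogger(__name__)


@dataclass
class ReplicateResult:
    junction_class: str
    seed: int
    report: PerfReport
    n_truth: int
    n_predicted: int
    truth: SimTruth


@dataclass
class BenchmarkResult:
    replicates: list[ReplicateResult] = field(default_factory=list)

    def reports(self, junction_class: Optional[str] = None) -> list[PerfReport]:
        return [
            r.report
            for r in self.replicates
            if junction_class is None or r.junction_class == junction_class
        ]

    def class_medians(self, junction_class: str) -> dict[str, float]:
        reps = self.reports(junction_class)
        sens = [r.per_class[junction_class].sensitivity for r in reps]
        prec = [r.per_class[junction_class].precision for r in reps]
        return {
            "median_sensitivity": float(np.nanmedian(sens)),
            "median_precision": float(np.nanmedian(prec)),
            "mean_sensitivity": float(np.nanmean(sens)),
            "mean_precision": float(np.nanmean(prec)),
        }

    def mean_over_classes(self) -> dict[str, float]:
        """Per-class mean sensitivity/precision, averaged over the classes."""
        sens, prec = [], []
        for c in JUNCTION_CLASSES:
            reps = self.reports(c)
            if not reps:
                continue
            sens.append(np.nanmean([r.per_class[c].sensitivity for r in reps]))
            prec.append(np.nanmean([r.per_class[c].precision for r in reps]))
        return {
            "mean_sensitivity": float(np.mean(sens)),
            "mean_precision": float(np.mean(prec)),
        }

    def total_truth(self) -> int:
        return sum(r.n_truth for r in self.replicates)


def run_class_replicate(
    genome: Genome,
    annotation: Annotation,
    junction_class: str,
    cfg: PipelineConfig,
    seed: int,
) -> ReplicateResult:
    truth = simulate_variant_annotation(annotation, junction_class, cfg, seed=seed)
    tumor_reads = simulate_reads(
        truth.tumor_annotation, genome, cfg, seed=seed * 2 + 1, sample="t"
    )
    normal_reads = simulate_reads(
        truth.normal_annotation, genome, cfg, seed=seed * 2 + 2, sample="n"
    )
    tumor_sj = extract_junction_support(tumor_reads, cfg)
    normal_sj = extract_junction_support(normal_reads, cfg)
    truth_keys = derive_truth_junctions(
        tumor_sj.as_sj_counts(), normal_sj.as_sj_counts(), cfg
    )
    injected_class = {j.key: j.junction_class for j in truth.junctions}
    truth_map = {k: injected_class.get(k, junction_class) for k in truth_keys}

    result = run_pipeline(
        tumor_reads, normal_reads, annotation, genome, cfg, through="junctions"
    )
    report = evaluate_predictions(
        result.called_keys(), truth_map, classes=[junction_class]
    )
    log.info(
        "replicate class=%s seed=%d: truth=%d predicted=%d tp=%d fp=%d fn=%d",
        junction_class, seed, len(truth_keys), len(result.called_keys()),
        report.overall.tp, report.overall.fp, report.overall.fn,
    )
    return ReplicateResult(
        junction_class=junction_class, seed=seed, report=report,
        n_truth=len(truth_keys), n_predicted=len(result.called_keys()),
        truth=truth,
    )


def run_benchmark(
    seeds: Sequence[int],
    classes: Sequence[str] = JUNCTION_CLASSES,
    n_genes: int = 20,
    n_chroms: int = 4,
    cfg: Optional[PipelineConfig] = None,
    fixture_seed: int = 1234,
) -> BenchmarkResult:
    """Run every (class, seed) replicate on a shared fixture genome."""
    cfg = cfg or PipelineConfig()
    genome, annotation = make_fixture_genome(
        n_genes=n_genes, n_chroms=n_chroms, seed=fixture_seed, cfg=cfg
    )
    out = BenchmarkResult()
    for junction_class in classes:
        for seed in seeds:
            out.replicates.append(
                run_class_replicate(genome, annotation, junction_class, cfg, seed)
            )
    return out
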