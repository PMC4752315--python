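"""Genome-wide orchestration: discretize -> select -> evaluate -> summarize.

Per-gene seeds are derived from the global seed and the gene id by a
stable hash, so results are independent of the order genes are iterated
and identical between serial and parallel execution.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import classifiers as clf
from . import selection as sel
from .core import (
    ExpressionMatrix,
    LabelVector,
    MethylationMatrix,
    ProbeAnnotation,
    SelectionResult,
)
from .discretize import DiscretizationConfig, discretize_gene, usable_gene
from .evaluation import evaluate_selection, summarize
from .io import build_gene_probe_map

logger = logging.getLogger(__name__)

METHODS = (
    "sfs",
    "svm_rfe",
    "ga_knn",
    "relieff",
    "random",
    "top2",
    "all",
    "upstream_cpg_island",
    "tss_window",
    "top_sd",
)

#: methods whose selection size is tied to the SFS selection size
K_MATCHED_METHODS = ("svm_rfe", "relieff", "random")


def derive_seed(global_seed: int, gene_id: str) -> int:
    """Stable per-gene seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{gene_id}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Knobs for one genome-wide run."""

    method: str = "sfs"
    classifier: clf.ClassifierSpec = field(
        default_factory=lambda: clf.ClassifierSpec(family="knn", k_neighbors=1)
    )
    discretization: DiscretizationConfig = field(
        default_factory=DiscretizationConfig
    )
    n_folds: int = 10
    seed: int = 450
    min_samples: int = 10
    min_per_class: int = 2
    tss_window: int = 2500
    ga: sel.GAConfig = field(default_factory=sel.GAConfig)
    #: fixed selection size for k-matched methods when no reference is given
    k_override: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class RunResult:
    selections: list[SelectionResult]
    records: list  # EvaluationRecord
    skips: list[tuple[str, str]]  # (gene_id, reason)
    summary: pd.DataFrame
    histograms: dict

    @property
    def exit_code(self) -> int:
        total = len(self.selections) + len(self.skips)
        if total and len(self.skips) * 2 > total:
            return 1
        return 0


def _loo_spec(method: str, config: RunConfig) -> clf.ClassifierSpec:
    """Classifier used in the LOO evaluation, paired to the selector.

    SFS evaluates with its own wrapped classifier; GA-KNN, ReliefF and the
    controls with KNN; SVM-RFE with the (linear-kernel) SVM; annotation-
    based selections with the configured classifier.
    """
    if method in ("ga_knn", "relieff", "random", "top2"):
        k = (
            config.classifier.k_neighbors
            if config.classifier.family == "knn"
            else 1
        )
        return clf.ClassifierSpec(family="knn", k_neighbors=k)
    if method == "svm_rfe":
        return clf.ClassifierSpec(family="svm_linear")
    return config.classifier


def discretize_all(
    expr: ExpressionMatrix,
    meth: MethylationMatrix,
    config: DiscretizationConfig,
) -> dict[str, LabelVector]:
    """Per-gene label vectors over the samples shared with the methylation
    matrix (methylation order); non-overlapping samples are dropped."""
    expr_samples = set(expr.sample_ids)
    common = [s for s in meth.sample_ids if s in expr_samples]
    dropped = (len(meth.sample_ids) - len(common)) + (
        len(expr.sample_ids) - len(common)
    )
    if dropped:
        logger.warning("%d non-overlapping samples dropped", dropped)
    col_idx = [expr.sample_index[s] for s in common]
    labels = {}
    for gene in expr.gene_ids:
        values = expr.values[expr.gene_index[gene], col_idx]
        labels[gene] = discretize_gene(gene, common, values, config)
    return labels


def select_for_gene(
    gene: str,
    candidates: Sequence[str],
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    labels: LabelVector,
    annotations: Mapping[str, ProbeAnnotation],
    config: RunConfig,
    k_for_gene: Optional[int] = None,
) -> SelectionResult:
    """Dispatch one gene to the configured selection method."""
    gseed = derive_seed(config.seed, gene)
    method = config.method
    if method == "sfs":
        plan = sel.make_cv_plan(labels, config.n_folds, gseed)
        return sel.sfs_select(config.classifier, gene, candidates, meth, labels, plan)
    if method == "ga_knn":
        ga = sel.GAConfig(
            population_size=config.ga.population_size,
            n_generations=config.ga.n_generations,
            mutation_rate=config.ga.mutation_rate,
            crossover_rate=config.ga.crossover_rate,
            elitism_count=config.ga.elitism_count,
            tournament_size=config.ga.tournament_size,
            k_neighbors=config.ga.k_neighbors,
            seed=gseed,
        )
        return sel.ga_knn_select(candidates, meth, labels, ga)
    if method in K_MATCHED_METHODS:
        k = k_for_gene if k_for_gene is not None else config.k_override
        if k is None:
            raise ValueError(
                f"method {method!r} needs a per-gene selection size "
                "(reference SFS run or k_override)"
            )
        k = max(1, min(k, len(candidates)))
        if method == "random":
            chosen = sel.control_random(candidates, k, gseed)
        elif method == "relieff":
            state = sel.relieff_weights(
                candidates, meth, labels, k_neighbors=1, seed=gseed
            )
            chosen = sel.select_top_k(state.ranking(), k)
        else:  # svm_rfe
            if len(candidates) < 2:
                chosen = list(candidates)
            else:
                ranking = sel.svm_rfe_rank(candidates, meth, labels, seed=gseed)
                chosen = sel.select_top_k(ranking, k)
        return SelectionResult(gene_id=gene, method=method, selected_probe_ids=chosen)
    if method == "top2":
        e_idx = expr.gene_index[gene]
        cols = [expr.sample_index[s] for s in labels.sample_ids]
        chosen = sel.control_top_two_correlated(
            candidates, meth, expr.values[e_idx, cols], labels.sample_ids
        )
        return SelectionResult(gene_id=gene, method=method, selected_probe_ids=chosen)
    chosen = sel.select_annotation_based(
        method, gene, candidates, annotations, meth, window_bp=config.tss_window
    )
    return SelectionResult(gene_id=gene, method=method, selected_probe_ids=chosen)


def run_genome(
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    annotations: Sequence[ProbeAnnotation],
    config: RunConfig,
    reference_k: Optional[Mapping[str, int]] = None,
    genes: Optional[Sequence[str]] = None,
) -> RunResult:
    """Apply the per-gene pipeline to every gene in the inputs.

    Genes failing the usability filter, producing empty selections or
    raising are skipped with a logged reason; the run continues.
    ``reference_k`` supplies the per-gene selection size for the k-matched
    methods (typically taken from an SFS run, as in the benchmark design).
    """
    ann_by_probe = {a.probe_id: a for a in annotations}
    gmap = build_gene_probe_map(annotations)
    labels_by_gene = discretize_all(expr, meth, config.discretization)
    gene_list = sorted(gmap) if genes is None else list(genes)

    selections: list[SelectionResult] = []
    records = []
    skips: list[tuple[str, str]] = []
    for gene in gene_list:
        if gene not in gmap:
            skips.append((gene, "no annotated probes"))
            continue
        if gene not in labels_by_gene:
            skips.append((gene, "no expression row"))
            continue
        labels = labels_by_gene[gene]
        if len(labels) == 0:
            skips.append((gene, "all samples baseline"))
            continue
        if not usable_gene(labels, config.min_samples, config.min_per_class):
            skips.append((gene, "failed usability filter"))
            continue
        candidates = [p for p in gmap[gene] if p in meth.probe_index]
        if not candidates:
            skips.append((gene, "no probes in methylation matrix"))
            continue
        k_for_gene = reference_k.get(gene) if reference_k else None
        try:
            selection = select_for_gene(
                gene, candidates, meth, expr, labels, ann_by_probe, config,
                k_for_gene=k_for_gene,
            )
        except Exception as exc:  # keep the genome-wide run alive
            logger.warning("gene %s: selection failed (%s)", gene, exc)
            skips.append((gene, f"selection error: {exc}"))
            continue
        if not selection.selected_probe_ids:
            skips.append((gene, "empty selection"))
            continue
        try:
            record = evaluate_selection(
                _loo_spec(config.method, config), selection, meth, labels
            )
        except Exception as exc:
            logger.warning("gene %s: evaluation failed (%s)", gene, exc)
            skips.append((gene, f"evaluation error: {exc}"))
            continue
        selections.append(selection)
        records.append(record)

    summary, histograms = summarize(records)
    return RunResult(
        selections=selections,
        records=records,
        skips=skips,
        summary=summary,
        histograms=histograms,
    )
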