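"""Probe-selection methods.

The core contribution is the sequential-forward-selection (SFS) wrapper:
probes are added one at a time to a growing set while the mean
misclassification count in a stratified 10-fold cross-validation strictly
improves.  Alongside it live the comparison selectors: Gaussian-kernel
SVM-RFE with class-balance weights, ReliefF feature weighting, a
GA-wrapped KNN, two expression-aware controls (random, top-two
correlated), and the four expression-agnostic annotation selectors (all,
upstream CpG island, TSS window, top SD).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from . import classifiers as clf
from .core import (
    DOWN,
    UP,
    UPSTREAM_GROUPS,
    DegenerateTrainingError,
    LabelVector,
    MethylationMatrix,
    ProbeAnnotation,
    SelectionResult,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CVPlan:
    """Fixed fold assignment reused across all evaluations for one gene.

    Reusing one plan makes every candidate comparison within SFS a paired
    comparison on identical folds.
    """

    n_folds: int
    assignment: dict  # sample_id -> fold index
    stratified: bool = True
    seed: int = 0

    def fold_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([self.assignment[s] for s in sample_ids])


def make_cv_plan(labels: LabelVector, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Stratified fold assignment: per class, samples are shuffled and dealt
    round-robin, so per-fold class counts differ by at most one."""
    n = len(labels)
    folds = n_folds
    if n < n_folds:
        folds = n
        logger.info(
            "gene %s: %d samples < %d folds; using %d folds",
            labels.gene_id, n, n_folds, folds,
        )
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    counter = 0
    for cls in (DOWN, UP):
        ids = [s for s, l in zip(labels.sample_ids, labels.labels) if l == cls]
        if not ids:
            raise ValueError(f"gene {labels.gene_id}: class {cls!r} is empty")
        for i in rng.permutation(len(ids)):
            assignment[ids[i]] = counter % folds
            counter += 1
    return CVPlan(n_folds=folds, assignment=assignment, seed=seed)


def _features(
    m: MethylationMatrix, probes: Sequence[str], sample_ids: Sequence[str]
) -> np.ndarray:
    return m.submatrix(list(probes), list(sample_ids))


def _majority(labels: np.ndarray) -> str:
    n_down = int(np.sum(labels == DOWN))
    n_up = len(labels) - n_down
    if n_down == n_up:
        return DOWN
    return DOWN if n_down > n_up else UP


def cv_error(
    spec: clf.ClassifierSpec,
    probes: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
    plan: CVPlan,
) -> float:
    """Mean per-fold misclassification count O over the plan's folds.

    A fold whose training remainder collapses to one class under an SVM
    falls back to majority-of-training prediction (logged).
    """
    if not probes:
        raise ValueError("probes must be non-empty")
    x = _features(m, probes, labels.sample_ids)
    y = labels.labels
    ids = np.asarray(labels.sample_ids, dtype=object)
    fold_of = plan.fold_array(labels.sample_ids)
    counts = []
    for f in range(plan.n_folds):
        test = fold_of == f
        if not test.any():
            continue
        train = ~test
        try:
            model = clf.fit(spec, x[train], y[train], sample_ids=ids[train])
            o = clf.misclassification_count(model, x[test], y[test])
        except DegenerateTrainingError:
            maj = _majority(y[train])
            o = int(np.sum(y[test] != maj))
            logger.debug("fold %d degenerate; majority fallback", f)
        counts.append(o)
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# sequential forward selection


def sfs_select(
    spec: clf.ClassifierSpec,
    gene_id: str,
    candidates: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
    plan: CVPlan,
) -> SelectionResult:
    """Greedy forward selection of probes under cross-validated error.

    Round one evaluates every candidate singly and keeps the argmin (ties
    to the lowest candidate index).  Subsequent rounds evaluate the current
    set plus each remaining candidate and accept the argmin only on strict
    improvement over the incumbent error; otherwise the search stops.  The
    same :class:`CVPlan` is reused throughout so comparisons are paired.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    remaining = list(candidates)
    selected: list[str] = []
    trace: list[list[tuple[str, float]]] = []

    round_scores = [cv_error(spec, [p], m, labels, plan) for p in remaining]
    trace.append(list(zip(remaining, round_scores)))
    j = int(np.argmin(round_scores))
    selected.append(remaining.pop(j))
    oce = round_scores[j]

    while remaining:
        round_scores = [
            cv_error(spec, selected + [p], m, labels, plan) for p in remaining
        ]
        trace.append(list(zip(remaining, round_scores)))
        j = int(np.argmin(round_scores))
        if round_scores[j] < oce:
            selected.append(remaining.pop(j))
            oce = round_scores[j]
        else:
            break

    n = len(labels)
    return SelectionResult(
        gene_id=gene_id,
        method=f"sfs_{spec.family}"
        + (str(spec.k_neighbors) if spec.family == "knn" else ""),
        selected_probe_ids=selected,
        trace=trace,
        final_cv_error=oce * plan.n_folds / n,
    )


# ---------------------------------------------------------------------------
# SVM-RFE


@dataclass(frozen=True)
class ClassWeights:
    """Misclassification weights balancing class sizes: n0*w0 == n1*w1.

    n0/w0 refer to the down class, n1/w1 to the up class; the minority
    class receives the larger weight.  Weights are exact rationals.
    """

    n0: int
    n1: int
    w0: Fraction
    w1: Fraction

    def __post_init__(self) -> None:
        if self.n0 * self.w0 != self.n1 * self.w1:
            raise ValueError("weights must satisfy n0*w0 == n1*w1")

    def as_mapping(self) -> dict[str, float]:
        return {DOWN: float(self.w0), UP: float(self.w1)}


def balance_weights(labels: LabelVector) -> ClassWeights:
    """Solve n0*w0 = n1*w1 with w1 = 1 (w0 = n1/n0, exact)."""
    n0, n1 = labels.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to balance weights")
    return ClassWeights(n0=n0, n1=n1, w0=Fraction(n1, n0), w1=Fraction(1))


def svm_rfe_rank(
    candidates: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
    weights: Optional[ClassWeights] = None,
    seed: int = 0,
    c: float = 1.0,
) -> list[str]:
    """Rank probes by recursive elimination under a weighted Gaussian SVM.

    At each pass a class-weighted RBF SVM is fitted on the surviving
    features; each feature is scored by the change in the dual objective
    when it is removed from the kernel with the alphas held fixed, and the
    lowest-scoring feature is eliminated (score ties eliminate the larger
    candidate index first).  The ranking is the reverse elimination order.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    if weights is None:
        weights = balance_weights(labels)
    x_all = _features(m, candidates, labels.sample_ids)
    y = np.asarray(labels.labels, dtype=object)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")

    surviving = list(range(len(candidates)))
    eliminated: list[int] = []
    while len(surviving) > 1:
        x = x_all[:, surviving]
        d = x.shape[1]
        var = x.var()
        gamma = 1.0 / (d * var) if var > 0 else 1.0
        svc = SVC(
            kernel="rbf", C=c, gamma=gamma,
            class_weight=weights.as_mapping(), random_state=seed,
        )
        try:
            svc.fit(x, y)
        except Exception:
            svc = SVC(
                kernel="rbf", C=c, gamma=gamma, tol=1e-2,
                class_weight=weights.as_mapping(), random_state=seed,
            )
            svc.fit(x, y)
        dual = svc.dual_coef_[0]  # y_i * alpha_i over support vectors
        xs = x[svc.support_]
        d2 = cdist(xs, xs, "sqeuclidean")
        k_full = np.exp(-gamma * d2)
        j_full = 0.5 * dual @ k_full @ dual
        scores = np.empty(d)
        for f in range(d):
            diff2 = (xs[:, f][:, None] - xs[:, f][None, :]) ** 2
            k_minus = k_full * np.exp(gamma * diff2)
            scores[f] = abs(j_full - 0.5 * dual @ k_minus @ dual)
        lowest = scores.min()
        # among tied minima, drop the largest original candidate index
        tied = [i for i in range(d) if scores[i] == lowest]
        drop_local = max(tied, key=lambda i: surviving[i])
        eliminated.append(surviving.pop(drop_local))
    ranking_idx = surviving + eliminated[::-1]
    return [candidates[i] for i in ranking_idx]


# ---------------------------------------------------------------------------
# ReliefF


@dataclass
class ReliefFState:
    weights: np.ndarray
    probe_ids: list[str]
    k_neighbors: int
    n_iterations: int
    seed: int

    def ranking(self) -> list[str]:
        """Probes by descending weight; ties keep candidate order."""
        order = np.lexsort((np.arange(len(self.weights)), -self.weights))
        return [self.probe_ids[i] for i in order]


def relieff_step(
    w: np.ndarray, x: np.ndarray, hits: np.ndarray, misses: np.ndarray
) -> np.ndarray:
    """One un-normalized ReliefF update for a single sampled instance.

    W_i <- W_i - (x_i - h_i)^2 + (x_i - m_i)^2, with the squared
    differences averaged over the k nearest hits/misses (k = 1 reduces to
    the single-neighbor form).
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    hits = np.atleast_2d(np.asarray(hits, dtype=float))
    misses = np.atleast_2d(np.asarray(misses, dtype=float))
    return w - ((x - hits) ** 2).mean(axis=0) + ((x - misses) ** 2).mean(axis=0)


def relieff_weights(
    candidates: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
    k_neighbors: int = 1,
    n_iterations: Optional[int] = None,
    seed: int = 0,
) -> ReliefFState:
    """ReliefF feature weights over the candidate probes.

    Every sample is visited once in a seed-shuffled order (m = n
    iterations by default); per instance the k nearest same-class hits and
    other-class misses by Euclidean distance over all candidates update
    each weight, with 1/m normalization.  Classes smaller than k reduce k
    for that side with a warning.
    """
    x = _features(m, candidates, labels.sample_ids)
    y = np.asarray(labels.labels, dtype=object)
    n = x.shape[0]
    n_iter = n if n_iterations is None else n_iterations
    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations == n:
        visit = rng.permutation(n)
    else:
        visit = rng.integers(0, n, size=n_iter)
    d = cdist(x, x)
    w = np.zeros(x.shape[1])
    warned = False
    for idx in visit:
        same = np.flatnonzero((y == y[idx]) & (np.arange(n) != idx))
        other = np.flatnonzero(y != y[idx])
        kh = min(k_neighbors, len(same))
        km = min(k_neighbors, len(other))
        if (kh < k_neighbors or km < k_neighbors) and not warned:
            logger.warning(
                "gene %s: class too small for k=%d; reducing",
                labels.gene_id, k_neighbors,
            )
            warned = True
        if kh == 0 or km == 0:
            continue
        hits = same[np.argsort(d[idx, same], kind="stable")[:kh]]
        misses = other[np.argsort(d[idx, other], kind="stable")[:km]]
        w += (relieff_step(np.zeros_like(w), x[idx], x[hits], x[misses])) / n_iter
    return ReliefFState(
        weights=w,
        probe_ids=list(candidates),
        k_neighbors=k_neighbors,
        n_iterations=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# GA-KNN


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    n_generations: int = 100
    mutation_rate: Optional[float] = None  # default 1/N per bit
    crossover_rate: float = 0.8
    elitism_count: int = 2
    tournament_size: int = 3
    k_neighbors: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate,) + (
            (self.mutation_rate,) if self.mutation_rate is not None else ()
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def ga_fitness(resub_loss: float, n_total: int, n_selected: int) -> float:
    """resubLoss / (N - S); the shrinking denominator penalizes large S.

    Masks selecting nothing or everything are excluded via +inf.
    """
    if n_selected <= 0 or n_selected >= n_total:
        return math.inf
    return resub_loss / (n_total - n_selected)


def _resub_loss(
    x: np.ndarray, y: np.ndarray, ids: np.ndarray, k_neighbors: int
) -> float:
    spec = clf.ClassifierSpec(family="knn", k_neighbors=k_neighbors)
    model = clf.fit(spec, x, y, sample_ids=ids)
    return clf.misclassification_count(model, x, y) / len(y)


def ga_knn_select(
    candidates: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
    config: GAConfig = GAConfig(),
) -> SelectionResult:
    """Binary-mask genetic algorithm minimizing resubLoss/(N-S) with KNN.

    Tournament selection, uniform crossover, per-bit flip mutation and
    elitism; fully deterministic given ``config.seed``.  Note that with
    K = 1 the resubstitution loss of distinct points is identically zero,
    so the fitness is 0 for any non-degenerate mask — the search then only
    distinguishes masks through the exclusion of S = 0 and S = N.
    """
    n_feat = len(candidates)
    x_all = _features(m, candidates, labels.sample_ids)
    y = np.asarray(labels.labels, dtype=object)
    ids = np.asarray(labels.sample_ids, dtype=object)
    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_feat

    def evaluate(mask: np.ndarray) -> tuple[float, float]:
        s = int(mask.sum())
        if s <= 0 or s >= n_feat:
            return math.inf, math.nan
        loss = _resub_loss(x_all[:, mask], y, ids, config.k_neighbors)
        return ga_fitness(loss, n_feat, s), loss

    pop = rng.random((config.population_size, n_feat)) < 0.5
    if n_feat == 1:
        # single candidate: the only admissible mask selects it
        best_mask = np.array([True])
        loss = _resub_loss(x_all, y, ids, config.k_neighbors)
        return SelectionResult(
            gene_id=labels.gene_id,
            method=f"ga_knn{config.k_neighbors}",
            selected_probe_ids=list(candidates),
            trace=[[(candidates[0], loss)]],
            final_cv_error=loss,
        )

    best_mask: Optional[np.ndarray] = None
    best_fit = math.inf
    best_loss = math.nan
    history: list[list[tuple[str, float]]] = []
    for _ in range(config.n_generations):
        fits = np.empty(config.population_size)
        losses = np.empty(config.population_size)
        for i in range(config.population_size):
            fits[i], losses[i] = evaluate(pop[i])
            if fits[i] < best_fit:
                best_fit, best_mask, best_loss = fits[i], pop[i].copy(), losses[i]
        history.append([("best", best_fit if math.isfinite(best_fit) else math.nan)])
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: config.elitism_count]]
        while len(new_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, config.tournament_size)
                winner = contenders[np.argmin(fits[contenders])]
                parents.append(pop[winner])
            if rng.random() < config.crossover_rate:
                take = rng.random(n_feat) < 0.5
                child = np.where(take, parents[0], parents[1])
            else:
                child = parents[0].copy()
            child = child ^ (rng.random(n_feat) < mut)
            new_pop.append(child)
        pop = np.asarray(new_pop)

    if best_mask is None:  # every mask degenerate (vanishingly unlikely)
        best_mask = np.zeros(n_feat, dtype=bool)
        best_mask[0] = True
        best_loss = _resub_loss(x_all[:, best_mask], y, ids, config.k_neighbors)
    selected = [candidates[i] for i in np.flatnonzero(best_mask)]
    return SelectionResult(
        gene_id=labels.gene_id,
        method=f"ga_knn{config.k_neighbors}",
        selected_probe_ids=selected,
        trace=history,
        final_cv_error=best_loss,
    )


# ---------------------------------------------------------------------------
# controls and ranking helpers


def select_top_k(ranking: Sequence[str], k: int) -> list[str]:
    """First k of an ordered ranking; k past the end returns all (warned)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranking):
        logger.warning("k=%d exceeds ranking length %d; returning all", k, len(ranking))
        return list(ranking)
    return list(ranking[:k])


def control_random(candidates: Sequence[str], k: int, seed: int = 0) -> list[str]:
    """Uniform sample of k probes without replacement (seeded)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(candidates):
        raise ValueError("k exceeds candidate count")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(idx)]


def control_top_two_correlated(
    candidates: Sequence[str],
    m: MethylationMatrix,
    expression_values: np.ndarray,
    sample_ids: Sequence[str],
) -> list[str]:
    """The two probes most |Pearson|-correlated with continuous expression.

    Computed over the labeled (non-baseline) samples; constant probes score
    zero; ties keep the lower candidate index.
    """
    if len(candidates) < 2:
        return list(candidates)
    x = _features(m, candidates, sample_ids)
    e = np.asarray(expression_values, dtype=float)
    if len(e) != x.shape[0]:
        raise ValueError("expression length must match sample count")
    ec = e - e.mean()
    denom_e = np.sqrt((ec**2).sum())
    scores = np.zeros(len(candidates))
    for i in range(x.shape[1]):
        xc = x[:, i] - x[:, i].mean()
        denom_x = np.sqrt((xc**2).sum())
        if denom_x == 0 or denom_e == 0:
            continue
        scores[i] = abs(float(xc @ ec) / (denom_x * denom_e))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [candidates[i] for i in order[:2]]


def select_annotation_based(
    method: str,
    gene: str,
    candidates: Sequence[str],
    annotations: Mapping[str, ProbeAnnotation],
    m: MethylationMatrix,
    window_bp: int = 2500,
) -> list[str]:
    """Expression-agnostic selectors driven by the manifest.

    ``all``: every candidate.  ``upstream_cpg_island``: island probes whose
    region group for this gene is promoter-proximal (TSS200/TSS1500/
    5'UTR/1stExon).  ``tss_window``: probes within ±window_bp of the TSS
    (inclusive boundary).  ``top_sd``: the single probe with the largest
    sample standard deviation (ties to the lower candidate index).
    """
    if method == "all":
        return list(candidates)
    if method == "upstream_cpg_island":
        out = []
        for p in candidates:
            ann = annotations[p]
            if (
                ann.cpg_island_relation == "Island"
                and ann.region_group_per_gene.get(gene) in UPSTREAM_GROUPS
            ):
                out.append(p)
        if not out:
            logger.warning("gene %s: no upstream-island probes", gene)
        return out
    if method == "tss_window":
        out = []
        for p in candidates:
            tss = annotations[p].tss_distance_per_gene or {}
            if gene in tss and abs(tss[gene]) <= window_bp:
                out.append(p)
        if not out:
            logger.warning("gene %s: no probes within %d bp of TSS", gene, window_bp)
        return out
    if method == "top_sd":
        x = _features(m, candidates, m.sample_ids)
        sds = x.std(axis=0, ddof=1)
        return [candidates[int(np.argmax(sds))]]
    raise ValueError(f"unknown annotation-based method {method!r}")
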