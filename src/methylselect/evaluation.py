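"""Leave-one-out assessment of probe selections and MCC-based gene lists.

Down-expressed samples are the positive class throughout.  Per gene the
selected probes predict the discretized expression in a leave-one-out
cross-validation; the confusion counts yield accuracy, precision, recall,
specificity and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with a zero denominator mapped to MCC = 0.  Genes are stratified into
methylation-sensitive (MCC > 0.6) and insensitive (MCC < 0.2) lists, and
two gene lists can be compared with an upper-tail hypergeometric overlap
test.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import classifiers as clf
from .core import (
    DOWN,
    UP,
    ConfusionCounts,
    DegenerateTrainingError,
    EvaluationRecord,
    LabelVector,
    MethylationMatrix,
    SelectionResult,
)

logger = logging.getLogger(__name__)


def loo_confusion(
    spec: clf.ClassifierSpec,
    probes: Sequence[str],
    m: MethylationMatrix,
    labels: LabelVector,
) -> ConfusionCounts:
    """Fit-on-the-rest / predict-the-held-out-sample confusion counts."""
    if not probes:
        raise ValueError("probes must be non-empty")
    if len(labels) < 2:
        raise ValueError("need at least 2 samples for LOO")
    x = m.submatrix(list(probes), labels.sample_ids)
    y = labels.labels
    ids = np.asarray(labels.sample_ids, dtype=object)
    tp = tn = fp = fn = 0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        try:
            model = clf.fit(spec, x[keep], y[keep], sample_ids=ids[keep])
            pred = clf.predict(model, x[i])[0]
        except DegenerateTrainingError:
            counts = Counter(y[keep])
            pred = (
                DOWN
                if counts.get(DOWN, 0) >= counts.get(UP, 0)
                else UP
            )
            logger.debug("LOO remainder degenerate for sample %s", ids[i])
        truth = y[i]
        if truth == DOWN:
            if pred == DOWN:
                tp += 1
            else:
                fn += 1
        else:
            if pred == UP:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics_from_confusion(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and MCC from 2x2 counts.

    Undefined ratios (zero denominator) are NaN so that summary means can
    exclude them; the MCC alone uses the 0 convention when any factor of
    its denominator vanishes.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    specificity = tn / (tn + fp) if tn + fp > 0 else math.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "mcc": mcc,
    }


def evaluate_selection(
    spec: clf.ClassifierSpec,
    selection: SelectionResult,
    m: MethylationMatrix,
    labels: LabelVector,
) -> EvaluationRecord:
    """LOO-CV one selection and package the metrics."""
    confusion = loo_confusion(spec, selection.selected_probe_ids, m, labels)
    metrics = metrics_from_confusion(confusion)
    return EvaluationRecord(
        gene_id=selection.gene_id,
        method=selection.method,
        classifier=spec.family
        + (str(spec.k_neighbors) if spec.family == "knn" else ""),
        confusion=confusion,
        n_probes=len(selection.selected_probe_ids),
        **metrics,
    )


def stratify_by_mcc(
    records: Iterable[EvaluationRecord], high: float = 0.6, low: float = 0.2
) -> tuple[list[str], list[str]]:
    """Sorted gene lists with MCC strictly above ``high`` / below ``low``."""
    high_genes = sorted({r.gene_id for r in records if r.mcc > high})
    low_genes = sorted({r.gene_id for r in records if r.mcc < low})
    return high_genes, low_genes


def hypergeometric_overlap(
    list_a: set[str], list_b: set[str], universe: set[str]
) -> float:
    """P[overlap >= observed] drawing |list_b| genes from the universe."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not list_a <= universe or not list_b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    observed = len(list_a & list_b)
    if observed == 0:
        return 1.0
    return float(
        hypergeom.sf(observed - 1, len(universe), len(list_a), len(list_b))
    )


def summarize(
    records: Sequence[EvaluationRecord],
) -> tuple[pd.DataFrame, dict[str, dict[int, int]]]:
    """Per-method mean/median of each metric plus probes-per-gene histograms.

    NaN metrics (undefined ratios) are excluded from means and medians.
    """
    rows = []
    histograms: dict[str, dict[int, int]] = {}
    by_method: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        by_method.setdefault(r.method, []).append(r)
    for method, recs in sorted(by_method.items()):
        row: dict[str, object] = {"method": method, "n_genes": len(recs)}
        for metric in ("accuracy", "precision", "recall", "specificity", "mcc"):
            vals = np.asarray([getattr(r, metric) for r in recs], dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"mean_{metric}"] = float(vals.mean()) if vals.size else math.nan
            row[f"median_{metric}"] = float(np.median(vals)) if vals.size else math.nan
        rows.append(row)
        counts = Counter(
            r.n_probes for r in recs if r.n_probes is not None
        )
        histograms[method] = dict(sorted(counts.items()))
    return pd.DataFrame(rows), histograms
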