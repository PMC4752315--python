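"""Discretize continuous expression into up/down/baseline labels per gene.

Two designs are supported:

* ``paired_ratio`` — each value is already a treated/untreated expression
  ratio for one sample (e.g. mock vs hypomethylating-agent pairs); the
  shipped fold-change threshold is 1.1.
* ``median_reference`` — absolute expression referenced to the per-gene
  median across samples (tissue cohorts); the shipped threshold is 1.2,
  the larger cut absorbing the extra noise of unpaired tissue data.

Thresholding is reciprocal-symmetric on the linear-ratio scale: a sample
is *up* when r >= t, *down* when r <= 1/t, *baseline* otherwise, and
baseline samples are removed before classification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BASELINE, DOWN, UP, LabelVector

logger = logging.getLogger(__name__)

#: shipped defaults per design
DEFAULT_THRESHOLDS = {"paired_ratio": 1.1, "median_reference": 1.2}

_LOG_BASES = {"linear_ratio": None, "log2": 2.0, "log10": 10.0}


@dataclass(frozen=True)
class DiscretizationConfig:
    mode: str = "paired_ratio"
    fold_threshold: float | None = None
    scale: str = "linear_ratio"

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scale not in _LOG_BASES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.fold_threshold is None:
            object.__setattr__(
                self, "fold_threshold", DEFAULT_THRESHOLDS[self.mode]
            )
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


def _to_linear(values: np.ndarray, scale: str) -> np.ndarray:
    base = _LOG_BASES[scale]
    if base is None:
        return values
    return np.power(base, values)


def label_samples(
    values: np.ndarray, config: DiscretizationConfig
) -> np.ndarray:
    """Classify every sample into {up, down, baseline} (nothing removed).

    In ``median_reference`` mode the ratio is sample / per-gene median on
    the linear scale; in ``paired_ratio`` mode the value itself is the
    ratio.
    """
    linear = _to_linear(np.asarray(values, dtype=float), config.scale)
    if config.mode == "median_reference":
        if np.any(linear <= 0):
            raise ValueError(
                "median_reference mode requires positive linear-scale values"
            )
        if linear.size < 3:
            logger.warning(
                "median reference computed on %d samples; median is noisy",
                linear.size,
            )
        ratios = linear / np.median(linear)
    else:
        ratios = linear
    t = config.fold_threshold
    out = np.full(ratios.shape, BASELINE, dtype=object)
    out[ratios >= t] = UP
    out[ratios <= 1.0 / t] = DOWN
    return out


def discretize_gene(
    gene_id: str,
    sample_ids: list[str],
    values: np.ndarray,
    config: DiscretizationConfig,
) -> LabelVector:
    """Label one gene's samples and drop the baseline ones.

    Returns an empty :class:`LabelVector` when every sample is baseline;
    callers must skip such genes.
    """
    labels = label_samples(values, config)
    keep = labels != BASELINE
    return LabelVector(
        gene_id=gene_id,
        sample_ids=[s for s, k in zip(sample_ids, keep) if k],
        labels=labels[keep],
    )


def usable_gene(
    label_vector: LabelVector, min_samples: int = 10, min_per_class: int = 2
) -> bool:
    """True iff the gene has enough labeled samples in each class.

    Defaults (10 samples, 2 per class) keep 10-fold CV meaningful.
    """
    if len(label_vector) < min_samples:
        return False
    n_down, n_up = label_vector.class_counts()
    return n_down >= min_per_class and n_up >= min_per_class
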