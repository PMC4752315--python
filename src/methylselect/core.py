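"""Shared domain types for gene-centric methylation probe selection.

The toolkit links Illumina 450K probe-level beta values to per-gene
discretized expression.  These dataclasses are the common currency passed
between the IO layer, the discretizer, the probe-selection methods and the
leave-one-out evaluation harness.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Closed vocabulary of Illumina gene region groups.
REGION_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "Unknown")
#: Region groups counted as "upstream" of the gene (promoter-proximal).
UPSTREAM_GROUPS = frozenset({"TSS200", "TSS1500", "5'UTR", "1stExon"})
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea", "Unknown")

UP = "up"
DOWN = "down"
BASELINE = "baseline"
#: Down-expressed samples are the positive class in all confusion counts.
POSITIVE_CLASS = DOWN


class FormatError(ValueError):
    """A TSV input violated the expected format."""


class DegenerateTrainingError(ValueError):
    """A training set contained a single class where two are required."""


@dataclass
class ProbeAnnotation:
    """Genomic metadata for one 450K probe.

    A probe may annotate to several genes; ``region_group_per_gene`` holds
    one region group (TSS200, TSS1500, 5'UTR, 1stExon, Body, 3'UTR or
    Unknown) per gene, and ``tss_distance_per_gene`` optionally holds a
    signed distance to each gene's transcription start site in bp
    (negative = upstream).  Coordinates are 1-based (MAPINFO convention).
    """

    probe_id: str
    gene_symbols: list[str]
    region_group_per_gene: dict[str, str]
    cpg_island_relation: str
    chromosome: str
    position: int
    tss_distance_per_gene: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        for gene, group in self.region_group_per_gene.items():
            if group not in REGION_GROUPS:
                raise ValueError(
                    f"probe {self.probe_id}: unknown region group {group!r} for {gene}"
                )
        if self.cpg_island_relation not in ISLAND_RELATIONS:
            raise ValueError(
                f"probe {self.probe_id}: unknown island relation "
                f"{self.cpg_island_relation!r}"
            )


@dataclass
class _AlignedMatrix:
    """Numeric matrix with named rows and sample columns."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._row_index) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(self._sample_index) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def row_index(self) -> dict[str, int]:
        return self._row_index

    @property
    def sample_index(self) -> dict[str, int]:
        return self._sample_index

    def submatrix(self, rows: list[str], samples: list[str]) -> np.ndarray:
        """Return a samples x rows feature array (classifier orientation)."""
        ri = [self._row_index[r] for r in rows]
        si = [self._sample_index[s] for s in samples]
        return self.values[np.ix_(ri, si)].T.copy()


@dataclass
class MethylationMatrix(_AlignedMatrix):
    """Probes x samples matrix of beta values in [0, 1]."""

    @property
    def probe_ids(self) -> list[str]:
        return self.row_ids

    @property
    def probe_index(self) -> dict[str, int]:
        return self._row_index


@dataclass
class ExpressionMatrix(_AlignedMatrix):
    """Genes x samples expression matrix.

    ``mode`` records the study design: ``paired_ratio`` for per-sample
    treated/untreated ratios (mock/aza style) or ``median_reference`` for
    absolute values referenced to the per-gene median across samples
    (tissue-cohort style).
    """

    mode: str = "paired_ratio"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mode not in ("paired_ratio", "median_reference"):
            raise ValueError(f"unknown expression mode {self.mode!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids

    @property
    def gene_index(self) -> dict[str, int]:
        return self._row_index


@dataclass
class LabelVector:
    """Binary up/down labels for one gene, baseline samples removed."""

    gene_id: str
    sample_ids: list[str]
    labels: np.ndarray  # values in {"up", "down"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids lengths differ")
        bad = set(self.labels) - {UP, DOWN}
        if bad:
            raise ValueError(f"labels must be up/down, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> tuple[int, int]:
        """(n_down, n_up)."""
        n_down = int(np.sum(self.labels == DOWN))
        return n_down, len(self.labels) - n_down


#: gene -> ordered candidate probe ids (manifest order).
GeneProbeMap = dict[str, list[str]]


@dataclass
class SelectionResult:
    """Outcome of one probe-selection method on one gene.

    ``trace`` is a list of rounds; each round is the list of
    ``(candidate_probe, cv_error)`` pairs evaluated in that round, in
    candidate order.  ``final_cv_error`` is the terminal cross-validated
    error as a fraction of samples (NaN for selectors that do not
    cross-validate).
    """

    gene_id: str
    method: str
    selected_probe_ids: list[str]
    trace: list[list[tuple[str, float]]] = field(default_factory=list)
    final_cv_error: float = math.nan

    def __post_init__(self) -> None:
        if len(set(self.selected_probe_ids)) != len(self.selected_probe_ids):
            raise ValueError("selected probes must be unique")


@dataclass
class ConfusionCounts:
    """2x2 confusion counts with the down class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationRecord:
    """Per-gene LOO-CV metrics for one selection method."""

    gene_id: str
    method: str
    classifier: str
    confusion: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    specificity: float
    mcc: float
    n_probes: Optional[int] = None
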