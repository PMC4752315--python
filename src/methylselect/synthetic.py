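"""Synthetic 450K-style benchmark generator with planted informative probes.

Each simulated gene carries a handful of candidate probes; a configurable
number of them are *informative*, drawing beta values from class-
conditional truncated normals (down-labeled samples around ``mu_down``,
up-labeled around ``mu_up``), while the remaining probes are label-
independent Beta noise.  Expression ratios are generated deterministically
from the labels so that discretization at the configured threshold
recovers them exactly; an optional label-flip probability decouples
expression from methylation to create intermediate-MCC genes.

The default scenario — 200 genes, 10 probes each (1 informative + 9
noise), 25 samples, class-conditional means 0.2/0.8 with sd 0.05 — is the
benchmark used throughout the test-suite and the reproduction script.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.stats import truncnorm

from .core import (
    DOWN,
    UP,
    ExpressionMatrix,
    MethylationMatrix,
    ProbeAnnotation,
)

_REGION_CHOICES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
_REGION_PROBS = (0.15, 0.15, 0.10, 0.10, 0.40, 0.10)
_ISLAND_CHOICES = ("Island", "Shore", "Shelf", "OpenSea")
_ISLAND_PROBS = (0.30, 0.25, 0.15, 0.30)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic benchmark.

    ``probes_per_gene`` is either a fixed count or an inclusive (lo, hi)
    range drawn uniformly per gene (a (5, 30) range approximates the
    450K's average of ~18 probes per gene).
    """

    n_genes: int = 200
    probes_per_gene: Union[int, tuple[int, int]] = 10
    n_samples: int = 25
    n_informative_per_gene: int = 1
    mu_down: float = 0.2
    mu_up: float = 0.8
    effect_sd: float = 0.05
    noise_beta: tuple[float, float] = (2.0, 2.0)
    class_balance: float = 0.5  # fraction of down-labeled samples
    label_noise: float = 0.0
    fold_threshold: float = 1.1
    seed: int = 450

    def __post_init__(self) -> None:
        if not (0 < self.mu_down < 1 and 0 < self.mu_up < 1):
            raise ValueError("class-conditional means must lie in (0, 1)")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be positive")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must lie in [0, 1]")


def _truncnorm_01(rng: np.random.Generator, mu: float, sd: float, size: int):
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def simulate(
    scenario: SimulationScenario,
) -> tuple[MethylationMatrix, ExpressionMatrix, list[ProbeAnnotation], dict[str, list[str]]]:
    """Generate (methylation, expression, annotations, truth) from a seed.

    ``truth`` maps each gene to its informative probe ids.  Expression
    ratios sit at t*1.5 (up) and 1/(t*1.5) (down) so discretization at
    threshold t reproduces the planted labels with zero mismatches.
    """
    rng = np.random.default_rng(scenario.seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(scenario.n_samples)]
    t = scenario.fold_threshold
    up_ratio, down_ratio = t * 1.5, 1.0 / (t * 1.5)

    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    annotations: list[ProbeAnnotation] = []
    expr_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth: dict[str, list[str]] = {}
    probe_counter = 0
    position = 1

    for g in range(scenario.n_genes):
        gene = f"G{g + 1:04d}"
        gene_ids.append(gene)
        if isinstance(scenario.probes_per_gene, int):
            n_probes = scenario.probes_per_gene
        else:
            lo, hi = scenario.probes_per_gene
            n_probes = int(rng.integers(lo, hi + 1))
        n_info = min(scenario.n_informative_per_gene, n_probes)

        # methylation-driving labels
        meth_labels = np.where(
            rng.random(scenario.n_samples) < scenario.class_balance, DOWN, UP
        )
        # expression labels, optionally decoupled by flips
        flips = rng.random(scenario.n_samples) < scenario.label_noise
        expr_labels = np.where(
            flips, np.where(meth_labels == DOWN, UP, DOWN), meth_labels
        )
        truth_probes: list[str] = []
        info_slots = rng.choice(n_probes, size=n_info, replace=False)
        info_set = set(int(i) for i in info_slots)
        for j in range(n_probes):
            pid = f"cg{probe_counter:06d}"
            probe_counter += 1
            probe_ids.append(pid)
            if j in info_set:
                row = np.empty(scenario.n_samples)
                down_mask = meth_labels == DOWN
                row[down_mask] = _truncnorm_01(
                    rng, scenario.mu_down, scenario.effect_sd, int(down_mask.sum())
                )
                row[~down_mask] = _truncnorm_01(
                    rng, scenario.mu_up, scenario.effect_sd, int((~down_mask).sum())
                )
                truth_probes.append(pid)
            else:
                row = rng.beta(*scenario.noise_beta, size=scenario.n_samples)
            probe_rows.append(row)
            region = str(rng.choice(_REGION_CHOICES, p=_REGION_PROBS))
            island = str(rng.choice(_ISLAND_CHOICES, p=_ISLAND_PROBS))
            if region in ("TSS200", "TSS1500", "5'UTR", "1stExon"):
                tss = -int(rng.integers(0, 2001))
            else:
                tss = int(rng.integers(200, 50001))
            annotations.append(
                ProbeAnnotation(
                    probe_id=pid,
                    gene_symbols=[gene],
                    region_group_per_gene={gene: region},
                    cpg_island_relation=island,
                    chromosome="chr1",
                    position=position,
                    tss_distance_per_gene={gene: tss},
                )
            )
            position += 100
        truth[gene] = truth_probes
        expr_rows.append(
            np.where(expr_labels == UP, up_ratio, down_ratio).astype(float)
        )

    meth = MethylationMatrix(probe_ids, sample_ids, np.asarray(probe_rows))
    expr = ExpressionMatrix(
        gene_ids, sample_ids, np.asarray(expr_rows), mode="paired_ratio"
    )
    return meth, expr, annotations, truth


def recovery_rate(truth: dict[str, list[str]], selections) -> float:
    """Fraction of genes whose selection intersects the planted probes."""
    if not selections:
        return 0.0
    hit = 0
    for sel in selections:
        planted = set(truth.get(sel.gene_id, []))
        if planted & set(sel.selected_probe_ids):
            hit += 1
    return hit / len(selections)
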