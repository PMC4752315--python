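"""Readers and writers for the TSV formats the toolkit consumes and emits.

All files are tab-delimited UTF-8 with a header row.  Manifest column
names are configurable through ``column_map`` so real Illumina 450K
manifests (IlmnID, UCSC_RefGene_Name, ...) load without editing.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional

import pandas as pd

from .core import (
    EvaluationRecord,
    ExpressionMatrix,
    FormatError,
    GeneProbeMap,
    MethylationMatrix,
    ProbeAnnotation,
    SelectionResult,
)

logger = logging.getLogger(__name__)

#: canonical manifest column -> default header name
MANIFEST_COLUMNS = {
    "probe_id": "probe_id",
    "gene": "gene",
    "region_group": "region_group",
    "island_relation": "island_relation",
    "chromosome": "chromosome",
    "position": "position",
}
#: optional manifest columns
MANIFEST_OPTIONAL = {"tss_distance": "tss_distance"}

#: ready-made column_map for the real Illumina HumanMethylation450 manifest
ILLUMINA_450K_COLUMN_MAP = {
    "probe_id": "IlmnID",
    "gene": "UCSC_RefGene_Name",
    "region_group": "UCSC_RefGene_Group",
    "island_relation": "Relation_to_UCSC_CpG_Island",
    "chromosome": "CHR",
    "position": "MAPINFO",
}

_ISLAND_ALIASES = {
    "island": "Island",
    "n_shore": "Shore",
    "s_shore": "Shore",
    "shore": "Shore",
    "n_shelf": "Shelf",
    "s_shelf": "Shelf",
    "shelf": "Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "": "Unknown",
}

_REGION_ALIASES = {
    "tss200": "TSS200",
    "tss1500": "TSS1500",
    "5'utr": "5'UTR",
    "5utr": "5'UTR",
    "1stexon": "1stExon",
    "body": "Body",
    "3'utr": "3'UTR",
    "3utr": "3'UTR",
    "": "Unknown",
}


def _split_cell(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(";")]


def read_manifest(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[ProbeAnnotation]:
    """Parse a probe annotation table into :class:`ProbeAnnotation` records.

    Multi-gene cells use the Illumina semicolon dialect: the gene column and
    the region-group column are split on ";" and paired positionally.  When
    the same gene repeats within one probe with conflicting regions, the
    first-listed region wins and a warning is logged.
    """
    colmap = dict(MANIFEST_COLUMNS)
    colmap.update(MANIFEST_OPTIONAL)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical in MANIFEST_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise FormatError(
                f"manifest is missing required column {colmap[canonical]!r} "
                f"(for {canonical})"
            )
    has_tss = colmap["tss_distance"] in df.columns

    annotations: list[ProbeAnnotation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        probe_id = row[colmap["probe_id"]].strip()
        if probe_id in seen:
            raise FormatError(f"duplicate probe_id {probe_id!r} in manifest")
        seen.add(probe_id)

        genes = _split_cell(row[colmap["gene"]])
        regions = _split_cell(row[colmap["region_group"]])
        tss_cells = _split_cell(row[colmap["tss_distance"]]) if has_tss else []

        region_map: dict[str, str] = {}
        tss_map: dict[str, int] = {}
        ordered_genes: list[str] = []
        for i, gene in enumerate(genes):
            region_raw = regions[i] if i < len(regions) else ""
            region = _REGION_ALIASES.get(region_raw.lower(), region_raw)
            if gene in region_map:
                if region_map[gene] != region:
                    logger.warning(
                        "probe %s: gene %s listed with conflicting regions "
                        "(%s vs %s); keeping first",
                        probe_id, gene, region_map[gene], region,
                    )
                continue
            ordered_genes.append(gene)
            region_map[gene] = region
            if i < len(tss_cells) and tss_cells[i]:
                tss_map[gene] = int(tss_cells[i])

        island_raw = str(row[colmap["island_relation"]]).strip()
        island = _ISLAND_ALIASES.get(island_raw.lower(), island_raw)

        annotations.append(
            ProbeAnnotation(
                probe_id=probe_id,
                gene_symbols=ordered_genes,
                region_group_per_gene=region_map,
                cpg_island_relation=island,
                chromosome=str(row[colmap["chromosome"]]).strip(),
                position=int(row[colmap["position"]]),
                tss_distance_per_gene=tss_map or None,
            )
        )
    return annotations


def write_manifest(annotations: Iterable[ProbeAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        tss = ann.tss_distance_per_gene or {}
        rows.append(
            {
                "probe_id": ann.probe_id,
                "gene": ";".join(ann.gene_symbols),
                "region_group": ";".join(
                    ann.region_group_per_gene[g] for g in ann.gene_symbols
                ),
                "island_relation": ann.cpg_island_relation,
                "chromosome": ann.chromosome,
                "position": ann.position,
                "tss_distance": ";".join(
                    str(tss[g]) if g in tss else "" for g in ann.gene_symbols
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "probe_id", "gene", "region_group", "island_relation",
            "chromosome", "position", "tss_distance",
        ],
    ).to_csv(path, sep="\t", index=False)


def build_gene_probe_map(annotations: Iterable[ProbeAnnotation]) -> GeneProbeMap:
    """gene -> candidate probes, in manifest (input) order."""
    gmap: GeneProbeMap = {}
    for ann in annotations:
        for gene in ann.gene_symbols:
            gmap.setdefault(gene, []).append(ann.probe_id)
    return gmap


def _load_numeric(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                row_label = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"non-numeric cell at row {row_label!r}, column {col!r}"
                )
            df[col] = coerced
    return df.astype(float)


def read_matrix(
    path,
    kind: str,
    missing: str = "error",
    permissive: bool = False,
    mode: str = "paired_ratio",
):
    """Load a methylation or expression matrix from TSV.

    First column = row ids, header = sample ids.  Methylation values must
    lie in [0, 1] unless ``permissive`` is set.  ``missing`` is either
    ``"error"`` (default) or ``"drop_row"``.
    """
    if kind not in ("methylation", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = _load_numeric(path)
    if df.isna().any().any():
        if missing == "drop_row":
            before = len(df)
            df = df.dropna(axis=0)
            logger.warning("dropped %d rows with missing values", before - len(df))
        else:
            row_label = df.index[df.isna().any(axis=1).to_numpy().argmax()]
            raise FormatError(
                f"missing value in row {row_label!r} (use missing='drop_row' to drop)"
            )
    row_ids = [str(r) for r in df.index]
    sample_ids = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if kind == "methylation":
        if not permissive and values.size and (
            values.min() < 0.0 or values.max() > 1.0
        ):
            raise FormatError(
                "beta values outside [0, 1]; pass permissive=True to accept"
            )
        return MethylationMatrix(row_ids, sample_ids, values)
    return ExpressionMatrix(row_ids, sample_ids, values, mode=mode)


def write_matrix(matrix, path) -> None:
    """Write a matrix to TSV with full-precision (round-trippable) floats."""
    pd.DataFrame(
        matrix.values, index=matrix.row_ids, columns=matrix.sample_ids
    ).to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def write_labels(label_table: pd.DataFrame, path) -> None:
    """Write a gene x sample table of {up, down, baseline} strings."""
    label_table.to_csv(path, sep="\t", index_label="gene_id")


def write_selection_results(results: Iterable[SelectionResult], path) -> None:
    """One row per gene, sorted by gene_id: probes comma-joined in order."""
    rows = [
        {
            "gene_id": r.gene_id,
            "method": r.method,
            "n_selected": len(r.selected_probe_ids),
            "probes": ",".join(r.selected_probe_ids),
            "final_cv_error": r.final_cv_error,
        }
        for r in sorted(results, key=lambda r: r.gene_id)
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "method", "n_selected", "probes", "final_cv_error"]
    ).to_csv(path, sep="\t", index=False)


def read_selection_results(path) -> list[SelectionResult]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "probes": str})
    results = []
    for _, row in df.iterrows():
        probes = [] if pd.isna(row["probes"]) else str(row["probes"]).split(",")
        probes = [p for p in probes if p]
        results.append(
            SelectionResult(
                gene_id=str(row["gene_id"]),
                method=str(row["method"]),
                selected_probe_ids=probes,
                final_cv_error=float(row["final_cv_error"]),
            )
        )
    return results


def write_evaluation_records(records: Iterable[EvaluationRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "method": r.method,
            "classifier": r.classifier,
            "tp": r.confusion.tp,
            "tn": r.confusion.tn,
            "fp": r.confusion.fp,
            "fn": r.confusion.fn,
            "accuracy": r.accuracy,
            "precision": r.precision,
            "recall": r.recall,
            "specificity": r.specificity,
            "mcc": r.mcc,
            "n_probes": r.n_probes,
        }
        for r in sorted(records, key=lambda r: r.gene_id)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id", "method", "classifier", "tp", "tn", "fp", "fn",
            "accuracy", "precision", "recall", "specificity", "mcc", "n_probes",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_gene_list(genes: Iterable[str], path) -> None:
    """Plain text, one gene symbol per line (enrichment-tool ready)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")
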