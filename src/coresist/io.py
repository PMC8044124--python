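"""Readers and writers for all tabular dialects used by the pipeline.

Matrices (response, expression, binary alterations) are CSV with a header
row, cell lines as rows and drugs/genes as columns; mutations are a long TSV
(cell_line, gene, mutation_type); gene sets are one-gene-per-line text;
networks export as GraphML and a 3-column edge-list TSV.  Empty cells and
"NA" map to missing.  Output tables written by the pipeline start with a
``#`` comment line recording tool version and config hash, which all readers
here skip.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .binarize import (
    POLARITIES,
    RESISTANT,
    SENSITIVE,
    ResponseMatrix,
    SensitivityCalls,
    WaterfallResult,
)
from .errors import SchemaError
from .genomic_assoc import MUTATION_TYPES
from .geneset_match import GeneSet

NA_VALUES = ["", "NA"]


def _read_table(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(
            path, comment="#", na_values=NA_VALUES, keep_default_na=False, **kwargs
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicated {what}: {dup[:5]}")


def read_matrix(path, value_kind: str = "numeric") -> pd.DataFrame:
    """Cell-line × feature matrix; duplicate ids rejected, non-numeric cells named."""
    df = _read_table(path, index_col=0)
    _check_unique(df.index, "cell-line id", path)
    _check_unique(df.columns, "column id", path)
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_response(
    path, polarity: str = "high_is_sensitive", scale_label: str = ""
) -> ResponseMatrix:
    if polarity not in POLARITIES:
        raise SchemaError(f"unknown polarity {polarity!r}; expected one of {POLARITIES}")
    return ResponseMatrix(
        values=read_matrix(path), polarity=polarity, scale_label=scale_label
    )


def write_response(matrix: ResponseMatrix, path) -> None:
    matrix.values.to_csv(path, index_label="cell_line", float_format="%.17g")


def read_calls(path, thresholds_path=None) -> SensitivityCalls:
    """Binarized calls CSV (sensitive/resistant/blank) with optional thresholds CSV."""
    df = _read_table(path, index_col=0, dtype=str)
    _check_unique(df.index, "cell-line id", path)
    _check_unique(df.columns, "drug id", path)
    allowed = {SENSITIVE, RESISTANT}
    for col in df.columns:
        bad = df[col].dropna()[~df[col].dropna().isin(allowed)]
        if not bad.empty:
            raise SchemaError(
                f"{path}: invalid call at row {bad.index[0]!r}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            )
    thresholds: dict[str, WaterfallResult] = {}
    if thresholds_path is not None:
        tdf = _read_table(thresholds_path)
        required = {"drug_id", "n_used", "linearity_r", "rule", "threshold"}
        missing = required - set(tdf.columns)
        if missing:
            raise SchemaError(f"{thresholds_path}: missing columns {sorted(missing)}")
        for _, row in tdf.iterrows():
            cut = row.get("cutpoint_index")
            thresholds[row["drug_id"]] = WaterfallResult(
                drug_id=row["drug_id"],
                n_used=int(row["n_used"]),
                linearity_r=float(row["linearity_r"]),
                rule=row["rule"],
                threshold=float(row["threshold"]),
                cutpoint_index=None if pd.isna(cut) else int(cut),
            )
    return SensitivityCalls(calls=df.where(df.notna()), thresholds=thresholds)


def write_calls(calls: SensitivityCalls, path, thresholds_path=None) -> None:
    calls.calls.to_csv(path, index_label="cell_line")
    if thresholds_path is not None:
        rows = [
            {
                "drug_id": t.drug_id,
                "n_used": t.n_used,
                "linearity_r": t.linearity_r,
                "rule": t.rule,
                "threshold": t.threshold,
                "cutpoint_index": t.cutpoint_index,
            }
            for t in calls.thresholds.values()
        ]
        pd.DataFrame(rows).to_csv(thresholds_path, index=False, float_format="%.17g")


def read_mutations(path) -> pd.DataFrame:
    df = _read_table(path, sep="\t")
    required = {"cell_line", "gene", "mutation_type"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: mutation table missing columns {sorted(missing)}")
    bad = set(df["mutation_type"].dropna()) - set(MUTATION_TYPES)
    if bad:
        raise SchemaError(f"{path}: unknown mutation types {sorted(bad)}")
    return df


def read_gene_set(path, label: str | None = None) -> GeneSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(genes) != len(set(genes)):
        raise SchemaError(f"{path}: duplicated gene ids in gene set")
    return GeneSet(
        label=label or path.stem, members=frozenset(genes), source=str(path)
    )


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


def read_annotations(path, key: str, value: str) -> dict[str, str]:
    """Two columns of a CSV as a key → value map (e.g. cell_line → lineage)."""
    df = _read_table(path)
    for col in (key, value):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    _check_unique(pd.Index(df[key]), key, path)
    return dict(zip(df[key], df[value]))


def write_network(graph: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    """Export a co-resistance network as GraphML and/or an edge-list TSV."""
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edgelist_path is not None:
        rows = [
            {
                "drug_a": a,
                "drug_b": b,
                "normalized_frequency": data.get("normalized_frequency"),
                "count": data.get("count"),
                "degree_bin": data.get("degree_bin"),
            }
            for a, b, data in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows).to_csv(edgelist_path, sep="\t", index=False)


def read_network(graphml_path) -> nx.Graph:
    return nx.read_graphml(graphml_path)


def write_stage_table(df: pd.DataFrame, path, config_hash: str = "", **to_csv) -> None:
    """Write a pipeline output table with a version/config header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# coresist {__version__} config={config_hash}\n")
        df.to_csv(fh, **to_csv)
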