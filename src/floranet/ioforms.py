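"""Tabular and network I/O for the pipeline.

All tabular files are tab-separated with LF line endings and a fixed column
order, so writers are byte-deterministic. Floats are serialized with 6
significant digits. Counts must be exact integers ("." / NA is forbidden);
compound tables may carry "NA" for assay dropouts, which downstream
statistics handle pairwise-complete.

Schemas
-------
counts.tsv       gene_id, length, <sample...>           (integer cells)
design.tsv       sample_id, stage, replicate
compounds.tsv    analyte, kind, <sample...>             ("NA" allowed)
ct.tsv           sample, gene, ct_rep1..ct_repR; header comments
                 "# reference_gene: X" and "# calibrator: Y"
annotation.tsv   gene_id, pathway_id, pathway_name      (long format)
network.sif      "u\tco_expr\tv" per edge
network.graphml  node attrs kind/degree/rms_lfc/is_hub, edge attrs r/p
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .design import DEFAULT_STAGES, SampleDesign
from .diffexpr import CountMatrix
from .enrich import PathwayAnnotation
from .groupstats import CompoundTable
from .qpcr import CtTable

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n")


# -- counts -----------------------------------------------------------------

def read_counts(path) -> CountMatrix:
    raw = _read_tsv(path)
    if list(raw.columns[:2]) != ["gene_id", "length"]:
        raise ParseError(f"{path}: first columns must be gene_id, length")
    if raw["gene_id"].duplicated().any():
        dupes = raw.loc[raw["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene id(s) {dupes}")
    sample_cols = list(raw.columns[2:])
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns")

    def to_int(cell: str, gene: str, col: str) -> int:
        try:
            value = float(cell)
        except ValueError:
            raise ParseError(f"{path}: non-numeric count {cell!r} at gene {gene}, sample {col}")
        if not value.is_integer() or value < 0:
            raise ParseError(
                f"{path}: count must be a non-negative integer, got {cell!r} "
                f"at gene {gene}, sample {col}"
            )
        return int(value)

    counts = pd.DataFrame(
        {
            col: [to_int(c, g, col) for c, g in zip(raw[col], raw["gene_id"])]
            for col in sample_cols
        },
        index=pd.Index(raw["gene_id"], name="gene_id"),
        dtype=np.int64,
    )
    try:
        lengths = pd.to_numeric(raw["length"], errors="raise")
    except (ValueError, TypeError):
        bad = [v for v in raw["length"] if not str(v).replace(".", "", 1).isdigit()]
        raise ParseError(f"{path}: non-numeric gene length(s) {bad[:5]}")
    lengths = pd.Series(lengths.to_numpy(dtype=np.int64), index=counts.index, name="length")
    if (lengths <= 0).any():
        raise ParseError(f"{path}: non-positive gene length")
    return CountMatrix(counts=counts, lengths=lengths)


def write_counts(matrix: CountMatrix, path) -> None:
    frame = matrix.counts.reset_index()
    frame.insert(1, "length", matrix.lengths.to_numpy())
    _write_tsv(frame, path)


# -- design -----------------------------------------------------------------

def read_design(path, allowed_stages=DEFAULT_STAGES) -> SampleDesign:
    raw = _read_tsv(path)
    try:
        return SampleDesign(raw, allowed_stages=tuple(allowed_stages))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_design(design: SampleDesign, path) -> None:
    _write_tsv(design.table[["sample_id", "stage", "replicate"]], path)


# -- compounds --------------------------------------------------------------

def read_compounds(path) -> CompoundTable:
    raw = _read_tsv(path)
    if list(raw.columns[:2]) != ["analyte", "kind"]:
        raise ParseError(f"{path}: first columns must be analyte, kind")
    if raw["analyte"].duplicated().any():
        dupes = raw.loc[raw["analyte"].duplicated(), "analyte"].tolist()
        raise ParseError(f"{path}: duplicate analyte(s) {dupes}")
    sample_cols = list(raw.columns[2:])
    values = {}
    for col in sample_cols:
        parsed = []
        for cell, analyte in zip(raw[col], raw["analyte"]):
            if cell in ("NA", ""):
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric concentration {cell!r} at analyte {analyte}, "
                    f"sample {col}"
                )
        values[col] = parsed
    frame = pd.DataFrame(values, index=pd.Index(raw["analyte"], name="analyte"))
    kinds = pd.Series(raw["kind"].to_numpy(), index=frame.index, name="kind")
    try:
        return CompoundTable(values=frame, kinds=kinds)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_compounds(table: CompoundTable, path) -> None:
    frame = table.values.copy()
    frame.insert(0, "kind", table.kinds.to_numpy())
    frame = frame.reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n", na_rep="NA")


# -- Ct ---------------------------------------------------------------------

def read_ct(path) -> CtTable:
    reference, calibrator = None, None
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").partition(":")
            if key.strip() == "reference_gene":
                reference = value.strip()
            elif key.strip() == "calibrator":
                calibrator = value.strip()
    if reference is None or calibrator is None:
        raise ParseError(f"{path}: missing '# reference_gene:' or '# calibrator:' header")
    raw = _read_tsv(path)
    rep_cols = [c for c in raw.columns if c.startswith("ct_rep")]
    if list(raw.columns[:2]) != ["sample", "gene"] or not rep_cols:
        raise ParseError(f"{path}: expected columns sample, gene, ct_rep1..")
    records = []
    for _, row in raw.iterrows():
        for col in rep_cols:
            if row[col] in ("NA", ""):
                continue
            try:
                ct = float(row[col])
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric Ct {row[col]!r} at sample {row['sample']}, "
                    f"gene {row['gene']}"
                )
            records.append({"sample": row["sample"], "gene": row["gene"], "ct": ct})
    try:
        return CtTable(table=pd.DataFrame.from_records(records), reference_gene=reference,
                       calibrator_sample=calibrator)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ct(ct: CtTable, path) -> None:
    wide = ct.table.copy()
    wide["rep"] = wide.groupby(["sample", "gene"]).cumcount() + 1
    pivot = wide.pivot(index=["sample", "gene"], columns="rep", values="ct")
    pivot.columns = [f"ct_rep{r}" for r in pivot.columns]
    pivot = pivot.reset_index()
    with open(path, "w", newline="\n") as handle:
        handle.write(f"# reference_gene: {ct.reference_gene}\n")
        handle.write(f"# calibrator: {ct.calibrator_sample}\n")
        pivot.to_csv(handle, sep="\t", index=False, float_format=FLOAT_FORMAT,
                     lineterminator="\n", na_rep="NA")


# -- annotation -------------------------------------------------------------

def read_annotation(path) -> PathwayAnnotation:
    raw = _read_tsv(path)
    needed = ["gene_id", "pathway_id", "pathway_name"]
    if list(raw.columns) != needed:
        raise ParseError(f"{path}: expected columns {needed}")
    gene_pathways: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for _, row in raw.iterrows():
        gene_pathways.setdefault(row["gene_id"], set()).add(row["pathway_id"])
        names[row["pathway_id"]] = row["pathway_name"]
    return PathwayAnnotation(gene_pathways=gene_pathways, pathway_names=names)


def write_annotation(annotation: PathwayAnnotation, path) -> None:
    rows = [
        {"gene_id": gene, "pathway_id": pw, "pathway_name": annotation.name_of(pw)}
        for gene in sorted(annotation.gene_pathways)
        for pw in sorted(annotation.gene_pathways[gene])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["gene_id", "pathway_id", "pathway_name"]), path)


# -- network ----------------------------------------------------------------

def export_network(graph: nx.Graph, path, fmt: str = "sif") -> None:
    """Write the co-expression network for standard network viewers.

    ``fmt`` is "sif" (one ``u  co_expr  v`` line per edge) or "graphml"
    (node kind/degree/rms_lfc/is_hub and edge r/p attributes preserved).
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        lines = [f"{u}\tco_expr\t{v}" for u, v in sorted(graph.edges())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), newline="\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")


# -- results tables ---------------------------------------------------------

def write_contrast_result(result, path) -> None:
    frame = result.table.reset_index().rename(columns={"index": "gene", "gene_id": "gene"})
    _write_tsv(frame, path)


def write_hub_table(hub_table: pd.DataFrame, path) -> None:
    frame = hub_table.copy()
    frame["is_hub"] = frame["is_hub"].map({True: "yes", False: "no"})
    _write_tsv(frame[["feature", "kind", "degree", "rms_lfc", "is_hub"]], path)


# -- config -----------------------------------------------------------------

def read_config(path) -> dict:
    """Flat key-value run configuration (YAML)."""
    with open(path) as handle:
        cfg = yaml.safe_load(handle) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w", newline="\n") as handle:
        yaml.safe_dump(cfg, handle, default_flow_style=False, sort_keys=True)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", newline="\n")
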