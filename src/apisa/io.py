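"""Readers and writers for the package's text formats.

Expression matrices travel as TSV/CSV with an identifier column; the common
file dialect puts genes in rows, while the in-memory convention everywhere
in this package is samples x genes, so the reader transposes by default.
Bicluster sets are serialised as a single JSON document (schema_version,
parameters, records) with an optional flat TSV companion for spreadsheets.
Label vectors, methylation beta matrices and CpG region annotations are
plain two-column / matrix TSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import REGION_CATEGORIES
from .records import BiclusterRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression", "subset_genes",
    "read_labels", "write_labels",
    "read_biclusters", "write_biclusters", "biclusters_to_tsv",
    "read_methylation", "write_methylation",
    "read_region_annotation", "write_region_annotation",
]

BICLUSTER_SCHEMA_VERSION = 1


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids, what: str, path) -> None:
    counts = pd.Index(ids).value_counts()
    dup = counts[counts > 1]
    if len(dup):
        raise ValueError(
            f"{path}: duplicate {what} identifiers: {list(dup.index[:5])}"
        )


def read_expression(path, orientation: str = "genes_in_rows",
                    impute: str | None = None) -> pd.DataFrame:
    """Load an expression matrix into samples x genes orientation.

    Parameters
    ----------
    path : file path to a TSV/CSV with a header row and identifiers in the
        first column.
    orientation : {"genes_in_rows", "samples_in_rows"}
        Axis meaning of the file's rows.  The returned frame is always
        samples x genes; the flag only controls transposition, never values.
    impute : None or "gene_mean"
        Missing values are rejected unless per-gene mean imputation is
        requested explicitly.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    _check_unique(df.index, "row", path)
    _check_unique(df.columns, "column", path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if orientation == "genes_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        if impute == "gene_mean":
            n_miss = int(df.isna().sum().sum())
            df = df.fillna(df.mean(axis=0))
            log.info("imputed %d missing values with per-gene means", n_miss)
            if df.isna().any().any():
                raise ValueError(f"{path}: genes with all values missing")
        else:
            miss = df.isna().sum().sum()
            raise ValueError(
                f"{path}: {miss} missing values (pass impute='gene_mean' "
                "to impute)"
            )
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 samples and 2 genes")
    log.info("loaded expression matrix: %d samples x %d genes", *df.shape)
    return df


def write_expression(E: pd.DataFrame, path,
                     orientation: str = "genes_in_rows") -> None:
    """Write a samples x genes frame in the requested file orientation."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    out = E.T if orientation == "genes_in_rows" else E
    out.to_csv(path, sep=_sep(path))


def subset_genes(E: pd.DataFrame, gene_list):
    """Restrict columns to ``gene_list``, preserving E's column order.

    Returns ``(matrix, n_unmatched)`` where ``n_unmatched`` counts requested
    names absent from the matrix.  An empty intersection is an error.
    """
    wanted = list(gene_list)
    if not wanted:
        raise ValueError("empty gene list")
    present = set(E.columns)
    matched = [g for g in wanted if g in present]
    n_unmatched = len(set(wanted) - present)
    if not matched:
        raise ValueError("no gene in the list matches the matrix")
    keep = set(matched)
    cols = [c for c in E.columns if c in keep]
    if n_unmatched:
        log.info("gene subset: %d requested names unmatched", n_unmatched)
    return E[cols], n_unmatched


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample_id, label) -> Series indexed by sample id."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns sample_id<TAB>label")
    _check_unique(df.iloc[:, 0], "sample", path)
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                  name=df.columns[1])
    return s


def write_labels(labels: pd.Series, path, label_name: str = "label") -> None:
    df = pd.DataFrame({"sample_id": labels.index,
                       label_name: labels.values})
    df.to_csv(path, sep=_sep(path), index=False)


def _record_to_json(rec: BiclusterRecord) -> dict:
    return {
        "id": rec.id,
        "samples": sorted(rec.samples),
        "genes": sorted(rec.genes),
        "seed_group": rec.seed_group,
        "t_g": rec.t_g,
        "t_c": rec.t_c,
        "n_iterations": rec.n_iterations,
        "converged": rec.converged,
        "basin_count": rec.basin_count,
    }


def write_biclusters(records, path, parameters: dict | None = None) -> None:
    """Serialise a bicluster set as one JSON document."""
    doc = {
        "schema_version": BICLUSTER_SCHEMA_VERSION,
        "parameters": parameters or {},
        "biclusters": [_record_to_json(r) for r in records],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_biclusters(path):
    """Load a bicluster JSON document; returns (records, parameters)."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != BICLUSTER_SCHEMA_VERSION:
        raise ValueError(f"{path}: unknown schema_version {version!r}")
    records = []
    for d in doc["biclusters"]:
        records.append(BiclusterRecord(
            id=str(d["id"]),
            samples=frozenset(d["samples"]),
            genes=frozenset(d["genes"]),
            seed_group=d.get("seed_group"),
            t_g=d.get("t_g"),
            t_c=d.get("t_c"),
            n_iterations=d.get("n_iterations"),
            converged=bool(d.get("converged", True)),
            basin_count=int(d.get("basin_count", 1)),
        ))
    return records, doc.get("parameters", {})


def biclusters_to_tsv(records, path) -> None:
    """Flat (bicluster_id, axis, id) companion table."""
    rows = []
    for rec in records:
        rows += [(rec.id, "sample", s) for s in sorted(rec.samples)]
        rows += [(rec.id, "gene", g) for g in sorted(rec.genes)]
    pd.DataFrame(rows, columns=["bicluster_id", "axis", "id"]).to_csv(
        path, sep="\t", index=False
    )


def read_methylation(path) -> pd.DataFrame:
    """CpG x sample beta matrix; values must be in [0, 1] or missing."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    _check_unique(df.index, "CpG", path)
    _check_unique(df.columns, "sample", path)
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.nansum(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: beta value {vals[i, j]} outside [0, 1] at "
            f"CpG {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_methylation(M: pd.DataFrame, path) -> None:
    M.to_csv(path, sep=_sep(path))


def read_region_annotation(path) -> pd.Series:
    """Two-column TSV (cpg_id, region); regions must be from the closed set."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns cpg_id<TAB>region")
    _check_unique(df.iloc[:, 0], "CpG", path)
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                  name="region")
    bad = set(s.unique()) - set(REGION_CATEGORIES)
    if bad:
        raise ValueError(f"{path}: unknown region categories {sorted(bad)}; "
                         f"expected one of {list(REGION_CATEGORIES)}")
    return s


def write_region_annotation(annotation: pd.Series, path) -> None:
    pd.DataFrame({"cpg_id": annotation.index,
                  "region": annotation.values}).to_csv(path, sep="\t",
                                                       index=False)
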