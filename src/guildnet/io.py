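"""Readers and writers for the on-disk formats.

TSV dialect throughout: tab-separated, UTF-8, first row header, first column
identifiers, ``#`` comment lines ignored.  Count tables may carry an optional
``taxonomy`` column with semicolon rank-prefixed lineage strings; networks go
to GraphML or a flat edge-list TSV (columns source, target, weight, sign).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (CountTable, RelAbundanceTable, SampleMetadata,
                         format_lineage, parse_lineage)
from .errors import ConfigurationError, FormatError

TAXONOMY_COLUMN = "taxonomy"


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=object)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return df


def read_count_table(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a count TSV and normalise it to the taxa x samples orientation.

    Parameters
    ----------
    orientation : {"taxa_rows", "samples_rows"}
        Which axis the file's rows represent.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty count table")
    lineage = None
    if orientation == "taxa_rows" and TAXONOMY_COLUMN in df.columns:
        lineage = {str(t): parse_lineage(v)
                   for t, v in df[TAXONOMY_COLUMN].items()}
        df = df.drop(columns=[TAXONOMY_COLUMN])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        raise FormatError(f"{path}: non-numeric cell in column {col!r}")
    if orientation == "samples_rows":
        numeric = numeric.T
    return CountTable(numeric, lineage=lineage)


def write_count_table(ct: CountTable, path) -> None:
    df = ct.counts.copy()
    if ct.lineage is not None:
        df[TAXONOMY_COLUMN] = [format_lineage(ct.lineage[t]) for t in ct.taxon_ids]
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> SampleMetadata:
    df = _read_tsv(path)
    df.index.name = "sample_id"
    for col in df.columns:
        if col not in ("group", "family_id"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path) -> None:
    md.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_matrix(path) -> pd.DataFrame:
    """Square matrix TSV (ids in header and first column) as a DataFrame."""
    df = _read_tsv(path).apply(pd.to_numeric, errors="coerce")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: matrix row and column ids differ")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


# -- networks ----------------------------------------------------------------

def validate_network(net: nx.Graph, rho_threshold: float | None = None) -> None:
    """Assert the structural invariants of a co-occurrence network."""
    if any(u == v for u, v in net.edges):
        raise FormatError("network contains a self-loop")
    for u, v, data in net.edges(data=True):
        if "weight" not in data or "sign" not in data:
            raise FormatError(f"edge {u}-{v} lacks weight/sign attributes")
        if data["sign"] not in ("+", "-"):
            raise FormatError(f"edge {u}-{v} has invalid sign {data['sign']!r}")
        if rho_threshold is not None and abs(data["weight"]) < rho_threshold:
            raise FormatError(f"edge {u}-{v} below the rho threshold")


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    validate_network(net)
    path = Path(path)
    if format == "edge_tsv":
        rows = [{"source": u, "target": v,
                 "weight": d["weight"], "sign": d["sign"]}
                for u, v, d in sorted(net.edges(data=True))]
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
            path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ConfigurationError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    path = Path(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        net = nx.Graph()
        for row in df.itertuples(index=False):
            net.add_edge(row.source, row.target,
                         weight=float(row.weight), sign=str(row.sign))
        return net
    if format == "graphml":
        return nx.read_graphml(path)
    raise ConfigurationError(f"unknown network format {format!r}")


# -- derived summaries --------------------------------------------------------

def firmicutes_bacteroidetes_ratio(ct: CountTable, metadata: SampleMetadata,
                                   firmicutes: str = "Firmicutes",
                                   bacteroidetes: str = "Bacteroidetes",
                                   ) -> pd.Series:
    """Per-group Firmicutes/Bacteroidetes ratio of the group-mean composition.

    The ratio is a standard coarse index of gut community structure.  A group
    whose mean Bacteroidetes abundance is zero gets NaN (undefined), never an
    exception.
    """
    phylum = ct.aggregate_rank("phylum")
    rel = phylum.to_relative().values
    metadata.require_samples(rel.columns)
    out = {}
    for group in sorted(metadata.groups.unique()):
        cols = [s for s in metadata.samples_in_group(group) if s in rel.columns]
        mean = rel[cols].mean(axis=1)
        f = float(mean.get(firmicutes, 0.0))
        b = float(mean.get(bacteroidetes, 0.0))
        out[group] = f / b if b > 0 else np.nan
    return pd.Series(out, name="firmicutes_bacteroidetes_ratio")
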