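"""Typed in-memory containers for the pipeline.

Everything downstream operates on four objects: an integer taxa-by-sample
:class:`CountTable` (optionally annotated with taxonomic lineages), its
closed :class:`RelAbundanceTable`, a :class:`SampleMetadata` table carrying
group / family / host-covariate information, and a validated
:class:`SymmetricMatrix` holding correlations or distances.  The internal
orientation is fixed as taxa x samples; any other orientation is handled at
the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSampleError, FormatError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                "f": "family", "g": "genus", "s": "species"}
UNCLASSIFIED = "Unclassified"
GROUPS = ("G1", "G2", "G3")


def parse_lineage(text: str | None) -> dict[str, str]:
    """Parse a semicolon-separated, rank-prefixed lineage string.

    ``k__Bacteria;p__Firmicutes;...`` is the dominant 16S convention; any
    field that cannot be parsed (or an empty name) maps to ``Unclassified``.
    """
    out = {rank: UNCLASSIFIED for rank in RANKS}
    if not text or not isinstance(text, str):
        return out
    for piece in text.split(";"):
        piece = piece.strip()
        if len(piece) >= 3 and piece[1:3] == "__" and piece[0].lower() in _RANK_PREFIX:
            name = piece[3:].strip()
            if name:
                out[_RANK_PREFIX[piece[0].lower()]] = name
    return out


def format_lineage(lineage: Mapping[str, str]) -> str:
    return ";".join(f"{p}__{lineage.get(r, UNCLASSIFIED)}"
                    for p, r in zip("kpcofgs", RANKS))


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise FormatError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


class CountTable:
    """Non-negative integer taxa-by-sample count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are taxa, columns are samples; all cells non-negative integers.
    lineage : mapping taxon_id -> {rank: name}, optional
        When present it must cover every taxon.
    """

    def __init__(self, counts: pd.DataFrame,
                 lineage: Mapping[str, Mapping[str, str]] | None = None):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise FormatError("empty count table")
        _check_unique(counts.index, "taxon")
        _check_unique(counts.columns, "sample")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if np.any(~np.isfinite(values.astype(float))):
            raise FormatError("count table contains non-finite cells")
        if np.any(values < 0):
            raise FormatError("count table contains negative cells")
        if not np.allclose(values, np.round(values.astype(float))):
            raise FormatError("count table contains non-integer cells")
        self.counts = pd.DataFrame(values.astype(np.int64),
                                   index=counts.index.astype(str),
                                   columns=counts.columns.astype(str))
        if lineage is not None:
            missing = [t for t in self.taxon_ids if t not in lineage]
            if missing:
                raise FormatError(f"lineage missing for taxa: {missing[:5]}")
            lineage = {t: dict(lineage[t]) for t in self.taxon_ids}
        self.lineage = lineage

    # -- basic introspection -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lineage == other.lineage

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} taxa x {self.shape[1]} samples)"

    # -- transforms ----------------------------------------------------------
    def to_relative(self) -> "RelAbundanceTable":
        """Close each sample column to sum 1 (total-sum scaling)."""
        totals = self.counts.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise DegenerateSampleError(str(zero.index[0]))
        return RelAbundanceTable(self.counts / totals)

    def aggregate_rank(self, rank: str) -> "CountTable":
        """Sum member taxa into one row per distinct name at ``rank``.

        Taxa with no assignment at ``rank`` pool into ``Unclassified``.
        Per-sample column totals are conserved exactly (integer sums).
        """
        if rank not in RANKS:
            raise ConfigurationError(f"unknown taxonomy rank {rank!r}")
        if self.lineage is None:
            raise ConfigurationError("count table has no lineage annotation")
        names = [self.lineage[t].get(rank, UNCLASSIFIED) for t in self.taxon_ids]
        agg = self.counts.groupby(pd.Index(names, name=rank), sort=True).sum()
        new_lineage = {name: {rank: name} for name in agg.index}
        return CountTable(agg, lineage=new_lineage)

    def filter_taxa(self, keep: Iterable[str]) -> "CountTable":
        keep = [t for t in self.taxon_ids if t in set(keep)]
        lineage = ({t: self.lineage[t] for t in keep}
                   if self.lineage is not None else None)
        return CountTable(self.counts.loc[keep], lineage=lineage)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise FormatError(f"unknown samples: {missing[:5]}")
        return CountTable(self.counts[sample_ids], lineage=self.lineage)


class RelAbundanceTable:
    """Per-sample compositions: same axes as a CountTable, columns sum to 1."""

    def __init__(self, values: pd.DataFrame):
        _check_unique(values.index, "taxon")
        _check_unique(values.columns, "sample")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < -1e-12):
            raise FormatError("relative abundances must be non-negative")
        sums = arr.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = values.columns[np.argmax(np.abs(sums - 1.0))]
            raise FormatError(f"sample column {bad!r} does not sum to 1")
        self.values = values.astype(float)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "RelAbundanceTable":
        return RelAbundanceTable(self.values[list(sample_ids)])

    def __repr__(self) -> str:
        return f"RelAbundanceTable({self.shape[0]} taxa x {self.shape[1]} samples)"


class SampleMetadata:
    """Per-sample group / family / generation labels and host covariates.

    Wraps a DataFrame indexed by sample id with reserved columns ``group``
    (G1/G2/G3), ``family_id`` and ``generation``; every remaining numeric
    column is treated as a named continuous host variable.  Missing host
    values stay NaN — they are never silently zero.
    """

    RESERVED = ("group", "family_id", "generation")

    def __init__(self, table: pd.DataFrame):
        if "group" not in table.columns:
            raise FormatError("metadata requires a 'group' column")
        _check_unique(table.index, "sample")
        table = table.copy()
        table.index = table.index.astype(str)
        bad = sorted(set(table["group"].astype(str)) - set(GROUPS))
        if bad:
            raise FormatError(f"unknown group labels {bad}; expected {GROUPS}")
        table["group"] = table["group"].astype(str)
        if "family_id" in table.columns:
            fam = table["family_id"]
            table["family_id"] = fam.where(fam.notna(), None)
            table.loc[table["family_id"].notna(), "family_id"] = (
                table.loc[table["family_id"].notna(), "family_id"].astype(str))
        if "generation" in table.columns:
            gen = pd.to_numeric(table["generation"], errors="coerce")
            ok = gen.dropna().isin((1, 2, 3)).all()
            if not ok:
                raise FormatError("generation must be 1, 2 or 3 when present")
            table["generation"] = gen.astype("Int64")
        self.table = table

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def family_ids(self) -> pd.Series:
        if "family_id" not in self.table.columns:
            return pd.Series([None] * len(self.table), index=self.table.index,
                             name="family_id", dtype=object)
        return self.table["family_id"]

    @property
    def host_vars(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c not in self.RESERVED]
        return self.table[cols].apply(pd.to_numeric, errors="coerce")

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise FormatError(f"metadata missing samples: {missing[:5]}")

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        self.require_samples(sample_ids)
        return SampleMetadata(self.table.loc[list(sample_ids)])

    def __repr__(self) -> str:
        counts = self.groups.value_counts().to_dict()
        return f"SampleMetadata({len(self.table)} samples, groups={counts})"


@dataclass
class SymmetricMatrix:
    """Validated symmetric matrix: either a correlation or a distance.

    ``kind='correlation'`` forces unit diagonal and entries in [-1, 1];
    ``kind='distance'`` forces zero diagonal and non-negative entries.
    """

    ids: list[str] = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    kind: str = "correlation"

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "matrix")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise FormatError("matrix shape does not match ids")
        if not np.array_equal(v, v.T):
            raise FormatError("matrix is not exactly symmetric")
        if self.kind == "correlation":
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise FormatError("correlation diagonal must be 1")
            if np.any(np.abs(v) > 1 + 1e-12):
                raise FormatError("correlation entries must lie in [-1, 1]")
        elif self.kind == "distance":
            if not np.allclose(np.diag(v), 0.0, atol=1e-12):
                raise FormatError("distance diagonal must be 0")
            if np.any(v < -1e-12):
                raise FormatError("distance entries must be non-negative")
        else:
            raise ConfigurationError(f"unknown matrix kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, ids: Iterable[str]) -> "SymmetricMatrix":
        ids = list(ids)
        pos = {t: i for i, t in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return SymmetricMatrix(ids, self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]
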