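"""Reading and writing count matrices, gene-set collections and gene lists.

The pipeline's entry point is a genes x samples integer read-count table
(TSV preferred, CSV accepted), one column per time-point library, first
column gene identifier.  Gene identifiers are opaque case-sensitive strings;
no symbol/alias mapping is attempted.  Gene sets use the Broad GMT dialect.
All gene-list output is lexicographically sorted for deterministic diffs.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gene_lists",
    "read_gene_lists",
]


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts per gene per sample, samples in time order.

    Attributes
    ----------
    gene_ids : tuple of str
        Unique, non-empty identifiers (row order of ``counts``).
    sample_labels : tuple of str
        Ordered time-point labels, e.g. ``("BEC0W", "BEC20W", "BEC40W",
        "BEC60W")``.
    counts : ndarray of int64, shape (n_genes, n_samples)
        Non-negative read counts.
    """

    gene_ids: tuple
    sample_labels: tuple
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_labels", tuple(self.sample_labels))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x samples array")
        if counts.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        dupes = [g for g, c in Counter(self.gene_ids).items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate gene ids: {sorted(dupes)}")
        if any(not g for g in self.gene_ids):
            raise ValidationError("empty gene id")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_labels)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy())

    def subset(self, gene_ids: Iterable[str]) -> "CountMatrix":
        """Rows restricted to ``gene_ids`` (kept in current row order)."""
        keep = set(gene_ids)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        missing = keep - {self.gene_ids[i] for i in idx}
        if missing:
            raise ValidationError(f"unknown gene ids: {sorted(missing)[:5]}")
        return CountMatrix(
            tuple(self.gene_ids[i] for i in idx), self.sample_labels, self.counts[idx]
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT contents): unique names, non-empty member sets."""

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _sniff_delimiter(header: str) -> str:
    # tab preferred, comma fallback: supplementary tables circulate in both
    return "\t" if "\t" in header else ","


def read_count_matrix(path, sample_order: Sequence[str] | None = None) -> CountMatrix:
    """Read a count table; columns re-ordered to ``sample_order`` if given.

    Raises
    ------
    ConfigurationError
        A requested sample label is absent from the header.
    ValidationError
        Duplicate gene ids (named in the message) or negative / non-integer
        counts.
    ParseError
        Non-numeric cell, reported with gene id and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)

    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate gene ids: {sorted(dupes)}")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric count at gene {frame.index[gi]!r}, "
            f"column {frame.columns[sj]!r}: {frame.iat[gi, sj]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing count at gene {frame.index[gi]!r}, "
            f"column {frame.columns[sj]!r}"
        )

    if sample_order is not None:
        missing = [s for s in sample_order if s not in numeric.columns]
        if missing:
            raise ConfigurationError(
                f"{path}: sample labels not found in header: {missing}"
            )
        numeric = numeric[list(sample_order)]

    values = numeric.to_numpy()
    if not np.all(np.equal(np.mod(values, 1), 0)):
        gi, sj = np.argwhere(~np.equal(np.mod(values, 1), 0))[0]
        raise ValidationError(
            f"{path}: non-integer count at gene {numeric.index[gi]!r}, "
            f"column {numeric.columns[sj]!r}"
        )
    if values.size and values.min() < 0:
        raise ValidationError(f"{path}: negative counts present")
    return CountMatrix(tuple(numeric.index), tuple(numeric.columns), values.astype(np.int64))


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members per line.

    Duplicate members within a line are collapsed; duplicate set names are a
    validation error; a line with fewer than three fields is a parse error.
    """
    path = Path(path)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in members if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=str(path))


def write_gene_lists(sets: Mapping[str, Iterable[str]], path) -> None:
    """Write one column per named set, genes sorted within each column.

    Mirrors supplementary-table style gene lists; ragged columns are padded
    with empty cells.
    """
    names = list(sets)
    if len(set(names)) != len(names):
        raise ValidationError("set names must be unique")
    columns = {name: sorted(set(sets[name])) for name in names}
    depth = max((len(v) for v in columns.values()), default=0)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(names)
        for i in range(depth):
            writer.writerow(
                [columns[n][i] if i < len(columns[n]) else "" for n in names]
            )


def read_gene_lists(path) -> dict[str, list[str]]:
    """Inverse of :func:`write_gene_lists` (empty cells dropped)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        col: [v for v in frame[col].tolist() if v] for col in frame.columns
    }
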