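"""The central H/L time-series pattern algorithm and its filters.

A gene observed at T ordered time points is coded with one letter per time
point: "H" where its (log-scale) expression is strictly above its own
cross-time-point mean, "L" otherwise.  The all-H and all-L codes are
degenerate (possible only for an exactly constant profile under the strict
rule) and are excluded from the category table, leaving 2^T - 2 admissible
categories — 14 for a four-point series.

Filters compose in the pipeline order: minimum-read filter on raw counts,
then normalization, then the fold-variation filter on log2 values, then
classification.  The fold filter keeps genes whose log2 range is at least
log2(fold) — boundary inclusive ("twofold or higher").

Tie rule: a value exactly equal to the gene mean codes as "L"; "H" requires
strictly higher.  Ties are measure-zero on log-transformed count data, but
the strict rule makes constant profiles detectably degenerate instead of
arbitrarily coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import CountMatrix
from .normalize import ExpressionMatrix

__all__ = [
    "PatternCode",
    "CategoryTable",
    "Thresholds",
    "filter_min_reads",
    "filter_fold_variation",
    "classify_pattern",
    "classify_matrix",
    "enumerate_categories",
    "tabulate_categories",
]


@dataclass(frozen=True)
class Thresholds:
    """The two pipeline thresholds: minimum reads and fold variation."""

    min_reads: int = 5
    fold: float = 2.0

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if not self.fold > 1:
            raise ValidationError("fold must be > 1")


@dataclass(frozen=True)
class PatternCode:
    """A length-T string over {H, L}; degenerate iff all-H or all-L."""

    code: str
    degenerate: bool = field(init=False)

    def __post_init__(self):
        if not self.code or set(self.code) - {"H", "L"}:
            raise ValidationError(f"invalid pattern code {self.code!r}")
        object.__setattr__(
            self, "degenerate", len(set(self.code)) == 1
        )

    def __str__(self) -> str:
        return self.code

    def __len__(self) -> int:
        return len(self.code)

    def complement(self) -> "PatternCode":
        swapped = self.code.translate(str.maketrans("HL", "LH"))
        return PatternCode(swapped)


@dataclass(frozen=True)
class CategoryTable:
    """Gene counts and member lists over all 2^T - 2 admissible codes.

    Every admissible code is present (possibly with zero genes); member
    lists are lexicographically sorted; counts sum to the number of
    classified genes.
    """

    T: int
    counts: Mapping[str, int]
    members: Mapping[str, tuple]

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, code: str) -> int:
        return self.counts[code]


def filter_min_reads(counts: CountMatrix, min_reads: int = 5) -> list[str]:
    """Gene ids with at least ``min_reads`` in at least one sample.

    The excluded complement is exactly the genes with fewer than
    ``min_reads`` reads in every sample; kept and excluded partition the
    input (row order preserved in the returned list).
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    keep = np.any(counts.counts >= min_reads, axis=1)
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def filter_fold_variation(expr: ExpressionMatrix, fold: float = 2.0) -> list[str]:
    """Gene ids whose log2 range across time points is >= log2(fold)."""
    if not fold > 1:
        raise ValidationError("fold must be > 1")
    ranges = expr.values.max(axis=1) - expr.values.min(axis=1)
    threshold = np.log2(fold)
    return [g for g, r in zip(expr.gene_ids, ranges) if r >= threshold]


def classify_pattern(profile: Sequence[float]) -> PatternCode:
    """Code each time point H (strictly above the profile mean) or L.

    A constant profile yields the degenerate all-L code.
    """
    values = np.asarray(profile, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("profile must be 1-D with at least two time points")
    if not np.all(np.isfinite(values)):
        raise ValidationError("profile contains non-finite values")
    mean = values.mean()
    return PatternCode("".join("H" if v > mean else "L" for v in values))


def classify_matrix(
    expr: ExpressionMatrix, gene_subset: Iterable[str] | None = None
) -> dict[str, PatternCode]:
    """Per-gene pattern codes, optionally restricted to a gene subset."""
    sub = expr if gene_subset is None else expr.subset(gene_subset)
    return {g: classify_pattern(row) for g, row in zip(sub.gene_ids, sub.values)}


def enumerate_categories(T: int) -> list[str]:
    """All 2^T - 2 admissible codes in lexicographic order (H < L)."""
    if T < 2:
        raise ValidationError("need at least two time points")
    return [
        "".join(letters)
        for letters in product("HL", repeat=T)
        if len(set(letters)) > 1
    ]


def tabulate_categories(codes: Mapping[str, PatternCode] | Iterable[PatternCode]) -> CategoryTable:
    """Count genes per admissible category.

    Accepts either a gene-id -> PatternCode mapping (member lists recorded)
    or a bare iterable of codes.  A degenerate code is a validation error:
    callers must drop or report degenerates separately, never fold them in
    silently.
    """
    if isinstance(codes, Mapping):
        items = list(codes.items())
    else:
        items = [(None, c) for c in codes]
    if not items:
        # length unknown for an empty input; default to the four-point design
        T = 4
    else:
        lengths = {len(c) for _, c in items}
        if len(lengths) != 1:
            raise ValidationError(f"mixed code lengths: {sorted(lengths)}")
        (T,) = lengths
    admissible = enumerate_categories(T)
    counts = {code: 0 for code in admissible}
    members: dict[str, list] = {code: [] for code in admissible}
    for gene, pc in items:
        if pc.degenerate:
            raise ValidationError(
                f"degenerate code {pc.code!r}"
                + (f" for gene {gene!r}" if gene else "")
                + "; drop or report degenerate genes separately"
            )
        counts[pc.code] += 1
        if gene is not None:
            members[pc.code].append(gene)
    return CategoryTable(
        T,
        counts,
        {code: tuple(sorted(genes)) for code, genes in members.items()},
    )
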