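"""Library-depth normalization and a regularized-log-style transform.

Size factors are the classic median-of-ratios estimate: per sample, the
median over genes (restricted to genes with positive counts in every
sample) of the ratio between the gene's count in that sample and the gene's
geometric mean across samples.

The expression transform is a transparent surrogate for a regularized log:

    v_gj = (1 - s) * log2(c_gj / f_j + pc)  +  s * mean_j log2(c_gj / f_j + pc)

i.e. a convex shrink of each gene's log2 normalized profile toward its own
mean, with shrinkage s in [0, 1) and pseudocount pc > 0.  With one library
per time point there are no replicates to estimate dispersions from, so a
model-based regularization is degenerate; the shrinkage knob makes the
downstream fold-threshold sensitivity explicit instead (at s = 0 the
transform is the plain log2, and a gene's log range contracts exactly by
(1 - s)).  Log base is 2 throughout, so "twofold variation" means a range
of at least 1 on this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix

__all__ = [
    "SizeFactors",
    "ExpressionMatrix",
    "compute_size_factors",
    "rlog_like_transform",
    "write_expression_matrix",
]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scale factors correcting library depth."""

    sample_labels: tuple
    factors: np.ndarray

    def __post_init__(self):
        factors = np.asarray(self.factors, dtype=float)
        if factors.shape != (len(self.sample_labels),):
            raise ValidationError("one factor per sample required")
        if factors.size and not np.all(factors > 0):
            raise ValidationError("size factors must be positive")
        factors.setflags(write=False)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "sample_labels", tuple(self.sample_labels))


@dataclass(frozen=True)
class ExpressionMatrix:
    """log2-scale normalized expression, same gene/sample order as its source."""

    gene_ids: tuple
    sample_labels: tuple
    values: np.ndarray
    pseudocount: float = 1.0
    shrinkage: float = 0.0
    size_factors: SizeFactors | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ValidationError("values shape must be genes x samples")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_labels", tuple(self.sample_labels))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_labels)
        )

    def profile(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise ValidationError(f"unknown gene id {gene_id!r}") from None
        return self.values[i]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        keep = set(gene_ids)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        missing = keep - {self.gene_ids[i] for i in idx}
        if missing:
            raise ValidationError(f"unknown gene ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in idx),
            self.sample_labels,
            self.values[idx],
            self.pseudocount,
            self.shrinkage,
            self.size_factors,
        )


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Only genes with positive counts in every sample enter the median (the
    geometric mean is zero otherwise).  If no gene qualifies, all-ones
    factors are returned with a warning.
    """
    if counts.n_genes == 0 or counts.n_samples == 0:
        raise ValidationError("cannot compute size factors of an empty matrix")
    c = counts.counts.astype(float)
    all_positive = np.all(c > 0, axis=1)
    if not all_positive.any():
        warnings.warn(
            "no gene has positive counts in every sample; "
            "falling back to all-ones size factors",
            stacklevel=2,
        )
        return SizeFactors(counts.sample_labels, np.ones(counts.n_samples))
    pos = c[all_positive]
    log_geomean = np.mean(np.log(pos), axis=1, keepdims=True)
    ratios = pos / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return SizeFactors(counts.sample_labels, factors)


def rlog_like_transform(
    counts: CountMatrix,
    factors: SizeFactors | None = None,
    pseudocount: float = 1.0,
    shrinkage: float = 0.0,
) -> ExpressionMatrix:
    """log2 of depth-normalized counts, shrunk toward the gene mean.

    Parameters
    ----------
    factors
        Size factors; computed from ``counts`` when omitted.
    pseudocount
        Added inside the log; must be > 0.  Default 1, so a zero count at
        unit depth maps to 0.
    shrinkage
        Convex weight s in [0, 1) on the gene's own mean; s = 0 is the
        plain transform, and each gene's (max - min) contracts by (1 - s).
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if not 0 <= shrinkage < 1:
        raise ValidationError("shrinkage must lie in [0, 1)")
    if factors is None:
        factors = compute_size_factors(counts)
    if tuple(factors.sample_labels) != tuple(counts.sample_labels):
        raise ValidationError("size factors do not match the count matrix samples")
    log_norm = np.log2(counts.counts / factors.factors[None, :] + pseudocount)
    gene_mean = log_norm.mean(axis=1, keepdims=True)
    values = (1.0 - shrinkage) * log_norm + shrinkage * gene_mean
    return ExpressionMatrix(
        counts.gene_ids,
        counts.sample_labels,
        values,
        pseudocount=pseudocount,
        shrinkage=shrinkage,
        size_factors=factors,
    )


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    """TSV with a provenance header line recording transform parameters."""
    factors = (
        ",".join(f"{f:.6g}" for f in expr.size_factors.factors)
        if expr.size_factors is not None
        else "NA"
    )
    with open(path, "w") as fh:
        fh.write(
            f"# pseudocount={expr.pseudocount:g} shrinkage={expr.shrinkage:g} "
            f"size_factors={factors}\n"
        )
        expr.to_frame().to_csv(fh, sep="\t", index_label="gene_id")
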