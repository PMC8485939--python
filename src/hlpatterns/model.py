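"""Model/Results facade over the full time-course pattern pipeline.

`TimeCoursePatternModel` holds a count matrix plus the analysis settings;
`fit()` runs the pipeline in the canonical order —

    min-read filter (raw counts)
      -> median-of-ratios size factors (kept genes)
      -> regularized-log-style transform
      -> fold-variation filter (log2 range)
      -> H/L classification and category table
      -> window analysis (interval change sets, sample clustering,
         maximal-change window)

— and returns a `TimeCoursePatternResults` carrying the accounting,
tables and window report, with `summary()`, a shrinkage/pseudocount
`sensitivity()` grid, and report writers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountMatrix, GeneSetCollection, read_count_matrix, write_gene_lists
from .normalize import (
    SizeFactors,
    ExpressionMatrix,
    compute_size_factors,
    rlog_like_transform,
    write_expression_matrix,
)
from .patterns import (
    CategoryTable,
    Thresholds,
    classify_matrix,
    filter_fold_variation,
    filter_min_reads,
    tabulate_categories,
)
from .windows import WindowReport, max_change_window
from .enrich import hypergeom_overrep

__all__ = ["TimeCoursePatternModel", "TimeCoursePatternResults"]


class TimeCoursePatternModel:
    """Time-course H/L expression-pattern analysis of one count matrix.

    Parameters
    ----------
    counts
        Genes x samples integer read counts, samples in time order.
    min_reads
        A gene is analyzed only if it reaches this many reads in at least
        one sample (default 5).
    fold
        Variation threshold; genes with log2 range >= log2(fold) across
        the time points are pattern-classified (default 2, i.e. twofold).
    pseudocount, shrinkage
        Transform parameters, see :func:`rlog_like_transform`.
    metric, linkage, center
        Sample-clustering settings for the window analysis.
    """

    def __init__(
        self,
        counts: CountMatrix,
        *,
        min_reads: int = 5,
        fold: float = 2.0,
        pseudocount: float = 1.0,
        shrinkage: float = 0.0,
        metric: str = "euclidean",
        linkage: str = "complete",
        center: bool = True,
    ):
        if counts.n_samples < 2:
            raise ValidationError("need at least two time-point samples")
        self.counts = counts
        self.thresholds = Thresholds(min_reads=min_reads, fold=fold)
        self.pseudocount = pseudocount
        self.shrinkage = shrinkage
        self.metric = metric
        self.linkage = linkage
        self.center = center

    @classmethod
    def from_tsv(cls, path, sample_order=None, **kwargs) -> "TimeCoursePatternModel":
        return cls(read_count_matrix(path, sample_order=sample_order), **kwargs)

    def fit(self) -> "TimeCoursePatternResults":
        kept_ids = filter_min_reads(self.counts, self.thresholds.min_reads)
        if not kept_ids:
            raise ValidationError("no gene passes the minimum-read filter")
        kept = self.counts.subset(kept_ids)
        factors = compute_size_factors(kept)
        expr = rlog_like_transform(
            kept, factors, pseudocount=self.pseudocount, shrinkage=self.shrinkage
        )
        survivors = filter_fold_variation(expr, self.thresholds.fold)
        codes = classify_matrix(expr, survivors) if survivors else {}
        degenerate = {g: c for g, c in codes.items() if c.degenerate}
        classified = {g: c for g, c in codes.items() if not c.degenerate}
        if degenerate:
            warnings.warn(
                f"{len(degenerate)} fold-variation survivors have degenerate "
                "all-H/all-L codes; reported separately",
                stacklevel=2,
            )
        table = tabulate_categories(classified)
        window = (
            max_change_window(
                expr,
                survivors,
                metric=self.metric,
                center=self.center,
                linkage=self.linkage,
                fold=self.thresholds.fold,
            )
            if survivors
            else None
        )
        return TimeCoursePatternResults(
            model=self,
            kept_ids=tuple(kept_ids),
            size_factors=factors,
            expression=expr,
            survivors=tuple(survivors),
            codes=classified,
            degenerate=degenerate,
            category_table=table,
            window=window,
        )


@dataclass(frozen=True)
class TimeCoursePatternResults:
    """Fitted pipeline output: accounting, categories, window report."""

    model: TimeCoursePatternModel
    kept_ids: tuple
    size_factors: SizeFactors
    expression: ExpressionMatrix
    survivors: tuple
    codes: dict
    degenerate: dict
    category_table: CategoryTable
    window: WindowReport | None

    # -- accounting ----------------------------------------------------

    @property
    def accounting(self) -> dict:
        """Stage-by-stage gene accounting; excluded + kept = total."""
        total = self.model.counts.n_genes
        kept = len(self.kept_ids)
        return {
            "total": total,
            "excluded_min_reads": total - kept,
            "kept": kept,
            "fold_survivors": len(self.survivors),
            "classified": len(self.codes),
            "degenerate": len(self.degenerate),
        }

    def top_categories(self, k: int = 2) -> list[tuple[str, int]]:
        return sorted(
            self.category_table.counts.items(), key=lambda kv: (-kv[1], kv[0])
        )[:k]

    # -- presentation --------------------------------------------------

    def summary(self) -> str:
        acc = self.accounting
        t = self.model.thresholds
        lines = [
            "Time-course H/L pattern analysis",
            "=" * 48,
            f"samples (time order):  {', '.join(self.model.counts.sample_labels)}",
            f"thresholds:            min_reads={t.min_reads}, fold={t.fold:g}",
            f"transform:             pseudocount={self.model.pseudocount:g}, "
            f"shrinkage={self.model.shrinkage:g}",
            f"size factors:          "
            + ", ".join(f"{f:.4f}" for f in self.size_factors.factors),
            "-" * 48,
            f"genes total:           {acc['total']:>8d}",
            f"  excluded (<{t.min_reads} reads in every sample): "
            f"{acc['excluded_min_reads']:d}",
            f"  kept:                {acc['kept']:>8d}",
            f"  >= {t.fold:g}-fold variation: {acc['fold_survivors']:>6d}",
        ]
        if acc["degenerate"]:
            lines.append(f"  degenerate codes:    {acc['degenerate']:>8d}")
        lines.append("-" * 48)
        lines.append("top categories:")
        for code, count in self.top_categories(4):
            lines.append(f"  {code}  {count:>6d}")
        if self.window is not None:
            a, b = self.window.max_window
            lines.append("-" * 48)
            lines.append(f"maximal-change window: {a} -> {b}")
            lines.append(
                "consecutive distances: "
                + ", ".join(
                    f"{x}->{y}: {d:.2f}"
                    for (x, y), d in self.window.consecutive_distances.items()
                )
            )
            cut = [
                "{" + ", ".join(sorted(c)) + "}" for c in self.window.two_cluster_cut
            ]
            lines.append(f"2-cluster cut:         {' vs '.join(cut)}")
            up, down = (
                self.window.up_sets[self.window.max_window],
                self.window.down_sets[self.window.max_window],
            )
            lines.append(
                f"changed >= {t.fold:g}-fold in window: "
                f"{len(up) + len(down)} ({len(up)} up + {len(down)} down)"
            )
        return "\n".join(lines)

    # -- diagnostics ---------------------------------------------------

    def sensitivity(
        self,
        shrinkages=(0.0, 0.1, 0.2),
        pseudocounts=(0.5, 1.0, 2.0),
        codes=("HHLL", "LLHH"),
    ) -> pd.DataFrame:
        """Survivor and category counts across a transform-parameter grid.

        The fold-variation survivor count (and hence every downstream
        count) depends on the transform; this grid documents how strongly.
        """
        rows = []
        for s in shrinkages:
            for pc in pseudocounts:
                refit = TimeCoursePatternModel(
                    self.model.counts,
                    min_reads=self.model.thresholds.min_reads,
                    fold=self.model.thresholds.fold,
                    pseudocount=pc,
                    shrinkage=s,
                    metric=self.model.metric,
                    linkage=self.model.linkage,
                    center=self.model.center,
                ).fit()
                row = {
                    "shrinkage": s,
                    "pseudocount": pc,
                    "fold_survivors": len(refit.survivors),
                }
                for code in codes:
                    if len(code) == refit.category_table.T:
                        row[code] = refit.category_table.counts.get(code, 0)
                if refit.window is not None:
                    row["max_window"] = "->".join(refit.window.max_window)
                rows.append(row)
        return pd.DataFrame(rows)

    def enrich(
        self, gene_set_collection: GeneSetCollection, query, universe=None
    ) -> pd.DataFrame:
        """ORA of a result gene set against a GMT collection.

        Universe defaults to the min-read-filtered gene list — the genes
        the pipeline could have detected.
        """
        if universe is None:
            universe = self.kept_ids
        return hypergeom_overrep(query, gene_set_collection, universe)

    # -- output --------------------------------------------------------

    def write_reports(self, outdir) -> list[str]:
        """Write the standard report bundle; returns the file names written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def emit(name):
            written.append(name)
            return outdir / name

        acc = self.accounting
        pd.DataFrame([acc]).T.rename(columns={0: "genes"}).to_csv(
            emit("accounting.tsv"), sep="\t", index_label="stage"
        )
        pd.DataFrame(
            sorted(self.category_table.counts.items()),
            columns=["code", "count"],
        ).to_csv(emit("category_table.tsv"), sep="\t", index=False)
        nonempty = {
            code: list(genes)
            for code, genes in self.category_table.members.items()
            if genes
        }
        if nonempty:
            write_gene_lists(nonempty, emit("category_gene_lists.tsv"))
        write_expression_matrix(self.expression, emit("expression.tsv"))
        if self.window is not None:
            w = self.window
            rows = []
            for iv in w.intervals:
                rows.append(
                    {
                        "interval": "->".join(iv),
                        "up": len(w.up_sets[iv]),
                        "down": len(w.down_sets[iv]),
                        "changed": len(w.up_sets[iv]) + len(w.down_sets[iv]),
                        "consecutive_distance": w.consecutive_distances[iv],
                        "is_max_window": iv == w.max_window,
                    }
                )
            pd.DataFrame(rows).to_csv(emit("window_report.tsv"), sep="\t", index=False)
            interval_lists = {}
            for iv in w.intervals:
                tag = "_to_".join(iv)
                if w.up_sets[iv]:
                    interval_lists[f"up_{tag}"] = sorted(w.up_sets[iv])
                if w.down_sets[iv]:
                    interval_lists[f"down_{tag}"] = sorted(w.down_sets[iv])
            if interval_lists:
                write_gene_lists(interval_lists, emit("interval_gene_lists.tsv"))
            with open(emit("dendrogram.nwk"), "w") as fh:
                fh.write(w.dendrogram.to_newick() + "\n")
        with open(emit("summary.txt"), "w") as fh:
            fh.write(self.summary() + "\n")
        return written

    def plot_heatmap(self, ax=None):  # pragma: no cover - plotting decoration
        """Heatmap of fold-survivor expression (gene-centered), samples ordered."""
        import matplotlib.pyplot as plt

        sub = self.expression.subset(self.survivors)
        values = sub.values - sub.values.mean(axis=1, keepdims=True)
        order = np.argsort([str(self.codes.get(g, "")) for g in sub.gene_ids])
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 8))
        ax.imshow(values[order], aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(sub.sample_labels)))
        ax.set_xticklabels(sub.sample_labels, rotation=90)
        ax.set_yticks([])
        ax.set_xlabel("sample")
        ax.set_ylabel(f"{len(sub.gene_ids)} genes (grouped by pattern)")
        return ax
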