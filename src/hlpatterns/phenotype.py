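"""Small-sample statistics for phenotype assays (colony counts, foci area).

The assays compare three replicates per group (control vs exposed) with a
two-sided two-sample t-test at significance level 0.05.  The pooled-
variance test is the default at these sample sizes; Welch's unequal-
variance variant is available behind a flag.  Degenerate inputs (both
groups constant) are reported explicitly rather than erroring, so batch
tables with saturated assays still produce a full comparison report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["TTestResult", "two_sample_ttest", "pairwise_ttests", "read_replicate_table"]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    significant: bool
    degenerate: bool = False


def _check_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"group {name!r} needs at least two replicates")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {name!r} contains non-finite values")
    return arr


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    equal_variance: bool = True,
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sided two-sample t-test (pooled by default, Welch optional).

    Degenerate zero-variance cases: two constant equal groups give t = 0,
    p = 1 with a warning (no evidence of difference, none possible); two
    constant unequal groups give the p -> 0 limit, flagged degenerate.
    """
    x = _check_group(a, "a")
    y = _check_group(b, "b")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            warnings.warn(
                "both groups constant and equal; t undefined, reporting p = 1",
                stacklevel=2,
            )
            return TTestResult(0.0, 1.0, df, False, degenerate=True)
        sign = np.sign(x.mean() - y.mean())
        return TTestResult(float(sign * np.inf), 0.0, df, True, degenerate=True)
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), p, df, p < alpha)


def pairwise_ttests(
    groups: Mapping[str, Sequence[float]],
    equal_variance: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise comparisons between named replicate groups."""
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups to compare")
    rows = []
    for a, b in combinations(names, 2):
        r = two_sample_ttest(groups[a], groups[b], equal_variance, alpha)
        rows.append((a, b, r.statistic, r.df, r.pvalue, r.significant, r.degenerate))
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "t", "df", "p", "significant", "degenerate"],
    )


def read_replicate_table(path) -> dict[str, list[float]]:
    """Read a TSV of (group, replicate, value) into per-group value lists."""
    frame = pd.read_csv(path, sep="\t")
    required = {"group", "value"}
    if not required <= set(frame.columns):
        raise ValidationError(
            f"{path}: replicate table needs columns {sorted(required)}"
        )
    groups: dict[str, list[float]] = {}
    for _, row in frame.iterrows():
        groups.setdefault(str(row["group"]), []).append(float(row["value"]))
    return groups
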