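"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of n genes drawn from a universe of N tested genes, the
overlap k with an annotated set of size K (after intersecting the set with
the universe) is scored with the upper hypergeometric tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

and Benjamini-Hochberg q-values are attached across all sets tested
together.  The universe defaults, at the pipeline level, to the minimum-
read-filtered gene list — the genes that could have been detected are the
sampling frame.  No annotation databases are bundled; users supply GMT
files, which keeps database versioning out of the analysis.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection

__all__ = ["hypergeom_overrep", "bh_fdr"]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_overrep(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, within ``universe``.

    Returns a DataFrame sorted by p with columns
    ``set, k, K, n, N, p, q`` (overlap, set size in universe, query size,
    universe size, hypergeometric tail p, BH q).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        raise ValidationError(
            f"query genes outside the universe: {sorted(outside)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets:
        members_in = members & universe
        K = len(members_in)
        k = len(query & members_in)
        # survival function at k-1 gives P(X >= k); K = 0 or k = 0 -> p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    result["q"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
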