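"""Pearson correlation per criteria pair, juxtaposed with ICrA degrees.

Correlation analysis measures linear association of the raw evaluations;
the degree of agreement mu measures concordance of their orderings.
Reporting them side by side (one row per criteria pair per evaluation
block) documents where the two views agree and where ICrA detects
relations that the product-moment coefficient misses.  No combined score
is produced.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import ICrAResult
from .index_matrix import IndexMatrix

__all__ = ["pearson", "juxtapose"]


class ConstantInputError(ValueError):
    """Pearson correlation is undefined when a column is constant."""


def pearson(xs: np.ndarray, ys: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient of two columns.

    Requires equal lengths >= 3 and non-constant inputs; raises
    :class:`ConstantInputError` otherwise instead of returning NaN.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if xs.ndim != 1 or xs.shape[0] < 3:
        raise ValueError("need one-dimensional columns of length >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ConstantInputError("correlation undefined for a constant column")
    r = stats.pearsonr(xs, ys).statistic
    return float(r)


def juxtapose(
    icra_by_block: Mapping[str, ICrAResult],
    matrices_by_block: Mapping[str, IndexMatrix],
) -> pd.DataFrame:
    """One row per (criteria pair, block) with both mu and r.

    Columns: pair, block, mu, nu, r; sorted by pair then block.  The ICrA
    result and the index matrix of each block must carry identical criteria
    labels.
    """
    if set(icra_by_block) != set(matrices_by_block):
        raise ValueError("block labels differ between ICrA results and matrices")
    rows = []
    for block in icra_by_block:
        res = icra_by_block[block]
        im = matrices_by_block[block]
        if res.criteria_labels != im.criteria_labels:
            raise ValueError(f"criteria labels differ in block {block!r}")
        for k, l in combinations(res.criteria_labels, 2):
            p = res.pair(k, l)
            r = pearson(im.column(k), im.column(l))
            rows.append(
                {"pair": f"{k}-{l}", "block": block, "mu": p.mu, "nu": p.nu, "r": r}
            )
    df = pd.DataFrame(rows, columns=["pair", "block", "mu", "nu", "r"])
    return df.sort_values(["pair", "block"], kind="stable").reset_index(drop=True)
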