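"""Intuitionistic fuzzy counters and degree-of-agreement pairs.

For each unordered pair of criteria (C_k, C_l) every unordered pair of
objects (O_i, O_j) is examined under the relation R = ">" on the raw
evaluations.  The concordance counter S^mu counts object pairs where R (or
its dual R-bar, "<") holds simultaneously in both criteria; the discordance
counter S^nu counts pairs where R holds in one criterion and R-bar in the
other.  Normalising by the number of comparisons m(m-1)/2 yields the
intuitionistic fuzzy pair

    mu = 2 S^mu / (m(m-1)),    nu = 2 S^nu / (m(m-1)),

the degrees of agreement and disagreement, with uncertainty
pi = 1 - mu - nu absorbing ties.  Because only the ordering of evaluations
matters, lower-is-better criteria (docking scores) need no sign handling:
concordance is direction-agnostic within a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd

from .index_matrix import IndexMatrix

__all__ = [
    "CounterTriple",
    "IFPair",
    "ICrAResult",
    "pairwise_counters",
    "degrees",
    "run_icra",
]

TieMode = Literal["unbiased", "mu_biased"]


@dataclass(frozen=True)
class CounterTriple:
    """Concordant / discordant / tied comparison counts for one criteria pair."""

    s_mu: int
    s_nu: int
    s_tie: int

    def __post_init__(self) -> None:
        if min(self.s_mu, self.s_nu, self.s_tie) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.s_mu + self.s_nu + self.s_tie


@dataclass(frozen=True)
class IFPair:
    """Intuitionistic fuzzy evaluation <mu, nu> with uncertainty pi = 1 - mu - nu."""

    mu: float
    nu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.nu <= 1.0):
            raise ValueError(f"mu and nu must lie in [0, 1], got <{self.mu}, {self.nu}>")
        if self.mu + self.nu > 1.0 + 1e-12:
            raise ValueError(f"mu + nu must not exceed 1, got {self.mu + self.nu}")

    @property
    def pi(self) -> float:
        return 1.0 - self.mu - self.nu


@dataclass(frozen=True)
class ICrAResult:
    """Symmetric criteria x criteria matrix of IF pairs; diagonal <1, 0>."""

    criteria_labels: tuple[str, ...]
    mu: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.criteria_labels)
        mu = np.asarray(self.mu, dtype=float)
        nu = np.asarray(self.nu, dtype=float)
        if mu.shape != (n, n) or nu.shape != (n, n):
            raise ValueError("mu/nu must be n x n for n criteria")
        object.__setattr__(self, "criteria_labels", tuple(self.criteria_labels))
        for a in (mu, nu):
            a.setflags(write=False)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "nu", nu)

    def pair(self, k: str, l: str) -> IFPair:
        i = self.criteria_labels.index(k)
        j = self.criteria_labels.index(l)
        return IFPair(float(self.mu[i, j]), float(self.nu[i, j]))

    def iter_pairs(self):
        """Yield (label_k, label_l, IFPair) over the n(n-1)/2 unordered pairs."""
        n = len(self.criteria_labels)
        for i, j in combinations(range(n), 2):
            yield (
                self.criteria_labels[i],
                self.criteria_labels[j],
                IFPair(float(self.mu[i, j]), float(self.nu[i, j])),
            )

    def mu_frame(self) -> pd.DataFrame:
        labels = list(self.criteria_labels)
        return pd.DataFrame(np.array(self.mu), index=labels, columns=labels)

    def nu_frame(self) -> pd.DataFrame:
        labels = list(self.criteria_labels)
        return pd.DataFrame(np.array(self.nu), index=labels, columns=labels)

    def long_frame(self) -> pd.DataFrame:
        """Long-format table with one row per unordered criteria pair."""
        rows = [
            {"pair": f"{k}-{l}", "mu": p.mu, "nu": p.nu, "pi": p.pi}
            for k, l, p in self.iter_pairs()
        ]
        return pd.DataFrame(rows, columns=["pair", "mu", "nu", "pi"])


def _validate_columns(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or ys.ndim != 1:
        raise ValueError("criterion columns must be one-dimensional")
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape[0]} vs {ys.shape[0]}")
    if xs.shape[0] < 2:
        raise ValueError("need at least 2 objects")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("evaluations must be finite")
    return xs, ys


def pairwise_counters(
    xs: np.ndarray,
    ys: np.ndarray,
    tie_mode: TieMode = "unbiased",
    epsilon: float = 0.0,
) -> CounterTriple:
    """Count concordant, discordant and tied object pairs for two criteria.

    A pair of objects ties in a criterion when its two evaluations differ by
    at most ``epsilon``.  With ``tie_mode="unbiased"`` any tie routes the
    comparison to ``s_tie`` (absorbed by the uncertainty pi); with
    ``"mu_biased"`` a simultaneous tie in both criteria counts as agreement.
    """
    xs, ys = _validate_columns(xs, ys)
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if tie_mode not in ("unbiased", "mu_biased"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")

    iu, ju = np.triu_indices(xs.shape[0], k=1)
    dx = xs[iu] - xs[ju]
    dy = ys[iu] - ys[ju]
    tie_x = np.abs(dx) <= epsilon
    tie_y = np.abs(dy) <= epsilon
    any_tie = tie_x | tie_y
    same = (dx > 0) == (dy > 0)

    s_mu = int(np.count_nonzero(~any_tie & same))
    s_nu = int(np.count_nonzero(~any_tie & ~same))
    if tie_mode == "mu_biased":
        s_mu += int(np.count_nonzero(tie_x & tie_y))
        s_tie = int(np.count_nonzero(any_tie & ~(tie_x & tie_y)))
    else:
        s_tie = int(np.count_nonzero(any_tie))
    return CounterTriple(s_mu=s_mu, s_nu=s_nu, s_tie=s_tie)


def degrees(counters: CounterTriple, m: int) -> IFPair:
    """Normalise counters into the degree-of-agreement/disagreement pair."""
    if m < 2:
        raise ValueError("need at least 2 objects")
    total = m * (m - 1) // 2
    if counters.total != total:
        raise ValueError(
            f"counters sum to {counters.total}, expected m(m-1)/2 = {total}"
        )
    return IFPair(mu=counters.s_mu / total, nu=counters.s_nu / total)


def run_icra(
    im: IndexMatrix,
    tie_mode: TieMode = "unbiased",
    epsilon: float = 0.0,
) -> ICrAResult:
    """Evaluate all n(n-1)/2 criteria pairs of an index matrix.

    Returns the symmetric output matrix of intuitionistic fuzzy pairs with
    <1, 0> on the diagonal.
    """
    n = im.n
    mu = np.eye(n)
    nu = np.zeros((n, n))
    ev = np.asarray(im.evaluations)
    for k, l in combinations(range(n), 2):
        c = pairwise_counters(ev[:, k], ev[:, l], tie_mode=tie_mode, epsilon=epsilon)
        p = degrees(c, im.m)
        mu[k, l] = mu[l, k] = p.mu
        nu[k, l] = nu[l, k] = p.nu
    return ICrAResult(criteria_labels=im.criteria_labels, mu=mu, nu=nu)
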