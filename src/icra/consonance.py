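"""Consonance/dissonance classification and threshold sweeps.

An intuitionistic fuzzy pair <mu, nu> is labelled against thresholds
alpha > beta.  Two scales are supported:

* ``quarters`` — the classical three-way rule (default thresholds
  alpha = 0.75, beta = 0.25): positive consonance when mu clears alpha and
  nu stays below beta, negative consonance in the mirrored case, dissonance
  otherwise.
* ``thirds`` — a symmetric four-way rule built around alpha ~ 2/3,
  beta ~ 1/3 that splits the former dissonance region of the unit triangle
  in two: pairs with mu + nu < alpha (large uncertainty pi) are labelled
  ``uncertainty`` rather than dissonance.

The ``boundary`` convention decides whether mu equal to alpha qualifies.
The default is inclusive (mu >= alpha and nu <= beta qualify), the
convention under which two-decimal published agreement tables reproduce
their summary counts; ``strict`` applies mu > alpha and nu < beta.

Sweeps vary alpha while keeping alpha + beta = 1 and summarise, per
evaluation block and per criteria pair, how many classifications land in
positive consonance — the threshold-sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .core import IFPair

__all__ = [
    "ThresholdScheme",
    "RelationLabel",
    "SweepSummary",
    "classify",
    "count_positive_per_block",
    "count_positive_per_pair",
    "threshold_sweep",
    "triangle_coordinates",
    "DEFAULT_SWEEP_ALPHAS",
    "LABEL_COLORS",
]

RelationLabel = Literal[
    "positive_consonance", "negative_consonance", "dissonance", "uncertainty"
]

#: Display colors matching the twin-table convention of ICrA software:
#: green = positive consonance, red = negative consonance, magenta = dissonance.
LABEL_COLORS: dict[str, str] = {
    "positive_consonance": "green",
    "negative_consonance": "red",
    "dissonance": "magenta",
    "uncertainty": "gray",
}

#: The five alpha values of the published threshold-impact study (beta = 1 - alpha).
DEFAULT_SWEEP_ALPHAS: tuple[float, ...] = (0.75, 0.70, 0.67, 0.65, 0.60)

MuTable = Mapping[str, Mapping[str, IFPair]]  # block label -> pair label -> <mu, nu>


@dataclass(frozen=True)
class ThresholdScheme:
    """Classification thresholds (alpha, beta) with scale and boundary convention."""

    alpha: float
    beta: float
    scale: Literal["quarters", "thirds"] = "quarters"
    boundary: Literal["strict", "inclusive"] = "inclusive"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.alpha <= self.beta:
            raise ValueError(f"alpha ({self.alpha}) must exceed beta ({self.beta})")
        if self.scale not in ("quarters", "thirds"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.boundary not in ("strict", "inclusive"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    def label(self) -> str:
        return f"{self.alpha:g}/{self.beta:g}"


def classify(pair: IFPair, scheme: ThresholdScheme) -> str:
    """Classify an IF pair; total and mutually exclusive over the label set."""
    inclusive = scheme.boundary == "inclusive"
    a, b = scheme.alpha, scheme.beta
    if inclusive:
        positive = pair.mu >= a and pair.nu <= b
        negative = pair.mu <= b and pair.nu >= a
    else:
        positive = pair.mu > a and pair.nu < b
        negative = pair.mu < b and pair.nu > a
    if positive:
        return "positive_consonance"
    if negative:
        return "negative_consonance"
    if scheme.scale == "thirds" and pair.mu + pair.nu < a:
        # large-uncertainty corner of the triangle: neither agreement nor
        # disagreement dominates and pi > 1 - alpha
        return "uncertainty"
    return "dissonance"


def triangle_coordinates(pair: IFPair) -> tuple[float, float]:
    """Coordinates (mu, nu) in the interpretative intuitionistic triangle.

    The triangle has vertices (0,0) full uncertainty, (1,0) perfect
    agreement, (0,1) perfect disagreement; valid pairs satisfy mu + nu <= 1.
    """
    return (pair.mu, pair.nu)


def _check_pair_sets(mu_table: MuTable) -> list[str]:
    blocks = list(mu_table)
    if not blocks:
        raise ValueError("mu_table has no blocks")
    ref = list(mu_table[blocks[0]])
    for b in blocks[1:]:
        if set(mu_table[b]) != set(ref):
            raise ValueError(
                f"block {b!r} has a different pair set than block {blocks[0]!r}"
            )
    return ref


def count_positive_per_block(
    mu_table: MuTable, scheme: ThresholdScheme
) -> dict[str, int]:
    """Number of criteria pairs in positive consonance within each block."""
    _check_pair_sets(mu_table)
    return {
        block: sum(
            classify(p, scheme) == "positive_consonance" for p in pairs.values()
        )
        for block, pairs in mu_table.items()
    }


def count_positive_per_pair(
    mu_table: MuTable, schemes: Iterable[ThresholdScheme]
) -> dict[str, dict[str, int]]:
    """Per criteria pair, per scheme: number of blocks in positive consonance."""
    pair_labels = _check_pair_sets(mu_table)
    schemes = list(schemes)
    out: dict[str, dict[str, int]] = {}
    for pair_label in pair_labels:
        out[pair_label] = {
            s.label(): sum(
                classify(mu_table[b][pair_label], s) == "positive_consonance"
                for b in mu_table
            )
            for s in schemes
        }
    return out


@dataclass(frozen=True)
class SweepSummary:
    """Both positive-consonance summaries of a threshold sweep."""

    per_block_counts: dict[str, dict[str, int]]  # scheme label -> block -> count
    per_pair_counts: dict[str, dict[str, int]]  # pair label -> scheme label -> count

    def per_block_frame(self) -> pd.DataFrame:
        """Rows = alpha/beta settings, columns = blocks."""
        df = pd.DataFrame(self.per_block_counts).T
        df.index.name = "alpha/beta"
        return df

    def per_pair_frame(self) -> pd.DataFrame:
        """Rows = criteria pairs, columns = alpha/beta settings."""
        df = pd.DataFrame(self.per_pair_counts).T
        df.index.name = "pair"
        return df


def threshold_sweep(
    mu_table: MuTable,
    alphas: Iterable[float] = DEFAULT_SWEEP_ALPHAS,
    scale: Literal["quarters", "thirds"] = "quarters",
    boundary: Literal["strict", "inclusive"] = "inclusive",
) -> SweepSummary:
    """Sweep alpha over ``alphas`` with beta = 1 - alpha and summarise.

    Requires alpha > 0.5 so that alpha > beta holds.  Per-block positive
    counts are non-increasing as alpha grows.
    """
    alphas = list(alphas)
    for a in alphas:
        if not (0.5 < a <= 1.0):
            raise ValueError(
                f"alpha must be in (0.5, 1] when beta = 1 - alpha, got {a}"
            )
    schemes = [
        ThresholdScheme(alpha=a, beta=round(1.0 - a, 12), scale=scale, boundary=boundary)
        for a in alphas
    ]
    per_block = {
        s.label(): count_positive_per_block(mu_table, s) for s in schemes
    }
    per_pair = count_positive_per_pair(mu_table, schemes)
    return SweepSummary(per_block_counts=per_block, per_pair_counts=per_pair)
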