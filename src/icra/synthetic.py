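"""Synthetic docking-output generator and packaged agreement-table fixture.

Raw docking runs (placement, scoring, pose RMSD) are expensive and tied to
proprietary software, so this module provides two stand-ins:

* a Gaussian-copula generator of docking-output-like index matrices with
  controllable pairwise concordance between criteria.  Latent vectors are
  drawn from a zero-mean multivariate normal with correlation ``target_rho``
  and each criterion's column is pushed through a strictly increasing,
  block-appropriate marginal transform (negative score-like values for
  score blocks, non-negative RMSD-like values for RMSD blocks).  Because
  the transforms are strictly monotone and the marginals continuous, the
  expected degree of agreement obeys the arcsine law

      mu = 1/2 + arcsin(rho) / pi,

  which gives an analytic handle for calibration and testing;

* the published table of degrees of agreement mu for the five MOE scoring
  functions and the experimental affinity column over four docking outputs
  (15 criteria pairs x 4 blocks), packaged as a fixture for the
  threshold-sweep analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .core import IFPair
from .index_matrix import IndexMatrix

__all__ = [
    "SCORING_FUNCTIONS",
    "EXPERIMENTAL_LABEL",
    "BLOCKS",
    "PAIR_LABELS",
    "SyntheticSpec",
    "generate_block",
    "rho_for_target_mu",
    "mu_for_rho",
    "nearest_correlation",
    "rho_matrix_from_mu_targets",
    "table1_fixture",
    "table1_mu_table",
    "simulate_table1_mu",
]

SCORING_FUNCTIONS: tuple[str, ...] = (
    "Affinity dG",
    "Alpha HB",
    "ASE",
    "GBVI/WSA dG",
    "London dG",
)
EXPERIMENTAL_LABEL = "-logK"

#: The four docking outputs: best docking score, lowest pose RMSD, RMSD of
#: the best-scored pose, and score of the lowest-RMSD pose.
BLOCKS: tuple[str, ...] = ("BestDS", "BestRMSD", "RMSD_BestDS", "DS_BestRMSD")

BlockKind = Literal["best_ds", "best_rmsd", "rmsd_best_ds", "ds_best_rmsd"]
_SCORE_KINDS = ("best_ds", "ds_best_rmsd")

# Degrees of agreement mu per criteria pair, one value per block in the
# order of BLOCKS.  Two-decimal values as published.
_TABLE1: dict[str, tuple[float, float, float, float]] = {
    "Affinity dG-Alpha HB": (0.60, 0.81, 0.67, 0.59),
    "Affinity dG-ASE": (0.62, 0.77, 0.68, 0.57),
    "Affinity dG-GBVI/WSA dG": (0.55, 0.83, 0.67, 0.61),
    "Affinity dG-London dG": (0.56, 0.78, 0.63, 0.56),
    "Alpha HB-ASE": (0.66, 0.79, 0.64, 0.62),
    "Alpha HB-GBVI/WSA dG": (0.47, 0.76, 0.69, 0.45),
    "Alpha HB-London dG": (0.72, 0.84, 0.68, 0.70),
    "ASE-GBVI/WSA dG": (0.44, 0.73, 0.66, 0.36),
    "ASE-London dG": (0.62, 0.77, 0.65, 0.60),
    "GBVI/WSA dG-London dG": (0.48, 0.73, 0.64, 0.46),
    "Affinity dG--logK": (0.45, 0.57, 0.50, 0.53),
    "Alpha HB--logK": (0.40, 0.53, 0.44, 0.49),
    "ASE--logK": (0.35, 0.56, 0.37, 0.57),
    "GBVI/WSA dG--logK": (0.58, 0.56, 0.60, 0.55),
    "London dG--logK": (0.45, 0.53, 0.45, 0.48),
}

PAIR_LABELS: tuple[str, ...] = tuple(_TABLE1)


def table1_fixture() -> dict[str, dict[str, float]]:
    """Published degrees of agreement, keyed block -> pair label -> mu."""
    return {
        block: {pair: vals[i] for pair, vals in _TABLE1.items()}
        for i, block in enumerate(BLOCKS)
    }


def table1_mu_table() -> dict[str, dict[str, IFPair]]:
    """Fixture as IF pairs with nu = 1 - mu.

    Only mu is published; taking nu = 1 - mu (zero uncertainty) is the
    worst case consistent with mu + nu <= 1 and is exact for any
    classification with alpha + beta = 1.
    """
    return {
        block: {pair: IFPair(mu, round(1.0 - mu, 12)) for pair, mu in pairs.items()}
        for block, pairs in table1_fixture().items()
    }


def mu_for_rho(rho: float) -> float:
    """Expected degree of agreement of a Gaussian-copula pair: 1/2 + arcsin(rho)/pi."""
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    return 0.5 + math.asin(rho) / math.pi


def rho_for_target_mu(mu_target: float) -> float:
    """Latent correlation achieving an expected agreement ``mu_target``.

    Inverts mu = 1/2 + arcsin(rho)/pi, i.e. rho = sin(pi (mu - 1/2)).
    The open interval (0, 1) only: for mu of exactly 0 or 1 use an exact
    anti-/comonotone construction (rho = +-1 in ``target_rho``) instead.
    """
    if not (0.0 < mu_target < 1.0):
        raise ValueError(
            f"mu_target must be in (0, 1), got {mu_target}; "
            "use rho = +-1 directly for exact co-/antimonotone columns"
        )
    return math.sin(math.pi * (mu_target - 0.5))


def nearest_correlation(a: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Nearest correlation matrix by alternating projections (Higham 2002)."""
    y = np.asarray(a, dtype=float).copy()
    ds = np.zeros_like(y)
    for _ in range(n_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2)
        x = (v * np.clip(w, 0, None)) @ v.T
        ds = x - r
        y = x.copy()
        np.fill_diagonal(y, 1.0)
    w = np.linalg.eigh((y + y.T) / 2)[0]
    if w.min() < -1e-8:
        raise ValueError("nearest-correlation projection failed to converge")
    return (y + y.T) / 2


def rho_matrix_from_mu_targets(
    mu_targets: Mapping[tuple[str, str], float],
    labels: tuple[str, ...],
    project: bool = True,
) -> np.ndarray:
    """Assemble a full target_rho from pairwise agreement targets.

    Missing pairs default to rho = 0.  A jointly infeasible set of pairwise
    targets yields an indefinite matrix; with ``project=True`` it is
    replaced by its nearest correlation matrix (achieved agreements then
    deviate slightly from the requested ones).
    """
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    rho = np.eye(n)
    for (k, l), mu in mu_targets.items():
        i, j = idx[k], idx[l]
        rho[i, j] = rho[j, i] = rho_for_target_mu(mu)
    w = np.linalg.eigh(rho)[0]
    if w.min() < -1e-10:
        if not project:
            raise ValueError(
                f"target_rho is not positive semi-definite (min eigenvalue {w.min():.3e})"
            )
        rho = nearest_correlation(rho)
    return rho


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic docking-output block.

    Defaults mirror the benchmark layout the generator emulates: 195
    protein-ligand complexes (objects) evaluated by five scoring functions
    plus one experimental -logKd/-logKi column.
    """

    m: int = 195
    criteria_labels: tuple[str, ...] = SCORING_FUNCTIONS + (EXPERIMENTAL_LABEL,)
    target_rho: np.ndarray | None = None
    block_kind: BlockKind = "best_ds"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.block_kind not in ("best_ds", "best_rmsd", "rmsd_best_ds", "ds_best_rmsd"):
            raise ValueError(f"unknown block_kind {self.block_kind!r}")
        n = len(self.criteria_labels)
        if self.target_rho is None:
            object.__setattr__(self, "target_rho", np.eye(n))
        rho = np.asarray(self.target_rho, dtype=float)
        if rho.shape != (n, n):
            raise ValueError(f"target_rho must be {n}x{n}, got {rho.shape}")
        if not np.allclose(rho, rho.T):
            raise ValueError("target_rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("target_rho must have unit diagonal")
        w = np.linalg.eigh(rho)[0]
        if w.min() < -1e-10:
            raise ValueError(
                f"target_rho is not positive semi-definite: eigenvalue {w.min():.6e} < 0"
            )
        rho.setflags(write=False)
        object.__setattr__(self, "target_rho", rho)
        object.__setattr__(self, "criteria_labels", tuple(self.criteria_labels))


def _marginal(z: np.ndarray, label: str, block_kind: BlockKind) -> np.ndarray:
    """Strictly increasing marginal transform for one criterion column."""
    if label == EXPERIMENTAL_LABEL:
        # -logKd/-logKi affinities, typically ~2-11
        return 6.0 + 1.5 * z
    if block_kind in _SCORE_KINDS:
        # docking scores: negative, lower = better binding
        return -15.0 + 3.0 * z
    # pose RMSD in angstroms: non-negative, log-normal-like
    return 2.0 * np.exp(0.6 * z)


def generate_block(spec: SyntheticSpec) -> IndexMatrix:
    """Draw one synthetic docking-output block.

    Latent rows ~ N(0, target_rho); each column then maps through a strictly
    increasing transform, so pairwise concordance between criteria is that
    of the latent Gaussian (arcsine law).  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    rho = np.asarray(spec.target_rho)
    n = rho.shape[0]
    w, v = np.linalg.eigh(rho)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((spec.m, n)) @ factor.T
    # comonotone/antimonotone pairs must be exact, not up to rounding
    for i in range(n):
        for j in range(i + 1, n):
            if rho[i, j] == 1.0:
                z[:, j] = z[:, i]
            elif rho[i, j] == -1.0:
                z[:, j] = -z[:, i]
    cols = [
        _marginal(z[:, k], lab, spec.block_kind)
        for k, lab in enumerate(spec.criteria_labels)
    ]
    return IndexMatrix(
        object_labels=tuple(f"L{i + 1:03d}" for i in range(spec.m)),
        criteria_labels=spec.criteria_labels,
        evaluations=np.column_stack(cols),
    )


_KIND_FOR_BLOCK: dict[str, BlockKind] = {
    "BestDS": "best_ds",
    "BestRMSD": "best_rmsd",
    "RMSD_BestDS": "rmsd_best_ds",
    "DS_BestRMSD": "ds_best_rmsd",
}


def simulate_table1_mu(
    seed: int, m: int = 195
) -> dict[str, dict[str, float]]:
    """Re-measure the published agreement profile from synthetic data.

    For every (criteria pair, block) cell, draws an independent
    two-criterion block at the latent correlation calibrated for the
    published mu (pairwise construction, so every target is individually
    feasible) and measures the achieved degree of agreement.  Returns the
    same block -> pair -> mu mapping shape as :func:`table1_fixture`.
    """
    from .core import degrees, pairwise_counters  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    for block, pairs in table1_fixture().items():
        kind = _KIND_FOR_BLOCK[block]
        achieved: dict[str, float] = {}
        for pair_label, mu_target in pairs.items():
            rho = rho_for_target_mu(mu_target)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec(
                m=m,
                criteria_labels=("C1", "C2"),
                target_rho=np.array([[1.0, rho], [rho, 1.0]]),
                block_kind=kind,
                seed=sub_seed,
            )
            im = generate_block(spec)
            c = pairwise_counters(im.evaluations[:, 0], im.evaluations[:, 1])
            achieved[pair_label] = degrees(c, m).mu
        out[block] = achieved
    return out
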