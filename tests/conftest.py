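"""Shared fixtures and the independent brute-force concordance oracle."""

from __future__ import annotations

import numpy as np
import pytest

from icra import IndexMatrix


def brute_counters(xs, ys, tie_mode="unbiased", epsilon=0.0):
    """Pure-Python double loop over object pairs, written independently of
    the library's vectorised counter; returns (s_mu, s_nu, s_tie)."""
    m = len(xs)
    s_mu = s_nu = s_tie = 0
    for i in range(m):
        for j in range(i + 1, m):
            tie_x = abs(xs[i] - xs[j]) <= epsilon
            tie_y = abs(ys[i] - ys[j]) <= epsilon
            if tie_x or tie_y:
                if tie_mode == "mu_biased" and tie_x and tie_y:
                    s_mu += 1
                else:
                    s_tie += 1
            else:
                if (xs[i] > xs[j]) == (ys[i] > ys[j]):
                    s_mu += 1
                else:
                    s_nu += 1
    return s_mu, s_nu, s_tie


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture
def toy_matrix():
    """4 objects x 3 criteria with a mix of agreement and ties."""
    return IndexMatrix(
        object_labels=("o1", "o2", "o3", "o4"),
        criteria_labels=("A", "B", "C"),
        evaluations=np.array(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 2.0], [2.0, 3.0, 1.0], [3.0, 3.0, 4.0]]
        ),
    )


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text("ligand,S1,S2\nL1,1.5,-2.0\nL2,2.5,-1.0\nL3,0.5,-3.0\n")
    return path
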