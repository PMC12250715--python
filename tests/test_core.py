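import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icra import (
    CounterTriple,
    ICrAResult,
    IFPair,
    IndexMatrix,
    degrees,
    pairwise_counters,
    run_icra,
)
from conftest import brute_counters


class TestPairwiseCounters:
    @pytest.mark.parametrize(
        "xs, ys, mode, expected",
        [
            # identical rankings: every pair concordant
            ([1, 2, 3], [1, 2, 3], "unbiased", (3, 0, 0)),
            # reversed rankings: every pair discordant
            ([1, 2, 3], [3, 2, 1], "unbiased", (0, 3, 0)),
            # hand-enumerated 6 object pairs with one tie in each column
            ([1, 2, 2, 3], [2, 1, 3, 3], "unbiased", (3, 1, 2)),
            # mu-biased counts the double tie into s_mu
            ([1, 2, 2, 3], [2, 2, 2, 3], "mu_biased", (4, 0, 2)),
        ],
    )
    def test_counts_match_hand_enumeration(self, xs, ys, mode, expected):
        c = pairwise_counters(np.array(xs, float), np.array(ys, float), tie_mode=mode)
        assert (c.s_mu, c.s_nu, c.s_tie) == expected

    def test_epsilon_widens_ties(self):
        xs = np.array([1.0, 1.004, 2.0])
        ys = np.array([1.0, 2.0, 3.0])
        exact = pairwise_counters(xs, ys)
        fuzzy = pairwise_counters(xs, ys, epsilon=0.01)
        assert (exact.s_mu, exact.s_tie) == (3, 0)
        assert (fuzzy.s_mu, fuzzy.s_tie) == (2, 1)

    def test_rejects_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_counters(np.ones(3), np.ones(4))
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_counters(np.ones(1), np.ones(1))

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=2, max_size=30
        ),
        mode=st.sampled_from(["unbiased", "mu_biased"]),
    )
    @settings(deadline=None, max_examples=150)
    def test_matches_brute_force_and_conserves_total(self, data, mode):
        xs = np.array([float(a) for a, _ in data])
        ys = np.array([float(b) for _, b in data])
        c = pairwise_counters(xs, ys, tie_mode=mode)
        assert (c.s_mu, c.s_nu, c.s_tie) == brute_counters(xs, ys, tie_mode=mode)
        m = len(xs)
        assert c.total == m * (m - 1) // 2


class TestDegrees:
    def test_perfect_agreement(self):
        assert degrees(CounterTriple(3, 0, 0), 3) == IFPair(1.0, 0.0)

    def test_derived_example_with_ties(self):
        p = degrees(CounterTriple(3, 1, 2), 4)
        assert p.mu == 0.5
        assert p.nu == pytest.approx(1 / 6, abs=1e-15)
        assert p.pi == pytest.approx(1 / 3, abs=1e-15)

    def test_constant_columns_give_pure_uncertainty(self):
        m = 5
        p = degrees(CounterTriple(0, 0, m * (m - 1) // 2), m)
        assert (p.mu, p.nu, p.pi) == (0.0, 0.0, 1.0)

    def test_rejects_inconsistent_counters(self):
        with pytest.raises(ValueError, match="expected"):
            degrees(CounterTriple(1, 1, 1), 4)


class TestIFPair:
    def test_rejects_mu_plus_nu_above_one(self):
        with pytest.raises(ValueError):
            IFPair(0.7, 0.6)

    def test_pi_complements_mu_and_nu(self):
        p = IFPair(0.3, 0.45)
        assert p.pi == pytest.approx(0.25, abs=1e-12)


class TestRunICrA:
    def test_identical_columns_give_full_agreement(self):
        im = IndexMatrix(
            ("a", "b", "c"), ("X", "Y"), np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        )
        res = run_icra(im)
        assert res.pair("X", "Y") == IFPair(1.0, 0.0)

    def test_result_invariants(self, rng):
        im = IndexMatrix(
            tuple(f"o{i}" for i in range(10)),
            ("A", "B", "C", "D"),
            rng.standard_normal((10, 4)),
        )
        res = run_icra(im)
        np.testing.assert_array_equal(np.diag(res.mu), 1.0)
        np.testing.assert_array_equal(np.diag(res.nu), 0.0)
        np.testing.assert_array_equal(res.mu, res.mu.T)
        np.testing.assert_array_equal(res.nu, res.nu.T)
        assert (res.mu + res.nu <= 1.0 + 1e-12).all()

    def test_matches_independent_recount(self, rng):
        ev = rng.integers(0, 6, size=(10, 4)).astype(float)  # forces ties
        im = IndexMatrix(
            tuple(f"o{i}" for i in range(10)), ("A", "B", "C", "D"), ev
        )
        res = run_icra(im)
        m = im.m
        for k in range(4):
            for l in range(k + 1, 4):
                s_mu, s_nu, _ = brute_counters(ev[:, k], ev[:, l])
                assert res.mu[k, l] == pytest.approx(2 * s_mu / (m * (m - 1)), abs=0)
                assert res.nu[k, l] == pytest.approx(2 * s_nu / (m * (m - 1)), abs=0)

    def test_permutation_invariance(self, toy_matrix, rng):
        perm = rng.permutation(toy_matrix.m)
        shuffled = IndexMatrix(
            tuple(toy_matrix.object_labels[i] for i in perm),
            toy_matrix.criteria_labels,
            toy_matrix.evaluations[perm],
        )
        a, b = run_icra(toy_matrix), run_icra(shuffled)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.nu, b.nu)

    def test_monotone_transform_invariance(self, rng):
        ev = rng.standard_normal((12, 3))
        im = IndexMatrix(tuple(f"o{i}" for i in range(12)), ("A", "B", "C"), ev)
        warped = ev.copy()
        warped[:, 1] = np.exp(3.0 * warped[:, 1])  # strictly increasing
        im2 = IndexMatrix(im.object_labels, im.criteria_labels, warped)
        np.testing.assert_array_equal(run_icra(im).mu, run_icra(im2).mu)

    def test_negating_a_column_swaps_mu_and_nu(self, rng):
        ev = rng.standard_normal((15, 3))  # continuous: tie-free
        im = IndexMatrix(tuple(f"o{i}" for i in range(15)), ("A", "B", "C"), ev)
        flipped = ev.copy()
        flipped[:, 0] = -flipped[:, 0]
        im2 = IndexMatrix(im.object_labels, im.criteria_labels, flipped)
        a, b = run_icra(im), run_icra(im2)
        for other in (1, 2):
            assert a.mu[0, other] == b.nu[0, other]
            assert a.nu[0, other] == b.mu[0, other]
        assert a.mu[1, 2] == b.mu[1, 2]

    def test_kendall_identity_on_tie_free_data(self, rng):
        xs, ys = rng.standard_normal((2, 40))
        c = pairwise_counters(xs, ys)
        p = degrees(c, 40)
        tau = stats.kendalltau(xs, ys).statistic  # tau-b == tau-a without ties
        assert p.mu - p.nu == pytest.approx(tau, abs=1e-12)
        assert p.mu == pytest.approx((1 + tau) / 2, abs=1e-12)

    def test_long_frame_has_all_pairs(self, toy_matrix):
        df = run_icra(toy_matrix).long_frame()
        assert list(df.columns) == ["pair", "mu", "nu", "pi"]
        assert len(df) == 3
        assert ((df.mu + df.nu + df.pi - 1.0).abs() < 1e-12).all()
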