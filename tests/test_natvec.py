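import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alfphylo.natvec import (
    EnumerationCapExceeded,
    PositionSet,
    _order_statistic_weights,
    central_moment,
    component_names,
    covariance_brute,
    covariance_closed,
    mean_position,
    natural_vector,
    position_sets,
    symbol_pairs,
    vectors_to_frame,
)
from alfphylo.seqio import DNA, PROTEIN, SequenceRecord, make_record


def ps(positions, N, symbol="A"):
    return PositionSet(symbol=symbol, positions=tuple(positions), N=N)


@st.composite
def position_set_pair(draw, max_n=8, max_N=40):
    """Two disjoint position sets over a shared sequence length."""
    N = draw(st.integers(16, max_N))
    n = draw(st.integers(1, max_n))
    m = draw(st.integers(1, n))
    pool = draw(st.permutations(range(1, N + 1)))
    a = tuple(sorted(pool[:n]))
    b = tuple(sorted(pool[n : n + m]))
    return ps(a, N), ps(b, N)


class TestPositionSets:
    def test_worked_example(self, dna_example):
        sets = position_sets(dna_example)
        assert sets["A"].positions == (1, 3, 5)
        assert sets["C"].positions == (2, 4, 6)
        assert sets["G"].positions == (7, 9)
        assert sets["T"].positions == (8, 10)

    def test_homopolymer(self):
        sets = position_sets(make_record("h", "AAAA", DNA))
        assert sets["A"].positions == (1, 2, 3, 4)
        assert sets["C"].positions == () and sets["G"].positions == () and sets["T"].positions == ()

    def test_noncanonical_in_no_set(self):
        rec = make_record("x", "AXA", DNA, "skip")
        sets = position_sets(rec)
        assert sets["A"].positions == (1, 3)
        assert rec.length == 3
        assert sum(len(s) for s in sets.values()) == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            ps([0, 2], 5)
        with pytest.raises(ValueError):
            ps([3, 2], 5)


class TestMeanPosition:
    def test_paper_values(self):
        assert mean_position(ps([1, 3, 5], 10)) == 3
        assert mean_position(ps([7, 9], 10)) == 8
        assert mean_position(ps([2, 4, 6], 10)) == 4

    def test_empty_convention(self):
        assert mean_position(ps([], 10)) == 0.0


class TestCentralMoment:
    def test_first_moment_vanishes(self, rng):
        for _ in range(50):
            n = rng.integers(1, 10)
            positions = sorted(rng.choice(np.arange(1, 50), size=n, replace=False))
            assert central_moment(ps(positions, 60), 1) == 0.0

    def test_second_moment_example(self):
        # ((1-3)^2 + (3-3)^2 + (5-3)^2) / (3 * 10)
        assert central_moment(ps([1, 3, 5], 10), 2) == pytest.approx(8 / 30, rel=1e-15)

    def test_singleton(self):
        assert central_moment(ps([5], 10), 2) == 0.0

    def test_empty(self):
        assert central_moment(ps([], 10), 2) == 0.0

    def test_higher_order(self):
        # j=3: sum (i-mu)^3 / (n^2 N^2)
        expected = ((1 - 3) ** 3 + 0 + (5 - 3) ** 3) / (9 * 100)
        assert central_moment(ps([1, 3, 5], 10), 3) == pytest.approx(expected)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            central_moment(ps([1], 10), 0)


def brute_fraction(a, b, N):
    """Exact-rational subset-averaged covariance (independent of package code)."""
    big, small = (a, b) if len(a) >= len(b) else (b, a)
    m = len(small)
    mu_b = Fraction(sum(small), m)
    total = Fraction(0)
    count = 0
    for subset in itertools.combinations(big, m):
        mu_s = Fraction(sum(subset), m)
        total += sum((Fraction(x) - mu_s) * (Fraction(y) - mu_b) for x, y in zip(subset, small))
        count += 1
    return total / m / count / N


class TestCovarianceBrute:
    def test_paper_equal_counts(self):
        assert covariance_brute(ps([1, 3, 5], 10), ps([2, 4, 6], 10)) == pytest.approx(4 / 15, rel=1e-15)

    def test_paper_unequal_counts(self):
        assert covariance_brute(ps([1, 3, 5], 10), ps([7, 9], 10)) == pytest.approx(2 / 15, rel=1e-15)

    def test_empty_set(self):
        assert covariance_brute(ps([1, 3, 5], 10), ps([], 10)) == 0.0

    def test_matches_exact_rational(self, rng):
        for _ in range(30):
            N = 30
            pool = rng.permutation(np.arange(1, N + 1))
            n, m = sorted(rng.integers(1, 7, size=2))[::-1]
            a, b = sorted(pool[:n].tolist()), sorted(pool[n : n + m].tolist())
            assert covariance_brute(ps(a, N), ps(b, N)) == pytest.approx(
                float(brute_fraction(a, b, N)), abs=1e-12
            )

    def test_cap(self):
        a = ps(list(range(1, 41)), 100)
        b = ps(list(range(50, 70)), 100)
        with pytest.raises(EnumerationCapExceeded):
            covariance_brute(a, b, enumeration_cap=1000)

    def test_different_N_rejected(self):
        with pytest.raises(ValueError):
            covariance_brute(ps([1], 10), ps([2], 12))


class TestCovarianceClosed:
    def test_paper_unequal_counts(self):
        assert covariance_closed(ps([1, 3, 5], 10), ps([7, 9], 10)) == pytest.approx(2 / 15, rel=1e-12)

    def test_self_covariance_is_spread(self):
        # {2,4,6} against itself: ((-2)^2 + 0 + 2^2)/3/10
        assert covariance_closed(ps([2, 4, 6], 10), ps([2, 4, 6], 10)) == pytest.approx(4 / 15, rel=1e-12)

    def test_empty_set(self):
        assert covariance_closed(ps([], 10), ps([2, 4], 10)) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(position_set_pair())
    def test_matches_brute(self, pair):
        a, b = pair
        assert covariance_closed(a, b) == pytest.approx(covariance_brute(a, b), abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(position_set_pair())
    def test_symmetry(self, pair):
        a, b = pair
        assert covariance_closed(a, b) == pytest.approx(covariance_closed(b, a), abs=1e-12)
        assert covariance_brute(a, b) == pytest.approx(covariance_brute(b, a), abs=1e-12)

    def test_weight_rows_are_distributions(self):
        for n, m in [(5, 2), (8, 8), (12, 5), (200, 40), (1000, 3)]:
            w = _order_statistic_weights(n, m)
            assert w.shape == (m, n)
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_weights_match_binomials(self):
        n, m = 7, 3
        w = _order_statistic_weights(n, m)
        for i in range(m):
            for j in range(n):
                assert w[i, j] == pytest.approx(comb(j, i) * comb(n - 1 - j, m - 1 - i) / comb(n, m))

    def test_large_sets_finite(self, rng):
        pool = rng.permutation(np.arange(1, 20001))
        a = ps(sorted(pool[:900].tolist()), 20000)
        b = ps(sorted(pool[900:1300].tolist()), 20000)
        assert np.isfinite(covariance_closed(a, b))

    def test_reversal_invariance_equal_counts(self, rng):
        N = 50
        for _ in range(20):
            pool = rng.permutation(np.arange(1, N + 1))
            a, b = sorted(pool[:5].tolist()), sorted(pool[5:10].tolist())
            ra = sorted(N + 1 - p for p in a)
            rb = sorted(N + 1 - p for p in b)
            assert covariance_closed(ps(a, N), ps(b, N)) == pytest.approx(
                covariance_closed(ps(ra, N), ps(rb, N)), abs=1e-12
            )


class TestNaturalVector:
    def test_dna_extended_layout(self, dna_example):
        nv = natural_vector(dna_example, extended=True)
        assert nv.dim == 18
        values = dict(zip(nv.names, nv.values))
        assert values["cov_A_C"] == pytest.approx(4 / 15, rel=1e-12)
        assert values["cov_A_G"] == pytest.approx(2 / 15, rel=1e-12)
        assert values["mu_A"] == 3 and values["mu_G"] == 8

    def test_protein_extended_dim(self, protein_record):
        assert natural_vector(protein_record, extended=True).dim == 250

    def test_basic_dims(self, dna_example, protein_record):
        assert natural_vector(dna_example, extended=False).dim == 12
        assert natural_vector(protein_record, extended=False).dim == 60

    def test_homopolymer_basic_values(self):
        nv = natural_vector(make_record("h", "AAAA", DNA), extended=False)
        np.testing.assert_allclose(nv.counts, [4, 0, 0, 0])
        np.testing.assert_allclose(nv.means, [2.5, 0, 0, 0])
        np.testing.assert_allclose(nv.second_moments, [0.3125, 0, 0, 0])

    def test_zero_count_symbols_zero_everywhere(self):
        nv = natural_vector(make_record("h", "AAAA", DNA), extended=True)
        values = dict(zip(nv.names, nv.values))
        for pair in ["cov_A_C", "cov_A_G", "cov_C_T", "cov_G_T"]:
            assert values[pair] == 0.0

    def test_all_entries_finite(self, rng):
        from conftest import random_record

        for _ in range(10):
            rec = random_record(rng, PROTEIN, 80)
            assert np.all(np.isfinite(natural_vector(rec).values))

    def test_component_order(self):
        names = component_names(DNA, extended=True)
        assert names[:4] == ["n_A", "n_C", "n_G", "n_T"]
        assert names[4:8] == ["mu_A", "mu_C", "mu_G", "mu_T"]
        assert names[8:12] == ["D2_A", "D2_C", "D2_G", "D2_T"]
        assert names[12:] == ["cov_A_C", "cov_A_G", "cov_A_T", "cov_C_G", "cov_C_T", "cov_G_T"]

    def test_pair_counts(self):
        assert len(symbol_pairs(DNA)) == 6
        assert len(symbol_pairs(PROTEIN)) == 190

    def test_counts_sum_excludes_noncanonical(self):
        nv = natural_vector(make_record("x", "AXGT", DNA, "skip"))
        assert nv.counts.sum() == 3

    def test_injectivity_spot_check(self, rng):
        seen = set()
        n_seqs = 10_000
        sequences = set()
        while len(sequences) < n_seqs:
            sequences.add("".join(rng.choice(list(DNA.symbols), size=12)))
        for s in sequences:
            nv = natural_vector(SequenceRecord("s", DNA, s), extended=False)
            seen.add(tuple(np.round(nv.values, 12)))
        assert len(seen) == n_seqs

    def test_frame_export(self, dna_example):
        df = vectors_to_frame([dna_example])
        assert list(df.columns) == component_names(DNA)
        assert list(df.index) == ["ex"]
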