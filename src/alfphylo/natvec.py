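"""Natural vectors with pairwise positional covariances.

A sequence is summarized by, for every canonical symbol k: its count n_k,
mean position mu_k = T_k/n_k, and normalized central moment
D_j^k = sum_i (i - mu_k)^j w_k(s_i) / (n_k^(j-1) N^(j-1)); the extended
vector appends, for every unordered symbol pair, the rank-paired positional
covariance divided by N.  For unequal counts the covariance is the average
over all same-size increasing subsets of the larger position set; the
production path evaluates that average in closed form with hypergeometric
order-statistic weights, while :func:`covariance_brute` enumerates subsets
and serves as the independent oracle.

Vector layout (fixed): counts in alphabet order, then means, then second
moments, then pairs (X, Y) with X before Y, lexicographic in alphabet order.
Zero-count symbols contribute 0 everywhere so the dimension is constant
(18 for DNA, 250 for protein).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from alfphylo.seqio import Alphabet, SequenceRecord, TaxonProfile

DEFAULT_ENUMERATION_CAP = 100_000


class EnumerationCapExceeded(ValueError):
    """Brute-force subset enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class PositionSet:
    """Sorted 1-based occurrence positions of one symbol in one sequence."""

    symbol: str
    positions: tuple[int, ...]
    N: int

    def __post_init__(self) -> None:
        if any(not (1 <= p <= self.N) for p in self.positions):
            raise ValueError(f"positions out of range [1, {self.N}]")
        if any(a >= b for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.positions)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class NaturalVector:
    """Fixed-layout numeric feature vector for one sequence."""

    alphabet: Alphabet
    counts: np.ndarray
    means: np.ndarray
    second_moments: np.ndarray
    covariances: np.ndarray | None  # None for the basic (non-extended) vector

    @property
    def extended(self) -> bool:
        return self.covariances is not None

    @property
    def dim(self) -> int:
        return len(self.values)

    @property
    def values(self) -> np.ndarray:
        parts = [self.counts, self.means, self.second_moments]
        if self.covariances is not None:
            parts.append(self.covariances)
        return np.concatenate(parts)

    @property
    def names(self) -> list[str]:
        return component_names(self.alphabet, extended=self.extended)


def symbol_pairs(alphabet: Alphabet) -> list[tuple[str, str]]:
    """Unordered symbol pairs in canonical (lexicographic-in-alphabet) order."""
    return list(itertools.combinations(alphabet.symbols, 2))


def component_names(alphabet: Alphabet, extended: bool = True) -> list[str]:
    names = [f"n_{s}" for s in alphabet.symbols]
    names += [f"mu_{s}" for s in alphabet.symbols]
    names += [f"D2_{s}" for s in alphabet.symbols]
    if extended:
        names += [f"cov_{x}_{y}" for x, y in symbol_pairs(alphabet)]
    return names


def position_sets(rec: SequenceRecord) -> dict[str, PositionSet]:
    """Map every canonical symbol to its (possibly empty) 1-based positions."""
    occ: dict[str, list[int]] = {s: [] for s in rec.alphabet.symbols}
    for i, ch in enumerate(rec.residues, start=1):
        if ch in occ:
            occ[ch].append(i)
    return {
        s: PositionSet(symbol=s, positions=tuple(pos), N=rec.length)
        for s, pos in occ.items()
    }


def mean_position(ps: PositionSet) -> float:
    """T_k / n_k; 0 for an empty set by convention."""
    if not ps.positions:
        return 0.0
    return float(sum(ps.positions)) / len(ps.positions)


def central_moment(ps: PositionSet, j: int) -> float:
    """Normalized central moment D_j^k = sum (i - mu)^j / (n^(j-1) N^(j-1)).

    j=1 vanishes identically; empty sets return 0.
    """
    if j < 1:
        raise ValueError("moment order must be >= 1")
    n = len(ps.positions)
    if n == 0 or j == 1:
        return 0.0
    mu = mean_position(ps)
    num = sum((p - mu) ** j for p in ps.positions)
    return float(num) / (n ** (j - 1) * ps.N ** (j - 1))


def _check_same_sequence(a: PositionSet, b: PositionSet) -> None:
    if a.N != b.N:
        raise ValueError(f"position sets come from different sequences (N={a.N} vs {b.N})")


def _rank_paired_cov(a: np.ndarray, b: np.ndarray, mu_b: float) -> float:
    # subset-mean term vanishes because sum(b - mu_b) = 0
    return float(np.dot(a - a.mean(), b - mu_b)) / len(b)


def covariance_brute(
    A: PositionSet, B: PositionSet, enumeration_cap: int = DEFAULT_ENUMERATION_CAP
) -> float:
    """Subset-enumeration covariance feature Cov(A, B)/N (test oracle).

    Equal counts: rank-paired sample covariance over m pairs.  Unequal: the
    larger set contributes every size-m increasing subset, each rank-paired
    with the smaller set; the C(n, m) sample covariances are averaged.  The
    result is divided by the sequence length N.
    """
    _check_same_sequence(A, B)
    if not A.positions or not B.positions:
        return 0.0
    big, small = (A, B) if len(A) >= len(B) else (B, A)
    n, m = len(big), len(small)
    n_subsets = comb(n, m)
    if n_subsets > enumeration_cap:
        raise EnumerationCapExceeded(
            f"C({n},{m}) = {n_subsets} exceeds cap {enumeration_cap}; use covariance_closed"
        )
    b = np.asarray(small.positions, dtype=float)
    mu_b = b.mean()
    total = 0.0
    for subset in itertools.combinations(big.positions, m):
        total += _rank_paired_cov(np.asarray(subset, dtype=float), b, mu_b)
    return total / n_subsets / A.N


def _order_statistic_weights(n: int, m: int) -> np.ndarray:
    """Row-stochastic m-by-n weight matrix w[i, j] = C(j, i) C(n-1-j, m-1-i) / C(n, m).

    w[i, j] is the probability that a uniform size-m increasing subset of n
    ordered items has item j (0-based) as its i-th (0-based) element —
    evaluated via log-gamma so C(n, m) is never materialized.
    """
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]

    def log_comb(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return np.where((b >= 0) & (b <= a), out, -np.inf)

    logw = log_comb(j, i) + log_comb(n - 1 - j, m - 1 - i) - log_comb(n, m)
    w = np.exp(logw)
    if __debug__:
        row_sums = w.sum(axis=1)
        assert np.allclose(row_sums, 1.0, atol=1e-9), "order-statistic weight rows must sum to 1"
    return w


def covariance_closed(A: PositionSet, B: PositionSet) -> float:
    """Closed-form covariance feature Cov(A, B)/N (production path).

    Equals :func:`covariance_brute` without subset enumeration:
    I = sum_i b_i * E[a_(i)] / m - mu_A * mu_B, where E[a_(i)] is the
    expected i-th element of a uniform size-m subset of the larger set,
    computed with hypergeometric order-statistic weights in O(n*m).
    """
    _check_same_sequence(A, B)
    if not A.positions or not B.positions:
        return 0.0
    big, small = (A, B) if len(A) >= len(B) else (B, A)
    a = np.asarray(big.positions, dtype=float)
    b = np.asarray(small.positions, dtype=float)
    n, m = len(a), len(b)
    if n == m:
        value = float(np.dot(a - a.mean(), b - b.mean())) / m
    else:
        expected_a = _order_statistic_weights(n, m) @ a
        value = float(np.dot(b, expected_a)) / m - a.mean() * b.mean()
    if not np.isfinite(value):
        raise FloatingPointError("non-finite covariance weight computation")
    return value / A.N


def natural_vector(rec: SequenceRecord, extended: bool = True) -> NaturalVector:
    """Compute the (extended) natural vector of one sequence.

    Basic: 3 * |alphabet| components (12 DNA / 60 protein).  Extended appends
    all C(|alphabet|, 2) pair covariances (18 / 250 total).
    """
    sets = position_sets(rec)
    symbols = rec.alphabet.symbols
    counts = np.array([len(sets[s]) for s in symbols], dtype=float)
    means = np.array([mean_position(sets[s]) for s in symbols])
    d2 = np.array([central_moment(sets[s], 2) for s in symbols])
    covs = None
    if extended:
        covs = np.array([covariance_closed(sets[x], sets[y]) for x, y in symbol_pairs(rec.alphabet)])
    return NaturalVector(
        alphabet=rec.alphabet, counts=counts, means=means, second_moments=d2, covariances=covs
    )


def profile_vectors(profile: TaxonProfile, extended: bool = True) -> np.ndarray:
    """Stack the natural vectors of a taxon's records into an (n, dim) array."""
    return np.vstack([natural_vector(r, extended=extended).values for r in profile.records])


def vectors_to_frame(records: Iterable[SequenceRecord], extended: bool = True):
    """Tabulate natural vectors as a pandas DataFrame (rows = record ids)."""
    import pandas as pd

    records = list(records)
    if not records:
        raise ValueError("no records to vectorize")
    names = component_names(records[0].alphabet, extended=extended)
    data = [natural_vector(r, extended=extended).values for r in records]
    return pd.DataFrame(data, index=[r.id for r in records], columns=names)
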