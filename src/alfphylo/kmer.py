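"""k-mer composition baseline for method comparison.

Each taxon is summarized by one pooled k-word frequency vector (counts
pooled over all its sequences, then normalized); taxa are compared by a
point metric over the full canonical k-word space.  Windows containing a
non-canonical character are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from alfphylo.metrics import DistanceMatrix, point_distance
from alfphylo.seqio import Alphabet, SequenceRecord, TaxonProfile


@dataclass(frozen=True)
class KmerVector:
    """Sparse k-word composition of one sequence."""

    k: int
    counts_or_freqs: dict[str, float]
    normalization: str  # "count" | "frequency"


def _count_words(residues: str, k: int, canonical: frozenset[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        word = residues[i : i + k]
        if all(c in canonical for c in word):
            counts[word] = counts.get(word, 0) + 1
    return counts


def kmer_vector(rec: SequenceRecord, k: int, normalization: str = "count") -> KmerVector:
    """Sliding-window (stride 1) k-word composition of one record."""
    if normalization not in ("count", "frequency"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not 1 <= k <= rec.length:
        raise ValueError(f"k={k} out of range for sequence of length {rec.length}")
    counts = _count_words(rec.residues, k, frozenset(rec.alphabet.symbols))
    if normalization == "count":
        return KmerVector(k=k, counts_or_freqs={w: float(c) for w, c in counts.items()},
                          normalization="count")
    total = sum(counts.values())
    freqs = {w: c / total for w, c in counts.items()} if total else {}
    return KmerVector(k=k, counts_or_freqs=freqs, normalization="frequency")


def _word_index(alphabet: Alphabet, k: int) -> dict[str, int]:
    words = itertools.product(alphabet.symbols, repeat=k)
    return {"".join(w): i for i, w in enumerate(words)}


def pooled_frequency_vector(profile: TaxonProfile, k: int) -> np.ndarray:
    """Dense pooled k-word frequency vector of a taxon over the full word space."""
    index = _word_index(profile.alphabet, k)
    dense = np.zeros(len(index))
    canonical = frozenset(profile.alphabet.symbols)
    for rec in profile.records:
        for word, c in _count_words(rec.residues, k, canonical).items():
            dense[index[word]] += c
    total = dense.sum()
    if total == 0:
        raise ValueError(f"taxon {profile.label!r} has no valid {k}-mer windows")
    return dense / total


def kmer_profile_distance(
    p1: TaxonProfile, p2: TaxonProfile, k: int = 3, base_metric: str = "euclidean"
) -> float:
    """Point distance between two taxa's pooled k-word frequency vectors."""
    if p1.alphabet.name != p2.alphabet.name:
        raise ValueError("profiles use different alphabets")
    return point_distance(
        pooled_frequency_vector(p1, k), pooled_frequency_vector(p2, k), base_metric
    )


def kmer_matrix(
    profiles: Sequence[TaxonProfile], k: int = 3, base_metric: str = "euclidean"
) -> DistanceMatrix:
    """Pairwise pooled k-mer distance matrix; feeds single_linkage unchanged."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    vecs = [pooled_frequency_vector(p, k) for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = point_distance(vecs[i], vecs[j], base_metric)
    return DistanceMatrix(
        labels=[p.label for p in profiles], values=d,
        base_metric=base_metric, set_metric="direct",
    )
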