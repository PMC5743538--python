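"""Single-linkage dendrograms, Newick output, and bootstrap clade support.

The agglomeration is the classical O(n^3) scheme: repeatedly merge the two
clusters with the smallest minimum cross-pair distance, breaking ties by the
lexicographically smallest member labels.  Merge heights coincide with the
sorted edge weights of a minimum spanning tree of the distance graph.

Bootstrap support resamples whole sequences with replacement within each
taxon (the method is alignment-free, so there are no columns to resample),
rebuilds the tree, and reports for each original internal clade the fraction
of replicate trees containing a clade with the identical leaf set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from alfphylo.metrics import DistanceMatrix, pairwise_matrix
from alfphylo.natvec import profile_vectors
from alfphylo.seqio import TaxonProfile


@dataclass
class Dendrogram:
    """Ultrametric merge tree over taxon labels."""

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(a > b + 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def clades(self) -> dict[frozenset, float]:
        """Internal clades (merged leaf subsets) mapped to their merge heights."""
        return {a | b: h for a, b, h in self.merges}

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def maximal_clades(self, k: int = 2) -> list[set[str]]:
        """The k clusters obtained by cutting just below the last k-1 merges."""
        clusters = [frozenset([l]) for l in self.leaves]
        for a, b, _ in self.merges[: len(self.leaves) - k]:
            clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        return [set(c) for c in clusters]


@dataclass
class SupportedTree:
    """A dendrogram plus bootstrap support per internal clade."""

    dendrogram: Dendrogram
    support: dict[frozenset, float]
    n_replicates: int

    def __post_init__(self) -> None:
        missing = set(self.dendrogram.clades) - set(self.support)
        if missing:
            raise ValueError("support missing for some internal clades")


def single_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerate a distance matrix by single linkage.

    Each step merges the pair of clusters with minimum cross-pair distance;
    ties go to the pair with lexicographically smallest member labels.
    """
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distance entries")
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 taxa")
    index = {l: i for i, l in enumerate(labels)}
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    merges: list[tuple[frozenset, frozenset, float]] = []

    def linkage(a: frozenset, b: frozenset) -> float:
        return min(dm.values[index[x], index[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                key = (linkage(a, b), *sorted((min(a), min(b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, *_), a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append((a, b, float(d)))
    return Dendrogram(leaves=labels, merges=merges)


_SAFE_LABEL = re.compile(r"^[^\s()\[\]':;,]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(
    tree: Dendrogram,
    support: dict[frozenset, float] | None = None,
) -> str:
    """Serialize an ultrametric dendrogram to Newick.

    Branch length = parent merge height - child height (leaves sit at 0).
    Support values, when given, become internal node labels.
    """
    clade_height = tree.clades
    children: dict[frozenset, tuple[frozenset, frozenset]] = {
        a | b: (a, b) for a, b, _ in tree.merges
    }

    def height(clade: frozenset) -> float:
        return 0.0 if len(clade) == 1 else clade_height[clade]

    def render(clade: frozenset, parent_height: float) -> str:
        bl = parent_height - height(clade)
        if len(clade) == 1:
            (leaf,) = clade
            return f"{_quote(leaf)}:{bl:.10g}"
        a, b = children[clade]
        sub = ",".join(render(c, height(clade)) for c in sorted((a, b), key=min))
        label = ""
        if support is not None and clade in support:
            label = f"{support[clade]:.10g}"
        return f"({sub}){label}:{bl:.10g}"

    root = frozenset(tree.leaves)
    root_height = height(root)
    a, b = children[root]
    sub = ",".join(render(c, root_height) for c in sorted((a, b), key=min))
    label = ""
    if support is not None and root in support:
        label = f"{support[root]:.10g}"
    return f"({sub}){label};"


def bootstrap_support(
    profiles: Sequence[TaxonProfile],
    n_replicates: int = 100,
    base_metric: str = "euclidean",
    set_metric: str = "hausdorff",
    seed: int = 0,
    extended: bool = True,
) -> SupportedTree:
    """Bootstrap clade support for the single-linkage tree of ``profiles``.

    Each replicate independently resamples, within each taxon, its sequences
    with replacement to the original per-taxon count (vectors are reused, not
    recomputed, since resampling permutes whole sequences).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    vectors = [profile_vectors(p, extended=extended) for p in profiles]
    original = single_linkage(
        pairwise_matrix(profiles, base_metric, set_metric, extended, vectors=vectors)
    )
    target = list(original.clades)
    hits = {c: 0 for c in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        resampled = []
        for v in vectors:
            idx = rng.integers(0, v.shape[0], size=v.shape[0])
            resampled.append(v[idx])
        rep_tree = single_linkage(
            pairwise_matrix(profiles, base_metric, set_metric, extended, vectors=resampled)
        )
        rep_clades = set(rep_tree.clades)
        for c in target:
            if c in rep_clades:
                hits[c] += 1
    support = {c: hits[c] / n_replicates for c in target}
    return SupportedTree(dendrogram=original, support=support, n_replicates=n_replicates)
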