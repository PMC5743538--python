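"""Leave-one-out nearest-neighbor assignment of sequences to taxa.

A query vector is assigned to the taxon whose vector set contains its
nearest neighbor by Euclidean distance, excluding the query instance itself
(instance-level exclusion: other identical vectors stay eligible).  Ties go
to the lexicographically smallest taxon label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from alfphylo.natvec import profile_vectors
from alfphylo.seqio import TaxonProfile


@dataclass
class ClassificationReport:
    """Per-taxon accuracy, confusion counts, and worst-confusion statistics."""

    per_taxon_accuracy: dict[str, float]
    total_accuracy: float
    confusion: dict[tuple[str, str], int]
    most_wrong: dict[str, tuple[str | None, float]]
    taxon_sizes: dict[str, int]

    def accuracy_tsv(self, path=None) -> str:
        lines = ["strain\taccuracy"]
        for label in sorted(self.per_taxon_accuracy):
            lines.append(f"{label}\t{self.per_taxon_accuracy[label]:.4f}")
        lines.append(f"Total\t{self.total_accuracy:.4f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def most_wrong_tsv(self, path=None) -> str:
        lines = ["strain\tmost_wrong_strain\tmost_error_rate_percent"]
        for label in sorted(self.most_wrong):
            wrong, rate = self.most_wrong[label]
            lines.append(f"{label}\t{wrong if wrong is not None else '-'}\t{100 * rate:.2f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_query(
    x: np.ndarray,
    taxa_vectors: Mapping[str, np.ndarray],
    exclude: tuple[str, int] | None = None,
) -> str:
    """Nearest-neighbor taxon of a query vector.

    ``exclude=(label, row)`` removes exactly that instance from its taxon's
    candidate set (leave-one-out).  The winning taxon minimizes the minimum
    Euclidean distance from ``x`` to its vectors; ties break lexicographically.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    best: tuple[float, str] | None = None
    for label in sorted(taxa_vectors):
        v = taxa_vectors[label]
        if exclude is not None and exclude[0] == label:
            v = np.delete(v, exclude[1], axis=0)
        if v.shape[0] == 0:
            continue
        d = float(cdist(x, v).min())
        if best is None or d < best[0]:
            best = (d, label)
    if best is None:
        raise ValueError("no candidate vectors remain after exclusion")
    return best[1]


def most_error_stats(
    confusion: Mapping[tuple[str, str], int],
    taxon_sizes: Mapping[str, int],
) -> dict[str, tuple[str | None, float]]:
    """Per-taxon worst misassignment: (most-wrong label, most-error rate).

    The most-wrong label is the foreign taxon receiving the largest
    misassignment count; the rate is that count over the taxon's size.
    Taxa without errors map to (None, 0.0); count ties break
    lexicographically.
    """
    out: dict[str, tuple[str | None, float]] = {}
    for label in sorted(taxon_sizes):
        errors = {
            pred: n for (true, pred), n in confusion.items()
            if true == label and pred != label and n > 0
        }
        if not errors:
            out[label] = (None, 0.0)
            continue
        worst = min(errors, key=lambda p: (-errors[p], p))
        out[label] = (worst, errors[worst] / taxon_sizes[label])
    return out


def evaluate_all(
    profiles: Sequence[TaxonProfile],
    extended: bool = True,
    vectors: Sequence[np.ndarray] | None = None,
) -> ClassificationReport:
    """Leave-one-out classification of every sequence in the collection."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 taxa")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels")
    if vectors is None:
        vectors = [profile_vectors(p, extended=extended) for p in profiles]
    taxa_vectors = dict(zip(labels, vectors))

    confusion: dict[tuple[str, str], int] = {}
    sizes = {l: v.shape[0] for l, v in taxa_vectors.items()}
    correct = {l: 0 for l in labels}
    for label, v in taxa_vectors.items():
        for row in range(v.shape[0]):
            pred = classify_query(v[row], taxa_vectors, exclude=(label, row))
            confusion[(label, pred)] = confusion.get((label, pred), 0) + 1
            if pred == label:
                correct[label] += 1
    per_taxon = {l: correct[l] / sizes[l] for l in labels}
    total = sum(correct.values()) / sum(sizes.values())
    return ClassificationReport(
        per_taxon_accuracy=per_taxon,
        total_accuracy=total,
        confusion=confusion,
        most_wrong=most_error_stats(confusion, sizes),
        taxon_sizes=sizes,
    )
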