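"""FASTA input, canonical alphabets, and synthetic strain collections.

A taxon is a labeled set of sequences (one multi-FASTA file per taxon).
Non-canonical residues (X, B, Z, U, gaps, nucleotide ambiguity codes, ...)
occupy positions and count toward the sequence length N but belong to no
symbol class; under ``policy="strict"`` they raise instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

Policy = Literal["skip", "strict"]

FASTA_SUFFIXES = (".fa", ".fasta", ".faa", ".fna", ".ffn", ".frn", ".mpfa")


@dataclass(frozen=True)
class Alphabet:
    """An ordered canonical symbol set; order fixes vector component layout."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


DNA = Alphabet("DNA", ("A", "C", "G", "T"))
PROTEIN = Alphabet(
    "PROTEIN",
    ("A", "R", "N", "D", "C", "E", "Q", "G", "H", "I",
     "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V"),
)

ALPHABETS = {"DNA": DNA, "PROTEIN": PROTEIN}


class NonCanonicalError(ValueError):
    """Raised under strict policy when a residue is outside the alphabet."""

    def __init__(self, record_id: str, symbol: str, position: int):
        self.record_id = record_id
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"record {record_id!r}: non-canonical character {symbol!r} at position {position}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """One identified sequence over a declared alphabet.

    ``residues`` is upper-cased and stop-stripped; its full length is N, the
    denominator used by all positional statistics, including positions held
    by non-canonical characters.
    """

    id: str
    alphabet: Alphabet
    residues: str
    n_noncanonical: int = 0

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TaxonProfile:
    """A labeled, non-empty set of records representing one organism/strain."""

    label: str
    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"taxon {self.label!r} has no records")
        alphabets = {r.alphabet.name for r in self.records}
        if len(alphabets) > 1:
            raise ValueError(f"taxon {self.label!r} mixes alphabets {sorted(alphabets)}")

    @property
    def alphabet(self) -> Alphabet:
        return self.records[0].alphabet

    def __len__(self) -> int:
        return len(self.records)


def make_record(record_id: str, raw: str, alphabet: Alphabet, policy: Policy = "skip") -> SequenceRecord:
    """Normalize a raw residue string into a :class:`SequenceRecord`.

    Upper-cases, strips exactly one trailing ``*``, then counts characters
    outside the alphabet.  Internal ``*`` is non-canonical like any other
    foreign character.
    """
    residues = raw.strip().upper()
    if residues.endswith("*"):
        residues = residues[:-1]
    if not residues:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    canonical = set(alphabet.symbols)
    n_bad = 0
    for pos, ch in enumerate(residues, start=1):
        if ch not in canonical:
            if policy == "strict":
                raise NonCanonicalError(record_id, ch, pos)
            n_bad += 1
    return SequenceRecord(id=record_id, alphabet=alphabet, residues=residues, n_noncanonical=n_bad)


def read_fasta(path: str | os.PathLike, alphabet: Alphabet, policy: Policy = "skip") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into records, preserving file order."""
    path = Path(path)
    records = [
        make_record(entry.id, str(entry.seq), alphabet, policy)
        for entry in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records to FASTA (id + residues only)."""
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def load_profiles(directory: str | os.PathLike, alphabet: Alphabet, policy: Policy = "skip") -> list[TaxonProfile]:
    """Load one taxon per FASTA file in ``directory``; label = file stem.

    Profiles are returned in lexicographic label order.  Duplicate stems
    (e.g. ``a.faa`` and ``a.fasta``) are an error.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in FASTA_SUFFIXES
    )
    if not files:
        raise ValueError(f"no FASTA files found in {directory}")
    seen: dict[str, Path] = {}
    for p in files:
        if p.stem in seen:
            raise ValueError(f"duplicate taxon label {p.stem!r}: {seen[p.stem].name} and {p.name}")
        seen[p.stem] = p
    profiles = [
        TaxonProfile(label=p.stem, records=read_fasta(p, alphabet, policy))
        for p in sorted(files, key=lambda p: p.stem)
    ]
    return profiles


@dataclass(frozen=True)
class PlantedPartition:
    """Clade membership planted by :func:`simulate_strains`."""

    clades: tuple[frozenset[str], ...]

    def clade_of(self, label: str) -> int:
        for i, clade in enumerate(self.clades):
            if label in clade:
                return i
        raise KeyError(label)

    def as_sets(self) -> list[set[str]]:
        return [set(c) for c in self.clades]

    def to_tsv(self) -> str:
        lines = ["strain\tclade"]
        for i, clade in enumerate(self.clades):
            for label in sorted(clade):
                lines.append(f"{label}\t{i}")
        return "\n".join(lines) + "\n"


def _mutate(seq: np.ndarray, rate: float, n_symbols: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substituted site is redrawn uniformly from the other symbols, so
    ``rate`` is the realized per-site divergence in expectation.
    """
    out = seq.copy()
    hits = rng.random(seq.size) < rate
    n_hits = int(hits.sum())
    if n_hits:
        # shift by 1..n_symbols-1 mod n_symbols: uniform over the other symbols
        out[hits] = (out[hits] + rng.integers(1, n_symbols, size=n_hits)) % n_symbols
    return out


def simulate_strains(
    n_clades: int,
    strains_per_clade: int,
    seqs_per_strain: int,
    seq_len: int,
    between_divergence: float,
    within_divergence: float,
    alphabet: Alphabet = PROTEIN,
    seed: int = 0,
) -> tuple[list[TaxonProfile], PlantedPartition]:
    """Generate a planted-clade strain collection.

    A single random root sequence is mutated once per clade at
    ``between_divergence`` to give each clade its ancestral sequence; every
    sequence of every strain in the clade is an independent mutation of that
    ancestor at ``within_divergence``.  Each clade is therefore a tight cloud
    of points around its ancestor, well separated from other clades.  With
    ``within_divergence=0`` all strains of a clade carry identical sets.
    """
    if not (0 <= within_divergence < between_divergence <= 1):
        raise ValueError("require 0 <= within_divergence < between_divergence <= 1")
    if seq_len < 10:
        raise ValueError("seq_len must be >= 10")
    if min(n_clades, strains_per_clade, seqs_per_strain) < 1:
        raise ValueError("counts must be positive")

    rng = np.random.default_rng(seed)
    n_sym = alphabet.size
    symbols = np.array(list(alphabet.symbols))
    root = rng.integers(0, n_sym, size=seq_len)

    profiles: list[TaxonProfile] = []
    clades: list[frozenset[str]] = []
    strain_idx = 1
    for c in range(n_clades):
        ancestor = _mutate(root, between_divergence, n_sym, rng)
        members: list[str] = []
        for _ in range(strains_per_clade):
            label = f"strain{strain_idx:02d}"
            strain_idx += 1
            members.append(label)
            records = []
            for j in range(1, seqs_per_strain + 1):
                derived = _mutate(ancestor, within_divergence, n_sym, rng)
                records.append(
                    SequenceRecord(
                        id=f"{label}_seq{j:03d}",
                        alphabet=alphabet,
                        residues="".join(symbols[derived]),
                    )
                )
            profiles.append(TaxonProfile(label=label, records=records))
        clades.append(frozenset(members))
    return profiles, PlantedPartition(tuple(clades))


def write_simulation(
    profiles: Sequence[TaxonProfile],
    planted: PlantedPartition,
    directory: str | os.PathLike,
) -> None:
    """Write one FASTA per strain plus a plain-text planted-partition sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for profile in profiles:
        write_fasta(profile.records, directory / f"{profile.label}.faa")
    (directory / "planted_clades.tsv").write_text(planted.to_tsv())
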