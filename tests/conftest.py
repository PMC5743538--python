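import numpy as np
import pytest

from alfphylo.seqio import DNA, PROTEIN, SequenceRecord, TaxonProfile, make_record, simulate_strains


@pytest.fixture
def dna_example() -> SequenceRecord:
    """The worked-example sequence with known means and covariances."""
    return make_record("ex", "ACACACGTGT", DNA)


@pytest.fixture
def protein_record() -> SequenceRecord:
    return make_record("prot", "MKVLAARNDCEQGHILKMFPSTWYV" * 4, PROTEIN)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_record(rng: np.random.Generator, alphabet, length: int, rec_id: str = "r") -> SequenceRecord:
    residues = "".join(rng.choice(list(alphabet.symbols), size=length))
    return SequenceRecord(id=rec_id, alphabet=alphabet, residues=residues)


def random_profiles(rng, n_taxa=4, seqs=3, length=60, alphabet=DNA) -> list[TaxonProfile]:
    return [
        TaxonProfile(
            label=f"t{i}",
            records=[random_record(rng, alphabet, length, f"t{i}_s{j}") for j in range(seqs)],
        )
        for i in range(n_taxa)
    ]


@pytest.fixture(scope="session")
def planted_sim():
    """2 clades x 3 strains x 8 protein sequences of length 300 (shared across tests)."""
    return simulate_strains(
        n_clades=2, strains_per_clade=3, seqs_per_strain=8, seq_len=300,
        between_divergence=0.3, within_divergence=0.02, alphabet=PROTEIN, seed=1,
    )


@pytest.fixture(scope="session")
def planted_vectors(planted_sim):
    from alfphylo.natvec import profile_vectors

    profiles, _ = planted_sim
    return {p.label: profile_vectors(p) for p in profiles}
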