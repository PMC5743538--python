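# alfphylo

Alignment-free sequence comparison and phylogenetics built on **extended
natural vectors**: each DNA or protein sequence is embedded as a fixed-length
numeric vector of per-symbol counts, mean positions, normalized second
moments of positions, and rank-paired positional covariances for every
unordered symbol pair (18 components for DNA, 250 for protein). Organisms
represented as sets of sequences (e.g. whole ribosomal proteomes) are
compared with the Hausdorff distance between their vector sets, clustered by
single linkage with bootstrap clade support, and classified by leave-one-out
nearest neighbor. A pooled k-mer composition distance is included as a
baseline, and a seeded simulator generates planted-clade strain collections
so the whole pipeline is testable offline.

## Library overview

| Module | Contents |
| --- | --- |
| `alfphylo.seqio` | FASTA reading/writing, `DNA`/`PROTEIN` alphabets, non-canonical-residue policies, `simulate_strains` planted-clade generator |
| `alfphylo.natvec` | position sets, means, normalized central moments, pair covariances (`covariance_closed` production path, `covariance_brute` enumeration oracle), `natural_vector` |
| `alfphylo.metrics` | Euclidean/Manhattan point distances, `hausdorff`, labeled `DistanceMatrix`, `pairwise_matrix` |
| `alfphylo.phylo` | `single_linkage` dendrograms, Newick serialization, `bootstrap_support` (per-taxon sequence resampling) |
| `alfphylo.classify` | leave-one-out nearest-neighbor `evaluate_all`, confusion statistics, `most_error_stats` |
| `alfphylo.kmer` | pooled k-mer composition vectors and distance matrices |

```python
import alfphylo as ap

profiles, planted = ap.simulate_strains(
    n_clades=2, strains_per_clade=3, seqs_per_strain=8, seq_len=300,
    between_divergence=0.3, within_divergence=0.02, alphabet=ap.PROTEIN, seed=1)
dm = ap.pairwise_matrix(profiles, base_metric="euclidean", set_metric="hausdorff")
tree = ap.single_linkage(dm)
print(ap.to_newick(tree))
```

## Command line

Inputs are directories of FASTA files, one file per taxon (label = file
stem). Outputs are tab-delimited text and Newick.

```sh
alfphylo simulate --out-dir data/ --n-clades 2 --strains-per-clade 3 \
    --seqs-per-strain 8 --seq-len 300 --seed 1
alfphylo vectors data/ --out vectors.tsv                  # 250-column NV table
alfphylo distmat data/ --out dist.tsv                     # Hausdorff matrix
alfphylo tree data/ --out tree.nwk --n-replicates 100 --seed 1
alfphylo classify data/ --accuracy-out acc.tsv --errors-out errors.tsv
alfphylo kmer-tree data/ --out kmer.nwk -k 3
```

Single-sequence-per-taxon collections (rRNA-style analyses) use
`--set-metric direct`; `--base-metric manhattan` switches the underlying
norm; `--alphabet DNA` selects the 4-letter alphabet. Options can also be
given in a JSON file via `--config` (explicit flags win).

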