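# votuforge

Catalog construction and ecology for gut viromes: from putative viral
contigs to a dereplicated, rank-structured, quantified set of viral
operational taxonomic units (vOTUs), with the community statistics used to
interpret it.

Metagenomic virome studies — such as surveys of the chicken
gastrointestinal tract spanning thousands of samples — follow a common
computational skeleton once viral contigs have been predicted: filter
contigs on completeness and gene content, detect terminal repeats that
mark closed genomes, dereplicate into species-level vOTUs at 95% average
nucleotide identity (ANI) over 85% of the shorter sequence (the MIUViG
criterion), group vOTUs into approximate genera and families from
amino-acid identity (AAI) gene-sharing graphs with Markov Clustering,
quantify vOTUs by read recruitment under identity/aligned-fraction/breadth
thresholds, and test ecological structure (core viromes, accumulation
curves, Bray–Curtis + PERMANOVA, rank tests, negative-binomial richness
models). `votuforge` implements that skeleton as a tested Python library
and CLI, together with a synthetic-data generator that produces every
input with known ground truth, so the whole pipeline is verifiable
end-to-end without downloading any metagenome.

## The core operations

* **Contig QC** — retention iff (completeness ≥ 50, viral genes > 0,
  viral > 3× host genes) or (length ≥ 20 kb, completeness ≥ 40, viral > 0,
  viral > 3× host); DTR/ITR detection by exact border/longest-common-prefix
  algorithms; quality tiers complete/high/medium/low.
* **Species clustering** — merged-local-alignment ANI
  (ANI = Σ pidentᵢ·lenᵢ / Σ lenᵢ, coverage from interval unions) and
  greedy, longest-first centroid clustering at `--min_ani 95
  --min_tcov 85 --min_qcov 0`; cross-catalog species overlap counts.
* **Rank clustering** — AAI from filtered protein best hits (E < 1e-5,
  ≥ 50% coverage both ways); genus graph at ≥ 20% shared genes & AAI ≥ 40,
  family at ≥ 10% & ≥ 20; in-repo MCL at inflation 2.0 (genus) / 1.2
  (family); VIRIDIC-like tANI single-linkage clustering at 95/70.
* **Abundance** — SAM read recruitment at identity ≥ 90%, aligned
  fraction ≥ 75%, genome breadth ≥ 75% (below breadth: exactly 0).
* **Ecology** — richness, per-region core viromes (25/50/75%
  prevalence), random-permutation accumulation curves, Bray–Curtis,
  one-way PERMANOVA (pseudo-F, R², permutation p), PCoA, Wilcoxon /
  Kruskal–Wallis with tie corrections, host-group aggregation, NB
  richness ~ breed × diet regression.
* **Synthetic data** — hierarchically diverged lineages with designed
  within-rank divergence, decorated contigs, alignment and protein-hit
  tables, region-stratified communities with host-family niches, and
  seeded error-bearing reads as SAM.

See `docs/methods.md` for the full model description and the numerical
conventions.

## Worked example

Evolve a small lineage (2 families × 2 genera × 3 species × 2 variants),
align all pairs, and dereplicate at the species thresholds:

```python
from votuforge.synthetic_data import LineageSpec, evolve_lineages, emit_alignments
from votuforge.species_clustering import compute_pair_anis, greedy_cluster

spec = LineageSpec(n_families=2, genera_per_family=2, species_per_genus=3,
                   variants_per_species=2, genome_len_range=(5000, 8000))
genomes, truth = evolve_lineages(spec, seed=17)
lengths = {g.id: g.length for g in genomes}
pairs = compute_pair_anis(emit_alignments(genomes), lengths)
clusters = greedy_cluster(lengths, pairs, min_ani=95.0, min_tcov=85.0)
print(f"{len(genomes)} genomes -> {len(clusters)} species-level vOTUs "
      f"(designed: {spec.n_species})")
```

which prints

```
24 genomes -> 12 species-level vOTUs (designed: 12)
```

— the 24 genomes collapse exactly onto the 12 designed species. A
within-species pair reports, e.g.,

```
within-species pair fam00.gen00.sp00.v0 vs fam00.gen00.sp00.v1: ANI 97.70, qcov 100.0%, tcov 100.0%
```

consistent with the designed 2% within-species divergence: ANI ≈ 97.7
clears the 95% species threshold while full reciprocal coverage clears
the 85% aligned-fraction requirement.

The same steps are available from the shell:

```
votu-forge simulate --preset small --seed 17 --out fixtures/
votu-forge qc --qc-table fixtures/contigs.qc.tsv --genomes fixtures/contigs.fasta --out kept.tsv
votu-forge ani --aln fixtures/alignments.tsv --genomes fixtures/contigs.fasta --out ani.tsv
votu-forge cluster-species --ani ani.tsv --genomes fixtures/contigs.fasta --out clusters.tsv
```

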