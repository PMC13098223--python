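# Methods

`votuforge` re-implements, as a tested and reusable pipeline, the
computational core of large-scale gut-virome catalog construction: how a
heap of putative viral contigs becomes a dereplicated, rank-structured,
quantified catalog, and how community-level conclusions are drawn from it.
This note documents the models and procedures, the parameters that matter,
the numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Contig quality control

**Retention rules.** A contig enters the catalog iff

* RULE-A: completeness ≥ 50%, viral genes > 0, viral genes > 3 × host
  genes; or
* RULE-B: length ≥ 20,000 bp, completeness ≥ 40%, viral genes > 0, viral
  genes > 3 × host genes.

The completeness/contamination/gene-count estimates are inputs (a
CheckV-style summary table); only the filter logic and the terminal-repeat
detection are computed here. Records with *absent* completeness are
rejected rather than guessed, because both rules condition on it; absence
is represented as `None`, never as 0. The ratio clause is strict
(`viral > 3 × host`), so 6 viral / 2 host genes fails. Rejected records
carry the first failed clause as a machine-readable reason.

**Terminal repeats.** A direct terminal repeat (DTR) is a prefix of length
≥ `min_repeat_len` (default 20 bp) repeated as the suffix, in the same
orientation; an inverted terminal repeat (ITR) is a prefix whose reverse
complement is the suffix. Repeats are required to be *strictly terminal*
(start at base 0, end at the final base) — the simplest reading of the
closed-genome convention — and may cover at most half the sequence. With
the default `max_mismatches = 0` the search is exact and linear-time: DTR
candidates are precisely the borders of the sequence (Knuth–Morris–Pratt
failure function, following the border chain down to ≤ n/2), and the ITR
length is the longest common prefix of the sequence and its reverse
complement. A mismatch-tolerant configuration falls back to a
descending-length scan (quadratic, intended for small inputs). DTR takes
precedence when both qualify. Provirus boundary calls are trusted from the
input QC table; no provirus detection is re-implemented.

**Tiers.** Retained contigs are tiered: `complete` whenever a closure
signal (DTR/ITR/provirus) is present, regardless of the completeness
estimate; else `high` (≥ 90%), `medium` (≥ 50%), `low` (< 50%, reachable
only through RULE-B).

## Species-level dereplication (vOTUs)

Pairwise ANI is computed from a 12-column local-alignment table by
*combining* the alignments of each ordered genome pair: ANI is the
alignment-length-weighted mean of per-alignment identities, and coverage
on each genome is the merged (union) span of its alignment intervals
divided by its length. Overlapping alignments are merged only for
coverage, never for the identity weighting. Self-hits are excluded before
weighting. External coordinates are 1-based inclusive; all interval
arithmetic is 0-based half-open, converted exactly once at the I/O
boundary. Minus-strand rows are normalized at parse time to ascending
target coordinates with a strand flag; coverage ignores strand. Pairs
absent from the alignment table are treated as ANI 0 — no transitivity is
assumed.

Clustering is greedy and CD-HIT-like: genomes sorted by descending length
(ties: ascending id, which makes the output invariant to input row order),
each genome joining the earliest-founded centroid with ANI ≥ 95 and
coverage ≥ 85% **of the shorter of the two sequences** — the MIUViG
species criterion as worded, rather than strict target-coverage semantics
(a `coverage_of="target"` switch restores the latter). The result is a
partition; membership is certifiable post hoc (every member re-checks
ANI ≥ 95 / shorter-coverage ≥ 85 against its centroid).

Cross-catalog overlap clusters the union of two catalogs at the species
thresholds and counts clusters containing members of both; colliding ids
are refused with instructions to prefix.

## Genus and family rank clustering

Average amino-acid identity (AAI) between two genomes is the unweighted
mean percent identity over shared protein best hits, after filtering hits
at E-value < 1e-5 and ≥ 50% query and subject coverage. Best hits are
unidirectional — one hit per (query protein, target genome), ties broken
by lower E-value, then higher identity, then lexicographic target — taken
from the queries of the smaller-gene-count genome and emitted once per
unordered pair. The shared-gene fraction uses the smaller per-genome gene
count as denominator, which keeps fragments comparable to full genomes.

Rank graphs keep edges at ≥ 20% shared genes and ≥ 40% AAI (genus) or
≥ 10% and ≥ 20% (family), weighted by AAI, and are partitioned with an
in-repo Markov Clustering implementation: self-loops at each node's
maximum incident edge weight, column-stochastic normalization, then
alternating expansion (matrix squaring) and inflation (elementwise power
then renormalization) with pruning of entries < 1e-5, to a tolerance of
1e-6 within 100 iterations (non-convergence returns the current
interpretation with a warning). Inflation is 2.0 for genus and 1.2 for
family. Clusters are read off as connected components of the converged
matrix's support; isolated nodes are singletons. The procedure is fully
deterministic given graph and parameters.

**tANI clustering.** For the VIRIDIC-like comparison route, total ANI
discounts ANI by the aligned genome fraction. The exact discount is an
explicit assumption (the convention is not uniquely fixed in the
literature): the default is `tani = ani × (qcov + tcov)/2 / 100`, which is
symmetric in genome length; `ani × min(qcov, tcov)/100` is available as a
stricter alternative. Species (95%) and genus (70%) partitions are
single-linkage connected components; the species partition refines the
genus partition by construction.

## Read-recruitment abundance

Only mapped, primary SAM records contribute. Per read: identity =
100 × (columns − NM)/columns with columns = M/=/X + I + D (consistent with
the edit distance; an M-only denominator is available as a flag), and
aligned fraction = aligned read bases (M/=/X + I) over the *full* read
length including soft clips. Defaults follow viral community-profiling
practice: identity ≥ 90, aligned fraction ≥ 75. Filter order is read
filters first, then per-genome breadth (percent of positions covered by
≥ 1 passing read, computed by interval union); genomes under 75% breadth
are zeroed exactly, suppressing spurious detections from conserved
regions. Abundance is recruited reads over total sample reads; a
within-virome normalization (recruited-read fractions) is what the
composition statistics consume, and both are available because the choice
is not fully determined by convention.

## Ecology layer

* **Richness / prevalence / core virome** — presence is abundance
  strictly > 0 after the breadth filter. Core viromes are computed per gut
  region with region-only denominators, at prevalence thresholds
  0.25/0.50/0.75.
* **Accumulation curves** — random-permutation scheme (1,000 permutations
  by default): cumulative distinct vOTUs per step, mean ± sd across
  permutations. The final mean equals the total distinct count for every
  seed.
* **Bray–Curtis** — Σ|x−y| / Σ(x+y); all-zero sample pairs get distance 0.
* **PERMANOVA** — one-way, distance-based: SS_total = Σ_{i<j} d²/n,
  SS_within from within-group pairs, pseudo-F = (SS_B/(k−1))/(SS_W/(n−k)),
  R² = SS_B/SS_total, p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under free
  label permutation (no strata), default 999 permutations, mandatory seed.
* **PCoA** — classical scaling of the Gower-centered squared-distance
  matrix; axes ordered by eigenvalue, negative eigenvalues reported and
  their axes dropped.
* **Rank tests** — Wilcoxon rank-sum: exact enumeration (shift-algorithm
  recursion) for pooled n ≤ 25 without ties, otherwise the tie-corrected
  normal approximation with continuity correction; zero-variance data
  returns p = 1. Kruskal–Wallis with tie correction. Pairwise p-values are
  reported raw and Holm-adjusted (the adjustment choice is not dictated by
  convention; both are emitted).
* **Host-group aggregation** — per-sample abundances summed over vOTUs
  sharing the best-score predicted host taxon at family or genus rank;
  unassigned vOTUs pool into `no_host`; per-sample totals are conserved.
* **NB richness model** — negative-binomial regression (log link) of
  richness on breed, diet and their interaction, dispersion estimated by
  maximum likelihood (statsmodels); if the fit collapses toward the
  Poisson limit or fails to converge, a Poisson GLM is used with a
  warning. The "breed rate ratio" reported in benchmarks is the marginal
  (diet-averaged) contrast, exp(β_breed + ½ β_interaction).

## Synthetic data: what it emulates

The generator produces every input with ground truth, as a pure function
of (spec, seed):

* **Lineages** — family roots i.i.d. uniform over {A,C,G,T}; descendants
  mutated from parents at half the rank's designed *pairwise* divergence,
  so sibling taxa land at the specified distance in expectation. Small
  indels run at one tenth of the substitution rate with geometric(0.5)
  lengths — enough to exercise gap handling while keeping oracle
  alignment tractable. Defaults: 4 families × 2 genera × 5 species × 3
  variants (120 genomes, 40 species), pairwise divergences
  0.02/0.15/0.30 at species/genus/family, genome lengths 10–20 kb —
  phage-scale genomes small enough that all-vs-all alignment of the full
  default catalog runs in seconds on one core.
* **Contigs** — designed tier mixture (default 20/25/45/10% for
  complete/high/medium/low), truncation to the drawn completeness,
  DTR/ITR decoration (25–60 bp) or table-borne provirus calls for the
  complete tier, and gene counts consistent with the retention rules.
* **Alignments** — candidate pairs pre-filtered by k-mer containment
  (estimated identity = containment^(1/k) ≥ 0.70), then aligned
  end-to-end by edit-distance DP (edlib) in `oracle` mode, or by the
  built-in exact-seed/ungapped-extension aligner in `kmer` mode. The
  built-in aligner exists so tests run without an external alignment
  tool; it is not a general-purpose aligner.
* **Protein hits** — generated directly as hit tables with designed
  identity and sharing distributions per rank relationship (translation
  and protein search are not simulated; the AAI stage consumes hit
  tables, not proteomes).
* **Communities** — region-stratified host-family mixtures
  (Lactobacillaceae-weighted proximal regions, Lachnospiraceae/
  Bacteroidaceae/Ruminococcaceae-weighted distal) with multiplicative
  gamma noise, a configurable viral read fraction (default 1.5%), and
  uniform-position 150 bp reads with i.i.d. substitution errors, emitted
  as primary-only SAM (M-only CIGARs plus NM, the most common mapper
  dialect); non-viral reads appear as unmapped records.

**What passing the benchmark does not show.** The generator has no
sequencing-quality model, no coverage bias, no chimeric or misassembled
contigs, no strain mixtures within a species beyond the substitution
model, and its protein fixtures bypass gene calling entirely. Recovery of
designed quantities therefore validates the *pipeline logic* — filters,
interval arithmetic, clustering, thresholds, statistics — not robustness
to the failure modes of real assemblies or real aligners.

## Benchmark problem sizes

The shipped checks use desk-scale designs chosen to make each property
sharp: the default 120-genome lineage for species-cluster recovery;
50 alignment pairs of 2–5 kb against a Needleman–Wunsch oracle; 30-node
planted-partition graphs for MCL (against an independent textbook
implementation); 50,000-read single-sample communities for proportion
recovery; 200-replicate null simulations for PERMANOVA calibration;
100-replicate parameter-recovery runs for the NB model (30 samples per
breed × diet cell, dispersion 0.3 — at these conditions the marginal
rate-ratio estimator's standard error is ≈ 0.10 on the log scale, so the
[1.3, 1.7] recovery band is expected to capture ≈ 80% of replicates);
and a 40-sample, two-region community for the end-to-end host-niche
check. `scripts/acceptance.py` re-runs the same designs from a single
seed.
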