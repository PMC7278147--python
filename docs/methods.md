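# Methods

This note records the models, parameter choices, and numerical
conventions behind `strainscope`, and what the synthetic data used by
the test suite can and cannot establish about behavior on real
metagenomes.

## Synthetic populations

`simulate.simulate_population` draws a multi-subspecies bacterial
population whose pairwise distance structure is controlled exactly.

**Substitution model.** Sites evolve independently under Jukes–Cantor.
Target pairwise divergences *d* are converted to branch lengths
*t* = −(3/4)·ln(1 − 4d/3), which are additive along paths, so the
expected hamming distance between two genomes is the JC transform of
their path length. The topology is a star of subspecies ancestors
hanging off a common root; per-subspecies root branches are solved by
least squares so that path lengths reproduce the requested
inter-subspecies matrix (exactly, when the matrix is additive — the
default matrix is constructed to be additive).

**Within-subspecies diversity: founder-lineage mosaics.** Genomes are
not independent tips of the subspecies ancestor. Each subspecies first
spawns `n_lineages` founder lineages (default 16) at branch length
t_f; each genome is then a block mosaic over those founders
(`block_length`, default 2 kb) plus a short private tip t_ε, with the
tip carrying `lineage_tip_share` (default 0.2) of the intra-subspecies
divergence and the founder layer calibrated by
2·t_f·(1 − 1/M) + 2·t_ε = t_intra. The mosaic makes intra-subspecies
distance clouds diffuse and non-treelike — the geometry that heavily
recombining gut species such as the motivating organism actually show —
which matters for clustering: on a pure star the clouds are
near-simplices, k-medoids isolates stable singleton medoids at k above
the true cluster number, and prediction strength never drops, so no
cluster-number selection rule could recover the planted k. With the
mosaic, splits beyond the planted subspecies are arbitrary between
train/test halves and prediction strength falls off above the true k,
as observed in real populations. Full recombination machinery
(breakpoint processes, donor tracts) is deliberately not modeled.

**Defaults as study conditions.** Four subspecies named after their
dominant geography, intra-subspecies divergences (1.38, 1.40, 1.90,
1.95)%, inter-subspecies divergences in 2.00–2.47% with the
Europe/Eurasia pair the closest; a 34-gene contiguous operon deleted in
all ErEurope genomes (and lost by ~2% of other genomes, mirroring rare
independent losses); a 49,668 bp island at GC 0.377 inserted at a fixed
intergenic locus in 21% of ErEurope genomes against a genome background
of GC 0.423, nearly identical across carriers (island tip divergence
0.004) as expected for a recent horizontal acquisition. The default
inter matrix is the spec of the observed band realized additively while
maximizing the minimum margin between any inter distance and the larger
of the two intra distances (margins ≥ 0.003); this keeps
nearest-medoid classification well-posed at realistic alignment lengths
without leaving the observed band.

**Gene maps.** Genes of equal length are separated by uniform spacers;
a configurable core fraction of non-operon genes is present in every
genome, accessory genes follow per-(gene, subspecies) Bernoulli rates
drawn once per simulation (U(0.6, 1) generally; U(0.2, 1) for the
operon-free subspecies, giving it the elevated gene-content turnover
seen in the data). Because genes contain no indels, the concatenated
core genes of all genomes are already a gapless alignment — the
pipeline's alignment consumers accept gap/N symbols, but the generator
never needs an aligner.

**What the generator does not emulate.** Read-level errors and quality
strings (pileups are generated post-filtering), assembly fragmentation
biases and chimeras, rearrangements and indels, reverse-strand contigs,
within-sample strain phylogenies beyond two-strain mixtures. Green
tests therefore demonstrate correctness of the decision rules and
estimators under their stated models, not robustness to assembler or
mapping artifacts.

## Alignment backend

All hit consumers work from BLAST-style tabular hits behind a small
adapter (FASTA pair in, hit list out), so blastn output can be dropped
in via `io.read_tabular_hits`. The bundled backend is a k-mer anchored
(k = 15, ≥ 2 anchors per diagonal), ungapped, forward-strand local
aligner: candidate diagonals are trimmed to their maximal-scoring
segment under the blastn default scoring (+2/−3) and scored with the
ungapped Karlin–Altschul bit/E-value formulas. Ungapped alignment is
exact for the generator's substitution-only sequences; it is not
intended for indel-rich real data, where blastn should be used.

## Binning

Multi-hit evidence aggregation is greedy by descending bit score (ties:
lower E-value, then input order): each hit contributes the query
interval not already covered, and mean identity is weighted by kept
segment lengths. Hits against all conspecific references are pooled.
The FP/FN surface scales base counts by the average reference genome
size; the selected grid cell minimizes max(median FP, median FN) with
ties broken toward higher identity, then higher fraction (specificity
over sensitivity). The coverage filter removes contigs below 20% of the
unweighted per-contig median coverage, computed before any removal.

## Heterogeneity statistic ρ

The denominator counts codons fully covered by retained (depth ≥ 10)
positions, matching the numerator's definition on translated sequences;
`denominator="positions"` switches to retained nucleotide positions for
sensitivity analyses. The second-dominant sequence substitutes the
second allele only at variant sites. Exact 50/50 allele ties are broken
lexicographically — a measure-zero event at real depths, fixed for
determinism. Gene lengths not divisible by three have trailing bases
ignored (logged).

## PAM and prediction strength

PAM uses deterministic greedy BUILD followed by best-improvement SWAP;
because single-swap descent can stall in a local optimum on
unstructured matrices, `pam_cluster` additionally restarts SWAP from 8
seeded random initializations and keeps the best local optimum (still
deterministic given the seed). Prediction strength follows the
cross-validation semantics of the reference R implementation: per
subsample (each genome kept with probability 0.5), the mean over 20
random 50/50 train/test divisions of the minimum over test clusters of
the co-assignment fraction; test clusters with fewer than two members
carry no pair information and are skipped; ps(1) = 1 by definition. The
selection rule is the largest k whose mean ps exceeds 0.8.

## Diagnostic SNVs and abundances

The "absent outside" condition is evaluated against the pooled
frequency across all other subspecies (not per-subspecies), and
columns containing any gap/N are excluded so panel positions map onto
unambiguous consensus coordinates. Abundance medians use only panel
positions with nonzero depth. QC gates: mean panel depth ≥ 5, ≥ 75% of
panel positions covered ≥ 3×, raw estimate sum within [0.75, 1.25];
passing samples are rescaled to sum to one.

## Elements

Operon presence calls filter hits at ≥ 75% of the gene length, ≥ 95%
identity and E < 1e−44, then keep the best hit per overlapping locus.
The border-based locator demands exactly two border hits on a single
contig (E < 1e−30). A genome "lacking" an operon set misses more than
20% of its genes, counted by genes. Island calls: full requires exactly
one hit covering ≥ 95% of the seed element; any shorter hit yields
partial. GC profiles use full windows only, report window centers, and
exclude ambiguity codes from numerator and denominator, so the first
window/2 bases at each end (10 kb at the default 20 kb window) are
never queried. Boundary discovery walks outward from the island span to
the first flanking gene that is a reciprocal best hit (≥ 95% identity
over ≥ 75% length) in every island-free genome.

## Geography and transmission

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km; specific pairs may be routed through waypoints (the
Africa–Asia default route crosses the Arabian peninsula) and the
distance is the sum of legs. The Mantel test is one-sided for positive
association with the +1 permutation correction; for n ≤ 7 all n!
permutations are enumerated and the p-value is the exact tail
proportion. nGD normalizes patristic distance by the median length over
all edges of the tree (not the median pairwise distance — the
alternative reading; switching would rescale all nGDs by a common
factor and leave threshold calls unchanged since the threshold is a
percentile of the same quantity). The transmission threshold is the 1st
percentile of unrelated-pair nGDs under linear interpolation between
order statistics; a dyad transmits when any timepoint falls below it.

## Mini-study sizes

The orchestrated mini-study defaults to 4 × 20 genomes of ~260 kb
(~150 kb concatenated core), 3 spike-tuning assemblies and 3 binned
samples, prediction strength over 8 subsamples × 5 divisions, and
completes in a few minutes on one CPU; the acceptance script uses 4 ×
30 genomes over a ~100 kb core alignment with the full 50 × 20
prediction-strength schedule. These sizes were chosen so that every
statistic is estimated at useful precision at desk scale; all counts
are configuration fields and scale up transparently.

## Known limitations

- The aligner is forward-strand and ungapped; real assemblies must be
  aligned externally (blastn) and imported.
- The marker-based completeness/contamination estimator treats markers
  as independent single-copy sequences; it is a simplified stand-in for
  lineage-aware marker-set tools, whose summary tables can be imported
  instead.
- Subspecies geography in the mini-study uses fixed representative
  locations; with four subspecies the exact Mantel p-value cannot fall
  below 1/24.
- Desk-scale genomes (~260 kb) make the 50 kb island a large fraction
  of the genome, so island carriers can fail the isolate-derived size
  window during QC; at real genome sizes (3.4 Mb) the island is ~1.5%
  of the genome and no such interaction exists.
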