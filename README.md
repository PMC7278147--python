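# strainscope

Species-targeted reconstruction of bacterial genomes from metagenomic
assemblies, and population-structure analysis of the reconstructed
genomes — subspecies delineation, subspecies abundance estimation,
functional divergence, operon-loss and genomic-island detection,
isolation by distance, and mother–infant strain transmission.

The package is written for microbiome researchers who want to study a
single prevalent gut species (the motivating case is *Eubacterium
rectale*) at whole-genome resolution using only shotgun metagenomes: a
few conspecific reference genomes are enough to pull species-specific
contigs out of thousands of single-sample assemblies, quality-control
the resulting genome bins, and run comparative genomics on them as if
they were isolate genomes.

## What it computes

**Reference-based binning.** A contig is assigned to the target species
when it aligns against the reference set with a length-weighted mean
identity ≥ *I* over ≥ *F* of its length (defaults *I* = 95%, *F* = 50%).
Thresholds are tuned on semi-synthetic spike-in assemblies: fragments of
known genomes are dropped into species-free assemblies and false
positive / false negative bases are counted per grid cell, scaled by the
average reference genome size.

**Genome QC.** Single-copy-marker completeness and contamination, size
and contig-count windows, and a polymorphism-based strain-heterogeneity
statistic ρ: from a quality-filtered pileup, the dominant and
second-dominant allele per coding position are called (positions with
depth < 10 dropped; a position is a variant when the dominant allele is
≤ 80% of its coverage), both implied gene sequences are translated, and
ρ = (codons whose two translations differ) / (fully covered codons). A
high-quality genome has completeness > 90%, contamination < 5%, size
within the isolate-derived window, < 400 contigs, and ρ < 0.3%.

**Subspecies delineation.** PAM (k-medoids) on pairwise hamming
distances over the concatenated core-gene alignment (gap/N columns
excluded pairwise), with the number of clusters chosen by prediction
strength: over random subsamples and 50/50 train/test divisions, ps(k)
is the minimum over test clusters of the fraction of within-cluster test
pairs that the training medoids co-assign; the selected k is the largest
with mean ps above 0.8.

**Subspecies abundances.** Diagnostic single-nucleotide variants
(alignment columns whose base occurs in > 90% of one subspecies and in
< 10% of the rest) are read out of a sample pileup; the abundance of a
subspecies is the median ratio of diagnostic-allele depth to total depth
over its panel, with depth/breadth/sum-of-estimates QC gates, rescaled
to sum to one.

**Mobile and deletable elements.** Operon gene presence from filtered
alignment hits (≥ 75% of gene length, ≥ 95% identity, E < 1e−44) and
physical operon location between bordering genes; genomic-island calls
from a seed sequence (full = a single hit ≥ 95% of the seed), island
boundaries from the first flanking genes orthologous between carriers
and non-carriers, and rolling-window GC profiles (window 20 kb, step 10)
that expose the island's atypical GC content.

**Biogeography and transmission.** Great-circle distances between
subspecies' representative locations (optionally routed via waypoints)
against median inter-subspecies genetic distances with a Mantel
permutation test (exact enumeration for small n); vertical transmission
called when a mother–infant pair's normalized genetic distance (patristic
distance / median tree branch length) falls below the 1st percentile of
the unrelated-pair distribution.

Every analysis runs end-to-end on synthetic populations produced by
`strainscope.simulate`, which plants four subspecies with realistic
intra/inter divergences (~1.4–1.95% / 2.0–2.5%), a multi-gene operon
deleted wholesale in one subspecies, and a ~50 kb genomic island at GC
37.7% against a 42.3% background.

## Worked example

Delineate subspecies on a synthetic population:

```python
import numpy as np
from strainscope import (
    CoreAlignment, PopulationSimSpec, hamming_distance,
    prediction_strength, select_k, simulate_population, pam_cluster,
)

spec = PopulationSimSpec(
    n_genomes_per_subspecies=(15, 15, 15, 15),
    n_genes=80, gene_length=600, ancestral_length=56_000,
    island_present_in=None, operon_deleted_in=None, seed=9,
)
pop = simulate_population(spec)
labels, rows = pop.core_alignment()
dist = hamming_distance(CoreAlignment(labels, rows))
ps = prediction_strength(dist, range(1, 7), n_subsamples=10,
                         internal_divisions=8, seed=0)
for k in ps:
    print(f"k={k}  mean ps = {np.mean(ps[k]):.3f}")
print("selected k =", select_k(ps))
```

prints

```
k=1  mean ps = 1.000
k=2  mean ps = 0.634
k=3  mean ps = 0.572
k=4  mean ps = 0.938
k=5  mean ps = 0.596
k=6  mean ps = 0.499
selected k = 4
```

ps(1) is 1 by definition; partitions at k = 2, 3, 5 and 6 are unstable
across train/test divisions (splitting or merging the planted groups is
arbitrary), while the four planted subspecies are re-discovered in
essentially every division, so the largest-k-above-0.8 rule selects
k = 4. `pam_cluster(dist, 4)` then reproduces the planted subspecies
labels exactly.

The whole pipeline — simulate, spike, tune, bin, QC, distances,
subspecies, abundances, operon/island, geography, transmission — runs as
one command and writes every stage table plus a scalar summary:

```bash
strainscope run-mini-study --seed 7 --out runs/demo
```

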