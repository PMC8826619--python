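# Methods

This note documents the statistical procedures, the synthetic-data model and
the numerical choices behind `retropop`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The central object is the presence matrix: retroCNV insertion alleles × 
individuals, binary carrier status. Presence is per individual — the
underlying discovery pipelines detect an insertion junction without resolving
heterozygous vs homozygous carriers — so every statistic here treats
carriership as a 0/1 trait. Fixed alleles (carried by every individual) are
excluded by construction; a data set of segregating insertions cannot contain
them, and the constructor enforces this.

Coordinates follow BED convention for interval files (0-based half-open) and
VCF convention for SNPs (1-based). An insertion is located by the midpoint
`floor((start+end)/2)` of its estimated insertion interval. Missing SNP
genotypes are encoded as −1 and deleted pairwise per statistic; nothing is
imputed, the smallest-assumption default for low-coverage wild-caught
samples.

## Frequency groups and enrichment

Carrier counts over the whole cohort partition markers into low (= 1,
singletons), intermediate (2–5) and high (≥ 6) frequency groups. Singletons
represent the youngest insertions and serve as the baseline retroposition
pattern; enrichment of X-chromosomal parental genes among high-frequency
markers is the within-species analogue of the classic out-of-X retrogene
excess attributed to adaptive compensation of meiotic sex chromosome
inactivation.

The X-origin null is the genome-wide share of multi-exon (≥ 2 exon)
protein-coding genes on the X; significance uses Fisher's exact test,
two-sided by default (sidedness is configurable) both against the gene-count
margin and between pairs of groups. Element-overlap analysis enlarges each
insertion to a 500 bp interval (250 bp each side of the midpoint) and tests
≥ 1 bp overlap against each annotation category *independently* — a retroCNV
inside an intron also counts for the enclosing gene, and CDS/UTR are subsets
of exon, the only consistent reading of nested categories. "Intergenic" is
computed as the complement of protein-coding gene spans, never read from a
file.

## Sweep scan

Three classic signatures of a recent selective sweep at the insertion among
carriers:

* π ratio: region-wide per-bp nucleotide diversity of carriers over
  non-carriers across the ±50 kb flank. Per-site π with j alternate alleles
  among k non-missing chromosomes is `2j(k−j)/(k(k−1))`; windowed π divides
  the per-window sum by window length in bp (10 kb windows, 5 kb step for
  track output). Monomorphic-site accessibility masking is not modelled.
* Tajima's *D* among carriers over the same ±50 kb region, computed once on
  the whole region by default (a per-window mode exists; the single-region
  convention was chosen because the flank is the unit the eligibility filter
  reasons about). The sample size n entering the canonical constants is the
  rounded mean non-missing chromosome count over usable sites; sites with
  < 4 non-missing chromosomes are skipped, and *D* is undefined — never 0 —
  when S = 0 or the variance term vanishes.
* Mean genotype *r*² among carriers over ±5 kb: squared Pearson correlation
  of unphased dosage vectors over all defined pairs. Genotype (not
  haplotype) correlation is the default because wild-cohort genotypes are
  unphased.

Eligibility, per focal subspecies: present in ≥ 50 % of individuals of
*every* population of the subspecies; present and absent in ≥ 3 individuals
of that subspecies; ≥ 1 flanking SNP. The subspecies needs ≥ 2 populations
for the first rule to be meaningful.

The null distribution drops the *same* carrier/non-carrier labels onto 100
pseudo insertion sites drawn uniformly over the usable autosomal base pairs —
non-gap positions whose ±50 kb flank stays inside the chromosome — so each
chromosome receives draws in proportion to its usable length. Significance
per statistic is the add-one empirical tail probability
`p = (1 + #{background at least as extreme}) / (1 + n_background)`, with
"extreme" meaning ≤ for π ratio and *D*, ≥ for LD; ties count as extreme. A
marker is called positively selected when all three p-values are < 0.05. A
rank-sum mode (one-sided Mann–Whitney of the focal flank's window-level
values against pooled background windows) is provided as an alternative; a
rank-sum test of a single scalar against 100 scalars is not well-formed, so
the empirical tail is the default. A complete-linkage report lists flanking
variants with *r*² = 1 to the carrier vector (expected empty when the
insertion itself is the selected variant).

## Population differentiation index

For a polymorphic marker, `PDI = 1 − Σ F_i P_i(1−P_i) / (P(1−P))` — one
minus the ratio of size-weighted within-population binomial variance to
total variance. It is 0 when all populations share one frequency, 1 when the
marker is fixed or absent within each population, and lies in [0, 1] for any
configuration because `P = Σ F_i P_i` makes the within-population variance a
Jensen lower bound of the total. Markers with overall frequency 0 or 1 are
untestable (undefined, reported as NaN).

The null shuffles individual labels (1,000 permutations by default) keeping
population sizes fixed; one shared permutation schedule scores all markers
per replicate (cheaper and valid; a per-marker mode exists). p-values use
the add-one estimator, and Benjamini–Hochberg step-up at FDR ≤ 0.05 flags
differentiation markers.

## Population structure

Individual distance is the fraction of markers with differing carrier
status (normalised Hamming). PCA operates on the column-centred presence
matrix, optionally restricted to one subspecies. The population tree is
neighbor joining (via scikit-bio) on Euclidean distances between
per-population presence-fraction vectors; negative branch lengths are
clamped to zero with the deficit moved to the adjacent branch. Split
confidence comes from resampling markers (characters) with replacement,
rebuilding the tree, and counting recovery of each original split over
1,000 replicates; splits ≥ 80 % are flagged high-confidence. The SNP
comparison tree uses the per-population fraction of individuals carrying the
derived allele (dosage ≥ 1; heterozygous and homozygous count equally) after
greedy LD pruning (remove the later site of any pair with *r*² ≥ 0.2 in
500-SNP windows advancing by 100).

A caveat on bootstrap supports under no structure: the character bootstrap
is conditional on the realised sampling noise, so with exchangeable
populations an occasional noise-induced split can still appear stable
(about 5 % of splits reach 80 % in our exchangeable-null simulations, and
exactly identical spectra give an arbitrary but fully "supported" tie-broken
topology). Supports quantify stability under marker resampling, not
evidence against exchangeability.

## Synthetic cohort generator

The generator emulates the wild house mouse cohort design the analysis
targets: 96 individuals in nine
populations (IR, FR_C, FR_A, GE — *M. m. domesticus*; AF, KA, CZ —
*M. m. musculus*; IN, TA — *M. m. castaneus*), sized 11/11/11/11/11/11/10/10/10.

* **Marker frequencies.** Ancestral frequency p per marker from a
  configurable law, default Beta(0.25, 3.5); population frequencies from a
  Balding–Nichols Beta around p with differentiation F (default 0.2), i.e.
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `Var(p_i) = F·p(1−p)`. F = 0 is the
  exact panmictic limit. An optional hierarchical mode first draws a
  subspecies frequency (F = `fst_subspecies`) and then populations within it,
  which is what creates recoverable subspecies clades. The Beta default was
  chosen once so the default cohort's three-group split (~0.50/0.17/0.33) is
  singleton-heavy like real retroCNV spectra; the Balding–Nichols law is
  bimodal at the extremes and therefore under-fills the intermediate class
  relative to real data.
* **Presence sampling.** Each individual carries a marker independently with
  its population's frequency. All-ones and all-zero rows are redrawn (a
  segregating data set contains neither); after 100 failed redraws one entry
  is flipped, which only triggers at frequency extremes.
* **Flanking haplotypes.** Segregating sites are placed by a Poisson process
  whose density is calibrated so expected π/bp equals `theta_per_bp`
  (default 0.002, wild-mouse-like); allele frequencies follow the 1/j
  neutral law truncated at the sample size; genotypes are binomial draws —
  sites are unlinked under neutrality, so the neutral background mean r²
  equals the finite-sample floor ≈ 1/(n−1).
* **Sweep model.** Within `sweep_core_bp` (default 40 kb) of the midpoint,
  each carrier *haplotype* copies a single founder haplotype with
  probability `φ = 1 − sweep_strength^(−1/2)` and mutates off it at residual
  per-site rate `1/(2·sweep_strength)`; the founder-copy count is shared
  across sites within an individual. Strength 1 gives φ = 0, i.e. exactly
  the neutral model. This incomplete-sweep mixture was chosen deliberately:
  complete founder copying would leave only mutually independent residual
  singletons among carriers, which *lowers* mean r² below the neutral
  floor — haplotype-frequency structure is required for all three signals
  (core π ratio, negative carrier *D*, elevated carrier r²) to co-occur.
  The default strength 50 is a calibration choice; no effect sizes are
  reported for real sweeps at this scale.

What the generator does **not** model: linkage between flanking sites under
neutrality (no recombination map, no coalescent genealogy), ascertainment of
insertion calls, genotyping error or missingness, gene flow between
populations, and any correlation between marker frequency and genomic
location. Passing tests therefore demonstrate correctness of the statistics
and power under idealised signals, not performance on real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run at the cohort scale above where cheap
(96 individuals, 500–2,000 markers, 1,000 permutations, 100 pseudo-site
backgrounds, 1,000-marker flanks) and at 20 replicates for power/type-I
summaries. NJ tie-breaks are deterministic; bootstrap and permutation
schedules are seeded. The p-value uniformity check uses the
Kolmogorov–Smirnov distance with a 0.1 bound, accommodating the 1/1001
discreteness of add-one permutation p-values at 500 markers. Empirical
p-values never reach 0 by construction; quantities that are undefined
(monomorphic PDI, S = 0 Tajima's *D*, zero-variance r²) propagate as NaN and
are excluded, never coerced to 0.

## Known limitations

* The eligibility filter's "≥ 50 % in every population" rule assumes
  complete population sampling; small populations make it noisy.
* Tajima's *D* with heavy, site-varying missingness uses one averaged n; a
  fully per-site treatment would need a different normalisation.
* PDI ignores haplotype information and weights populations by sample size,
  inheriting sample-size imbalance as real differentiation would.
* The SNP comparison tree requires derived-allele orientation upstream;
  unoriented sites must be excluded before the spectrum is built.
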