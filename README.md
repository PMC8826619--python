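# retropop

Population-genetic analysis of **polymorphic gene retrocopies (retroCNVs)** —
reverse-transcribed mRNA copies of multi-exon parental genes inserted at new
genomic locations, present in some individuals of a cohort and absent in
others. The package targets the study design of wild house mouse cohorts
(96 diploid individuals, nine natural populations, three subspecies) but works
on any presence/absence table of insertion alleles with SNP genotypes for the
flanking regions.

## What it computes

Given a retroCNV presence matrix **X** (markers × individuals, 0/1), SNP
dosages, genome annotation intervals and population metadata:

* **Frequency patterns** — partition into low (1 carrier), intermediate (2–5)
  and high (≥ 6) frequency groups; X-chromosome-origin excess per group
  against the multi-exon gene-count null (Fisher exact), the population-level
  analogue of the "out-of-X" retrogene pattern; genomic-element overlap
  fractions for the 500 bp midpoint-centred insertion interval.
* **Parental-gene characterisation** — expressed fraction (FPKM > 0) and
  expression level of parental genes vs a bootstrap-resampled multi-exon gene
  control; recurrence (≥ 2 insertion alleles) vs expression; phylostratum
  (gene-age) excess.
* **Positive-selection scan** — for each eligible retroCNV, three statistics
  around the insertion midpoint:
  π ratio = π(carriers)/π(non-carriers) over ±50 kb, Tajima's *D* among
  carriers over ±50 kb, and mean genotype *r*² among carriers over ±5 kb.
  The null drops the same carrier labels onto 100 random autosomal, gap-free
  "pseudo" insertion sites; a marker is called selected when all three
  statistics beat the background at *p* < 0.05 (add-one empirical tail).
* **Population differentiation index (PDI)** — for a binary marker with
  overall frequency *P*, population frequencies *P<sub>i</sub>* and relative
  sizes *F<sub>i</sub> = N<sub>i</sub>/ΣN<sub>i</sub>*:

  PDI = [ *P*(1−*P*) − Σ<sub>i</sub> *F<sub>i</sub>P<sub>i</sub>*(1−*P<sub>i</sub>*) ] / [ *P*(1−*P*) ]

  a fixation-index-equivalent in [0, 1], tested by shuffling individual
  labels (1,000 permutations, population sizes fixed) with BH-FDR control.
* **Population structure** — pairwise individual distances (fraction of
  differing retroCNVs), PCA of the presence matrix, and neighbor-joining
  trees over the per-population presence-fraction spectrum (Euclidean
  distance, 1,000 marker-bootstrap replicates, splits ≥ 80 % flagged), plus a
  comparison tree from LD-pruned derived-SNP carrier fractions.
* **Synthetic cohorts** — a Balding–Nichols generator (optionally
  hierarchical: subspecies, then populations) for presence matrices, plus
  neutral or swept SNP flanks, so the whole pipeline runs with no external
  data.

## Worked example

```python
from retropop import SimConfig, simulate_cohort, DifferentiationTest, PopulationTree
from retropop.frequency import assign_frequency_groups

cfg = SimConfig(seed=1, n_markers=500, fst=0.05, fst_subspecies=0.2)
presence = simulate_cohort(cfg)
print(assign_frequency_groups(presence).counts())

fit = DifferentiationTest(presence).fit(n_perm=1000, alpha=0.05, seed=1)
print(fit.summary())
```

prints

```
{'low': 300, 'intermediate': 56, 'high': 144}
Population Differentiation Index (PDI) permutation test
========================================================
retroCNV markers:        500
testable (polymorphic):  500
permutations:            1000
FDR threshold:           0.05
differentiation markers: 82 (16.4% of all markers)
median PDI:              0.0905
```

Half the markers are singletons (the generator's skewed ancestral-frequency
law), and 82 markers carry enough between-population frequency contrast to be
flagged as differentiation markers at FDR ≤ 0.05 under this mild structure
(population-level F = 0.05 nested in subspecies-level F = 0.2).

```python
tree = PopulationTree(presence).fit(n_boot=500, seed=1)
print(tree.newick())
```

yields a Newick tree whose internal labels are bootstrap percentages; with
the hierarchical simulation above, the *M. m. musculus* clade (AF, KA, CZ)
and the *M. m. castaneus* clade (IN, TA) are each recovered with 100 %
support, while the within-subspecies French/German splits stay weak — the
same qualitative picture expected of closely related populations.

A command-line layer mirrors the library:

```bash
retropop simulate --out bundle/ --seed 1
retropop pdi --presence bundle/presence.tsv --meta bundle/metadata.tsv \
    --n-perm 1000 --seed 1 --out pdi.tsv
retropop tree --presence bundle/presence.tsv --meta bundle/metadata.tsv \
    --n-boot 1000 --seed 1 --out tree.nwk
```

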