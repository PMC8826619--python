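"""Core domain containers for retroCNV population analysis.

A retroCNV is a polymorphic gene retrocopy: a reverse-transcribed mRNA copy of
a multi-exon parental gene inserted at a new genomic location, present in some
individuals of a cohort and absent in others.  The central object is the
:class:`PresenceMatrix`, a binary retroCNV x individual carrier matrix; around
it sit SNP genotype dosages for flanking-region statistics and interval sets
for annotation overlap and gap avoidance.

Conventions
-----------
* Interval files (BED-style) are 0-based half-open; VCF positions 1-based.
* The insertion "site" used downstream is ``floor((start + end) / 2)`` of the
  estimated insertion interval.
* Presence is per individual (carrier yes/no), not per haplotype.
* Missing genotype dosages are encoded as -1 and excluded pairwise from each
  statistic, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class IndividualRecord:
    """One sampled individual with its population and subspecies assignment."""

    individual_id: str
    population_id: str
    subspecies_id: str


@dataclass
class RetroCNVRecord:
    """One retroCNV insertion allele.

    ``insertion_start``/``insertion_end`` delimit the estimated insertion
    interval (0-based half-open); ``midpoint`` is the downstream insertion
    site.  ``carrier_count`` is derived from the presence matrix row sum.
    """

    retrocnv_id: str
    parental_gene_id: str
    parental_chrom: str
    insertion_chrom: str
    insertion_start: int
    insertion_end: int
    carrier_count: int = 0

    def __post_init__(self) -> None:
        if self.insertion_start < 0 or self.insertion_start >= self.insertion_end:
            raise ValueError(
                f"retroCNV {self.retrocnv_id}: invalid insertion interval "
                f"[{self.insertion_start}, {self.insertion_end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.insertion_start + self.insertion_end) // 2


class PresenceMatrix:
    """Binary carrier matrix: rows = retroCNVs, columns = individuals.

    Fixed alleles (present in every individual) are excluded from the data-set
    definition; construction rejects all-ones rows unless ``allow_fixed``.
    """

    def __init__(
        self,
        individuals: list[IndividualRecord],
        retrocnvs: list[RetroCNVRecord],
        values: np.ndarray,
        allow_fixed: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (len(retrocnvs), len(individuals)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(retrocnvs)} retroCNVs, {len(individuals)} individuals)"
            )
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"non-binary presence value at retroCNV row {bad[0]}, "
                f"individual column {bad[1]}"
            )
        if not allow_fixed and values.size and values.all(axis=1).any():
            row = int(np.flatnonzero(values.all(axis=1))[0])
            raise ValueError(
                f"retroCNV {retrocnvs[row].retrocnv_id} is fixed (all carriers); "
                "fixed alleles are excluded from presence data sets"
            )
        ids = [ind.individual_id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual_id in cohort")
        rids = [r.retrocnv_id for r in retrocnvs]
        if len(set(rids)) != len(rids):
            dup = next(x for x in rids if rids.count(x) > 1)
            raise ValueError(f"duplicate retrocnv_id {dup!r}")
        self.individuals = list(individuals)
        self.retrocnvs = list(retrocnvs)
        self.values = values
        for rec, count in zip(self.retrocnvs, values.sum(axis=1)):
            rec.carrier_count = int(count)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_retrocnvs(self) -> int:
        return len(self.retrocnvs)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def retrocnv_ids(self) -> list[str]:
        return [r.retrocnv_id for r in self.retrocnvs]

    @property
    def carrier_counts(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def population_of(self) -> np.ndarray:
        return np.asarray([ind.population_id for ind in self.individuals])

    def subspecies_of(self) -> np.ndarray:
        return np.asarray([ind.subspecies_id for ind in self.individuals])

    def row(self, retrocnv_id: str) -> np.ndarray:
        idx = self.retrocnv_ids.index(retrocnv_id)
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.retrocnv_ids, columns=self.individual_ids
        )


@dataclass
class SNPMatrix:
    """Biallelic SNP dosages for one chromosome region.

    ``positions`` are 1-based and strictly increasing; ``dosages`` has shape
    (n_sites, n_samples) with values in {0, 1, 2} and -1 for missing.
    """

    chrom: str
    positions: np.ndarray
    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise ValueError("SNP positions must be strictly increasing")
        if self.dosages.shape != (self.positions.size, len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"({self.positions.size} sites, {len(self.sample_ids)} samples)"
            )

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "SNPMatrix":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in wanted]
        return SNPMatrix(self.chrom, self.positions, wanted, self.dosages[:, cols])

    def subset_region(self, start: int, end: int) -> "SNPMatrix":
        """Sites with 1-based position in [start, end]."""
        mask = (self.positions >= start) & (self.positions <= end)
        return SNPMatrix(
            self.chrom, self.positions[mask], list(self.sample_ids), self.dosages[mask]
        )

    @classmethod
    def empty(cls, chrom: str, sample_ids: Iterable[str]) -> "SNPMatrix":
        ids = list(sample_ids)
        return cls(chrom, np.empty(0, dtype=np.int64), ids, np.empty((0, len(ids)), dtype=np.int8))


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge 0-based half-open intervals; returns an (n, 2) array."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


class IntervalSet:
    """Per-chromosome sorted, merged 0-based half-open intervals."""

    def __init__(self, by_chrom: Mapping[str, np.ndarray] | None = None) -> None:
        self.by_chrom: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, arr in by_chrom.items():
                self.by_chrom[chrom] = merge_intervals(arr)

    def intervals(self, chrom: str) -> np.ndarray:
        return self.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def total_length(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else list(self.by_chrom)
        return int(
            sum((self.intervals(c)[:, 1] - self.intervals(c)[:, 0]).sum() for c in chroms)
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) has >= 1 bp overlap with any interval."""
        arr = self.intervals(chrom)
        if arr.size == 0:
            return False
        i = np.searchsorted(arr[:, 0], end)
        return bool((arr[:i, 1] > start).any())

    def chroms(self) -> list[str]:
        return list(self.by_chrom)


#: Assembly-gap intervals: regions to avoid when drawing pseudo insertion sites.
GapSet = IntervalSet

ELEMENT_CATEGORIES = (
    "intergenic",
    "protein_coding_gene",
    "intron",
    "exon",
    "CDS",
    "UTR",
)


class AnnotationSet:
    """Genomic element annotations by category.

    Intron/exon/CDS/UTR intervals come from protein-coding gene regions only;
    ``intergenic`` is the complement of protein-coding gene spans and is
    computed against a genome table rather than read from file.
    """

    def __init__(self, categories: Mapping[str, IntervalSet]) -> None:
        unknown = set(categories) - set(ELEMENT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
        self.categories = dict(categories)

    def get(self, category: str) -> IntervalSet:
        if category not in self.categories:
            raise KeyError(f"annotation category {category!r} not loaded")
        return self.categories[category]

    def with_intergenic(self, genome: "GenomeTable") -> "AnnotationSet":
        """Add the intergenic complement of protein_coding_gene spans."""
        genes = self.get("protein_coding_gene")
        inter: dict[str, np.ndarray] = {}
        for chrom, length in genome.lengths.items():
            spans = genes.intervals(chrom)
            gaps = []
            prev = 0
            for start, end in spans:
                if start > prev:
                    gaps.append((prev, start))
                prev = max(prev, end)
            if prev < length:
                gaps.append((prev, length))
            inter[chrom] = np.asarray(gaps, dtype=np.int64).reshape(-1, 2)
        cats = dict(self.categories)
        cats["intergenic"] = IntervalSet(inter)
        return AnnotationSet(cats)


@dataclass
class GenomeTable:
    """Chromosome lengths, multi-exon protein-coding gene counts, autosome flags.

    Gene counts (genes with >= 2 exons per chromosome) supply the null
    expectation for chromosomal-origin enrichment.
    """

    lengths: dict[str, int]
    multi_exon_gene_counts: dict[str, int]
    autosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        for chrom, count in self.multi_exon_gene_counts.items():
            if count < 0:
                raise ValueError(f"chromosome {chrom}: negative gene count")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosomes

    def gene_count(self, chrom: str) -> int:
        if chrom not in self.multi_exon_gene_counts:
            raise KeyError(f"chromosome {chrom!r} missing from genome table")
        return self.multi_exon_gene_counts[chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "length": [self.lengths[c] for c in self.chroms],
                "multi_exon_gene_count": [
                    self.multi_exon_gene_counts.get(c, 0) for c in self.chroms
                ],
                "is_autosome": [c in self.autosomes for c in self.chroms],
            }
        )
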