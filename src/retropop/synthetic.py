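"""Synthetic cohort generator: structured presence matrices, flanking
haplotypes with or without a linked sweep, and genome/annotation fixtures.

The generator emulates the cohort design the analysis modules target: 96
diploid individuals from nine natural populations spanning the three house
mouse subspecies (M. m. domesticus: IR, FR_C, FR_A, GE; M. m. musculus: AF,
KA, CZ; M. m. castaneus: IN, TA), with ~2,000 binary retroCNV markers whose
population frequencies follow a Balding-Nichols law around an ancestral
frequency, and per-insertion SNP flanks on which the sweep statistics run.

The sweep model is an incomplete hard sweep among carriers: within a core
around the insertion midpoint each carrier haplotype copies a single founder
haplotype with probability ``1 - sweep_strength**-0.5`` (zero at strength 1,
i.e. exactly neutral) and mutates off it at a residual per-site rate
``1/(2*sweep_strength)``.  Because the founder-copy indicator is shared
across sites within an individual, this produces the three advertised
signals at once: reduced carrier pi in the core, negative carrier Tajima's D
(excess rare and near-fixed variants), and elevated pairwise r^2 among
carriers.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import (
    GapSet,
    GenomeTable,
    IndividualRecord,
    IntervalSet,
    PresenceMatrix,
    RetroCNVRecord,
    SNPMatrix,
    AnnotationSet,
)

#: (population, subspecies, n individuals) — the nine surveyed wild mouse populations.
DEFAULT_POPULATIONS: tuple[tuple[str, str, int], ...] = (
    ("IR", "domesticus", 11),
    ("FR_C", "domesticus", 11),
    ("FR_A", "domesticus", 11),
    ("GE", "domesticus", 11),
    ("AF", "musculus", 11),
    ("KA", "musculus", 11),
    ("CZ", "musculus", 10),
    ("IN", "castaneus", 10),
    ("TA", "castaneus", 10),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``fst`` is the Balding-Nichols differentiation parameter (0 = panmictic
    limit); ``base_freq_distribution`` parameterises the ancestral marker
    frequency draw, either ("uniform", lo, hi) or ("beta", a, b);
    ``theta_per_bp`` is the expected per-bp pairwise diversity of the neutral
    flanks; ``sweep_core_bp``/``sweep_strength`` set the extent and intensity
    of the diversity reduction among carriers.
    """

    populations: tuple[tuple[str, str, int], ...] = DEFAULT_POPULATIONS
    n_markers: int = 2000
    fst: float = 0.2
    fst_subspecies: float = 0.0
    base_freq_distribution: tuple = ("beta", 0.25, 3.5)
    sweep_fraction: float = 0.0
    flank_length: int = 50_000
    theta_per_bp: float = 0.002
    sweep_core_bp: int = 40_000
    sweep_strength: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(size < 1 for _, _, size in self.populations):
            raise ValueError("all population sizes must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if not (0.0 <= self.fst_subspecies < 1.0):
            raise ValueError(
                f"fst_subspecies must be in [0, 1), got {self.fst_subspecies}"
            )
        if not (0.0 <= self.sweep_fraction <= 1.0):
            raise ValueError("sweep_fraction must be in [0, 1]")
        if self.sweep_core_bp > 2 * self.flank_length:
            raise ValueError(
                f"sweep_core_bp {self.sweep_core_bp} exceeds the "
                f"2 x flank_length = {2 * self.flank_length} simulated region"
            )

    @property
    def pop_sizes(self) -> list[int]:
        return [size for _, _, size in self.populations]

    @property
    def n_individuals(self) -> int:
        return sum(self.pop_sizes)

    def individuals(self) -> list[IndividualRecord]:
        out = []
        for pop, sub, size in self.populations:
            for i in range(size):
                out.append(IndividualRecord(f"{pop}_{i + 1:02d}", pop, sub))
        return out


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def _ancestral_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *params = config.base_freq_distribution
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=config.n_markers)
    if kind == "beta":
        a, b = params
        return np.clip(rng.beta(a, b, size=config.n_markers), 1e-6, 1 - 1e-6)
    raise ValueError(f"unknown base_freq_distribution kind {kind!r}")


def simulate_structured_frequencies(
    config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-marker, per-population frequencies under the Balding-Nichols law.

    For ancestral frequency p and differentiation F, each population's
    frequency is Beta(p (1-F)/F, (1-p) (1-F)/F), so that across populations
    E[p_i] = p and Var(p_i) = F p (1-p).  F = 0 returns p in every population
    (the panmictic limit).

    With ``fst_subspecies > 0`` the draw is hierarchical, mimicking the
    subspecies-then-population structure of the surveyed cohort: a subspecies
    frequency is drawn around p with F = fst_subspecies, then each population
    draws around its subspecies frequency with F = fst.  Populations of the
    same subspecies are then correlated, which is what makes subspecies
    clades recoverable in the population tree.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p = _ancestral_freqs(config, rng)
    n_pops = len(config.populations)

    def _bn(centre: np.ndarray, F: float, shape) -> np.ndarray:
        if F == 0.0:
            return np.broadcast_to(centre, shape).copy()
        scale = (1.0 - F) / F
        c = np.clip(centre, 1e-9, 1 - 1e-9)
        return rng.beta(c * scale, (1.0 - c) * scale, size=shape)

    if config.fst_subspecies > 0.0:
        subs = list(dict.fromkeys(s for _, s, _ in config.populations))
        p_sub = {
            s: _bn(p, config.fst_subspecies, (config.n_markers,)) for s in subs
        }
        cols = [
            _bn(p_sub[s], config.fst, (config.n_markers,))
            for _, s, _ in config.populations
        ]
        return np.column_stack(cols)
    return _bn(p[:, None], config.fst, (config.n_markers, n_pops))


def simulate_presence_matrix(
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    keep_monomorphic: bool = False,
    max_redraws: int = 100,
) -> PresenceMatrix:
    """Sample carrier status per individual from population frequencies.

    Rows that come out all-ones (fixed) or all-zero (absent) are redrawn
    unless ``keep_monomorphic``; after ``max_redraws`` failed attempts one
    entry is flipped so the marker is polymorphic, which only ever triggers
    for frequencies at the extremes.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    sizes = config.pop_sizes
    if freqs.shape[1] != len(sizes):
        raise ValueError(
            f"frequency matrix has {freqs.shape[1]} populations, config has {len(sizes)}"
        )
    per_ind_freq = np.repeat(freqs, sizes, axis=1)  # (markers, individuals)
    values = (rng.random(per_ind_freq.shape) < per_ind_freq).astype(np.int8)
    if not keep_monomorphic:
        for row in range(values.shape[0]):
            tries = 0
            while values[row].all() or not values[row].any():
                if tries >= max_redraws:
                    flip = rng.integers(values.shape[1])
                    values[row, flip] = 1 - values[row].max()
                    break
                values[row] = (
                    rng.random(per_ind_freq.shape[1]) < per_ind_freq[row]
                ).astype(np.int8)
                tries += 1

    individuals = config.individuals()
    rng_meta = np.random.default_rng(config.seed + 2)
    genome = synthetic_genome_table()
    autosomes = sorted(genome.autosomes, key=lambda c: genome.lengths[c], reverse=True)
    records = []
    n_genes = max(1, int(0.7 * freqs.shape[0]))  # ~30% of markers recurrent
    for m in range(freqs.shape[0]):
        gene = f"gene{rng_meta.integers(n_genes):05d}"
        parental = autosomes[int(rng_meta.integers(len(autosomes)))]
        if rng_meta.random() < 0.06:
            parental = "chrX"
        chrom = autosomes[int(rng_meta.integers(len(autosomes)))]
        length = genome.lengths[chrom]
        mid = int(
            rng_meta.integers(config.flank_length + 500, length - config.flank_length - 500)
        )
        records.append(
            RetroCNVRecord(
                retrocnv_id=f"rcnv{m:05d}",
                parental_gene_id=gene,
                parental_chrom=parental,
                insertion_chrom=chrom,
                insertion_start=mid - 250,
                insertion_end=mid + 250,
            )
        )
    return PresenceMatrix(individuals, records, values, allow_fixed=keep_monomorphic)


def simulate_cohort(config: SimConfig) -> PresenceMatrix:
    """Frequencies + presence matrix in one seeded call."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_structured_frequencies(config, rng)
    return simulate_presence_matrix(freqs, config, rng)


# ---------------------------------------------------------------------------
# flanking haplotypes


def _neutral_site_freqs(n_chroms: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Allele frequencies from the 1/j-weighted neutral law truncated at n."""
    j = np.arange(1, n_chroms)
    w = 1.0 / j
    w /= w.sum()
    return rng.choice(j, size=size, p=w) / n_chroms


def _site_density(config: SimConfig, n_chroms: int) -> float:
    """Segregating sites per bp so that expected pi/bp = theta_per_bp."""
    j = np.arange(1, n_chroms)
    w = (1.0 / j) / (1.0 / j).sum()
    q = j / n_chroms
    exp_pi_per_site = float((w * 2.0 * q * (1.0 - q)).sum())
    return config.theta_per_bp / exp_pi_per_site


def simulate_flank_haplotypes(
    n_carriers: int,
    n_noncarriers: int,
    config: SimConfig,
    sweep: bool = False,
    seed: int | None = None,
    chrom: str = "chr1",
    midpoint: int = 1_000_000,
    sample_ids: list[str] | None = None,
) -> tuple[SNPMatrix, np.ndarray]:
    """Simulate SNP dosages on midpoint +/- flank_length for a focal marker.

    Returns the SNP matrix (carriers first, then non-carriers) and the boolean
    carrier mask.  ``sweep=False`` (or sweep_strength 1) gives exchangeable
    neutral genotypes for all individuals; ``sweep=True`` applies the founder
    copying model to carrier genotypes at sites within sweep_core_bp of the
    midpoint.
    """
    if n_carriers < 1 or n_noncarriers < 1:
        raise ValueError("need at least one carrier and one non-carrier")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_ind = n_carriers + n_noncarriers
    n_chroms = 2 * n_ind
    region_start = max(1, midpoint - config.flank_length)
    region_end = midpoint + config.flank_length
    length = region_end - region_start + 1
    n_sites = int(rng.poisson(_site_density(config, n_chroms) * length))
    if n_sites > length:
        raise ValueError("site density too high for region length")
    positions = region_start + np.sort(rng.choice(length, size=n_sites, replace=False))
    q = _neutral_site_freqs(n_chroms, n_sites, rng)

    dosages = rng.binomial(2, q[:, None], size=(n_sites, n_ind)).astype(np.int8)
    carrier_mask = np.zeros(n_ind, dtype=bool)
    carrier_mask[:n_carriers] = True

    if sweep and config.sweep_strength > 1.0:
        half_core = config.sweep_core_bp // 2
        core = (positions >= midpoint - half_core) & (positions <= midpoint + half_core)
        n_core = int(core.sum())
        if n_core:
            phi = 1.0 - config.sweep_strength ** -0.5  # founder-copy probability
            eps = min(0.5, 0.5 / config.sweep_strength)  # residual flip rate
            founder = (rng.random(n_core) < q[core]).astype(np.int8)
            # founder-copy count per carrier, shared across sites -> LD
            f = rng.binomial(2, phi, size=n_carriers)
            p_founder = founder * (1.0 - eps) + (1 - founder) * eps
            from_founder = rng.binomial(f[None, :], p_founder[:, None])
            from_background = rng.binomial(
                (2 - f)[None, :], q[core][:, None]
            )
            dosages[np.ix_(core, carrier_mask)] = (from_founder + from_background).astype(
                np.int8
            )

    if sample_ids is None:
        sample_ids = [f"car_{i:02d}" for i in range(n_carriers)] + [
            f"non_{i:02d}" for i in range(n_noncarriers)
        ]
    snps = SNPMatrix(chrom, positions, sample_ids, dosages)
    return snps, carrier_mask


class SyntheticFlankProvider:
    """Deterministic neutral SNP flanks keyed by genomic position.

    Used as the SNP source for pseudo-insertion backgrounds on the synthetic
    genome: every (chrom, position) maps to a reproducible neutral flank for
    the full sample list, seeded from the base seed and a CRC of the locus.
    """

    def __init__(self, config: SimConfig, sample_ids: list[str], base_seed: int) -> None:
        self.config = config
        self.sample_ids = list(sample_ids)
        self.base_seed = int(base_seed)

    def __call__(self, chrom: str, midpoint: int) -> SNPMatrix:
        key = zlib.crc32(f"{chrom}:{midpoint}".encode())
        seed = (self.base_seed * 1_000_003 + key) % (2**31)
        n = len(self.sample_ids)
        snps, _ = simulate_flank_haplotypes(
            n_carriers=max(1, n - 1),
            n_noncarriers=1,
            config=self.config,
            sweep=False,
            seed=seed,
            chrom=chrom,
            midpoint=midpoint,
            sample_ids=self.sample_ids,
        )
        return snps


# ---------------------------------------------------------------------------
# genome fixtures

_AUTOSOME_MB = (20, 19, 18, 17, 16, 15, 15, 14, 13, 13, 12, 12, 11, 11, 10, 10, 9, 9, 8)


def synthetic_genome_table() -> GenomeTable:
    """A scaled-down 19-autosome + X genome with multi-exon gene counts."""
    lengths = {f"chr{i + 1}": mb * 1_000_000 for i, mb in enumerate(_AUTOSOME_MB)}
    lengths["chrX"] = 16_000_000
    counts = {c: max(50, length // 25_000 // 4) for c, length in lengths.items()}
    autosomes = {f"chr{i + 1}" for i in range(19)}
    return GenomeTable(lengths, counts, autosomes)


def synthetic_gaps(seed: int = 0) -> GapSet:
    """A handful of assembly-gap intervals per chromosome."""
    rng = np.random.default_rng(seed + 77)
    genome = synthetic_genome_table()
    by_chrom = {}
    for chrom, length in genome.lengths.items():
        starts = rng.integers(0, length - 200_000, size=3)
        by_chrom[chrom] = np.asarray([(int(s), int(s) + 100_000) for s in starts])
    return GapSet(by_chrom)


def synthetic_annotations(genome: GenomeTable | None = None) -> AnnotationSet:
    """Regular gene models for overlap tests: a 20 kb three-exon gene every
    100 kb, with CDS inside exons and UTRs at the gene ends."""
    genome = genome or synthetic_genome_table()
    genes, exons, introns, cds, utr = {}, {}, {}, {}, {}
    for chrom, length in genome.lengths.items():
        g, e, i_, c, u = [], [], [], [], []
        for start in range(50_000, length - 20_000, 100_000):
            end = start + 20_000
            g.append((start, end))
            exon_spans = [(start, start + 1_000), (start + 9_500, start + 10_500), (end - 1_000, end)]
            e.extend(exon_spans)
            i_.extend([(start + 1_000, start + 9_500), (start + 10_500, end - 1_000)])
            u.extend([(start, start + 200), (end - 200, end)])
            c.extend([(start + 200, start + 1_000), (start + 9_500, start + 10_500), (end - 1_000, end - 200)])
        genes[chrom] = np.asarray(g)
        exons[chrom] = np.asarray(e)
        introns[chrom] = np.asarray(i_)
        cds[chrom] = np.asarray(c)
        utr[chrom] = np.asarray(u)
    ann = AnnotationSet(
        {
            "protein_coding_gene": IntervalSet(genes),
            "exon": IntervalSet(exons),
            "intron": IntervalSet(introns),
            "CDS": IntervalSet(cds),
            "UTR": IntervalSet(utr),
        }
    )
    return ann.with_intergenic(genome)


# ---------------------------------------------------------------------------
# fixture bundle


def _write_vcf(snps: SNPMatrix, path: Path, contig_length: int) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={snps.chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(snps.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for pos, row in zip(snps.positions, snps.dosages):
            gts = "\t".join(gt_map[int(d)] for d in row)
            fh.write(f"{snps.chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_bundle(config: SimConfig, out_dir: str | Path, n_flank_vcfs: int = 3) -> dict:
    """Emit a complete, parseable input bundle under ``out_dir``.

    Writes the presence TSV, metadata TSV, genome table, gap BED, per-category
    element BEDs, flank VCFs for the first ``n_flank_vcfs`` high-frequency
    markers, and a manifest recording the seed.  Two runs with the same config
    produce byte-identical files.
    """
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presence = simulate_cohort(config)
    genome = synthetic_genome_table()
    gaps = synthetic_gaps(config.seed)
    annotations = synthetic_annotations(genome)

    rio.write_presence_table(presence, out / "presence.tsv")
    rio.write_metadata(presence.individuals, out / "metadata.tsv")
    rio.write_genome_table(genome, out / "genome.tsv")
    rio.write_bed(gaps, out / "gaps.bed")
    for category, ivs in annotations.categories.items():
        if category != "intergenic":  # intergenic is computed, not stored
            rio.write_bed(ivs, out / f"annotation_{category}.bed")

    flank_ids = []
    high = [r for r in presence.retrocnvs if r.carrier_count >= 6][:n_flank_vcfs]
    for rec in high:
        carriers = int(rec.carrier_count)
        snps, _ = simulate_flank_haplotypes(
            n_carriers=carriers,
            n_noncarriers=presence.n_individuals - carriers,
            config=config,
            sweep=False,
            seed=(config.seed * 9973 + zlib.crc32(rec.retrocnv_id.encode())) % (2**31),
            chrom=rec.insertion_chrom,
            midpoint=rec.midpoint,
            sample_ids=presence.individual_ids,
        )
        _write_vcf(snps, out / f"flank_{rec.retrocnv_id}.vcf", genome.lengths[rec.insertion_chrom])
        flank_ids.append(rec.retrocnv_id)

    manifest = {
        "seed": config.seed,
        "n_markers": config.n_markers,
        "n_individuals": config.n_individuals,
        "fst": config.fst,
        "flank_vcfs": flank_ids,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
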