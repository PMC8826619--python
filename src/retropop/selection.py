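"""Positive-selection signature test with a pseudo-insertion background null.

For an eligible retroCNV three statistics are computed from SNPs around the
insertion midpoint:

* pi ratio — mean per-bp nucleotide diversity of carriers over non-carriers
  in the +/- 50 kb flank (a sweep among carriers pushes it below 1);
* Tajima's D among carriers over the same flank (negative after a sweep);
* mean genotype r^2 among carriers in the +/- 5 kb flank (elevated by
  hitch-hiking).

The null is built by dropping the same carrier/non-carrier labels onto
random autosomal, gap-avoiding "pseudo" insertion sites (default 100) and
recomputing the triple there.  A retroCNV is called positively selected when
all three statistics are more extreme than the background at p < 0.05:
identical-or-smaller pi ratio, identical-or-smaller D, identical-or-greater
LD.  The default p is the add-one empirical tail probability; a rank-sum
mode comparing window-level distributions is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .popgen import mean_ld, sites_pi, tajimas_d, windowed_pi, genotype_r2
from .types import GapSet, GenomeTable, PresenceMatrix, RetroCNVRecord, SNPMatrix

FLANK_BP = 50_000
LD_FLANK_BP = 5_000

#: provider signature: (chrom, midpoint) -> SNPMatrix covering +/- FLANK_BP
SNPProvider = Callable[[str, int], SNPMatrix]


@dataclass
class EligibilityRecord:
    retrocnv_id: str
    subspecies_frequency_ok: bool
    carriers_ok: bool
    noncarriers_ok: bool
    has_flanking_snps: bool
    n_carriers: int
    n_noncarriers: int

    @property
    def eligible(self) -> bool:
        return (
            self.subspecies_frequency_ok
            and self.carriers_ok
            and self.noncarriers_ok
            and self.has_flanking_snps
        )


@dataclass
class EligibilityReport:
    subspecies: str
    records: list[EligibilityRecord]

    @property
    def candidates(self) -> list[str]:
        return [r.retrocnv_id for r in self.records if r.subspecies_frequency_ok]

    @property
    def eligible_ids(self) -> list[str]:
        return [r.retrocnv_id for r in self.records if r.eligible]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "retrocnv_id": r.retrocnv_id,
                    "subspecies_frequency_ok": r.subspecies_frequency_ok,
                    "carriers_ok": r.carriers_ok,
                    "noncarriers_ok": r.noncarriers_ok,
                    "has_flanking_snps": r.has_flanking_snps,
                    "eligible": r.eligible,
                }
                for r in self.records
            ]
        )


@dataclass
class SelectionTestResult:
    """The three observed sweep statistics and their background p-values."""

    retrocnv_id: str
    pi_ratio: float
    tajima_d_carriers: float
    mean_ld_carriers: float
    p_pi: float
    p_d: float
    p_ld: float
    n_background: int

    @property
    def significant(self) -> bool:
        ps = (self.p_pi, self.p_d, self.p_ld)
        if any(math.isnan(p) for p in ps):
            return False
        return max(ps) < 0.05


def eligibility_filter(
    presence: PresenceMatrix,
    subspecies: str,
    min_pop_fraction: float = 0.5,
    min_carriers: int = 3,
    min_noncarriers: int = 3,
    snp_checker: Callable[[RetroCNVRecord], bool] | None = None,
) -> EligibilityReport:
    """Apply the candidate filters for one focal subspecies.

    A retroCNV qualifies when it is present in at least ``min_pop_fraction``
    of individuals in *every* population of the subspecies, is both present
    and absent in at least three individuals of that subspecies, and has SNPs
    in its +/- 50 kb flank (``snp_checker``; assumed true when omitted).
    """
    sub_mask = presence.subspecies_of() == subspecies
    pops = presence.population_of()[sub_mask]
    unique_pops = list(dict.fromkeys(pops))
    if len(unique_pops) < 2:
        raise ValueError(
            f"subspecies {subspecies!r} has {len(unique_pops)} population(s); "
            "the all-populations frequency filter needs at least 2"
        )
    values = presence.values[:, sub_mask]
    records = []
    for rec, row in zip(presence.retrocnvs, values):
        pop_ok = all(
            row[pops == pop].mean() >= min_pop_fraction for pop in unique_pops
        )
        n_car = int(row.sum())
        n_non = int(row.size - n_car)
        has_snps = True if snp_checker is None else bool(snp_checker(rec))
        records.append(
            EligibilityRecord(
                retrocnv_id=rec.retrocnv_id,
                subspecies_frequency_ok=pop_ok,
                carriers_ok=n_car >= min_carriers,
                noncarriers_ok=n_non >= min_noncarriers,
                has_flanking_snps=has_snps,
                n_carriers=n_car,
                n_noncarriers=n_non,
            )
        )
    return EligibilityReport(subspecies=subspecies, records=records)


def draw_pseudo_sites(
    genome: GenomeTable,
    gaps: GapSet,
    n: int = 100,
    seed: int | None = None,
    flank: int = FLANK_BP,
) -> list[tuple[str, int]]:
    """Random autosomal non-gap positions for the background null.

    Sites are drawn uniformly over the usable autosomal base pairs — the
    non-gap positions whose +/- flank stays inside the chromosome — so each
    chromosome receives draws proportional to its usable length.  A
    chromosome entirely covered by gaps (or too short for the flank)
    contributes nothing.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, int, int]] = []  # (chrom, start_1based, end_1based)
    for chrom in genome.chroms:
        if not genome.is_autosome(chrom):
            continue
        length = genome.lengths[chrom]
        lo, hi = 1 + flank, length - flank  # flank-safe 1-based positions
        if hi < lo:
            continue
        prev = lo
        for g_start, g_end in gaps.intervals(chrom):  # 0-based half-open
            g_lo, g_hi = g_start + 1, g_end  # 1-based inclusive gap span
            if g_lo > prev:
                blocks.append((chrom, prev, min(g_lo - 1, hi)))
            prev = max(prev, g_hi + 1)
            if prev > hi:
                break
        if prev <= hi:
            blocks.append((chrom, prev, hi))
    blocks = [(c, s, e) for c, s, e in blocks if e >= s]
    if not blocks:
        raise ValueError("no autosome has usable non-gap sequence")
    sizes = np.asarray([e - s + 1 for _, s, e in blocks], dtype=np.int64)
    cum = np.cumsum(sizes)
    draws = rng.integers(0, cum[-1], size=n)
    out: list[tuple[str, int]] = []
    for d in draws:
        i = int(np.searchsorted(cum, d, side="right"))
        chrom, s, _ = blocks[i]
        offset = int(d - (cum[i] - sizes[i]))
        out.append((chrom, s + offset))
    return out


def observed_statistics(
    snps: SNPMatrix,
    carrier_ids: Sequence[str],
    noncarrier_ids: Sequence[str],
    midpoint: int,
) -> tuple[float, float, float]:
    """(pi_ratio, carrier Tajima's D, carrier mean LD) at one site.

    pi ratio uses the +/- 50 kb flank (region-wide per-bp pi of carriers over
    non-carriers); D the same flank for carriers; mean LD the +/- 5 kb flank
    for carriers.  Any statistic without usable sites is nan.
    """
    region = (max(1, midpoint - FLANK_BP), midpoint + FLANK_BP)
    flank = snps.subset_region(*region)
    length = region[1] - region[0] + 1

    def _pi_per_bp(ids: Sequence[str]) -> float:
        sub = flank.subset_samples(list(ids))
        vals = sites_pi(sub.dosages)
        return float(np.nansum(vals)) / length

    pi_car = _pi_per_bp(carrier_ids)
    pi_non = _pi_per_bp(noncarrier_ids)
    pi_ratio = pi_car / pi_non if pi_non > 0 else math.nan
    d = tajimas_d(flank, list(carrier_ids))
    ld_region = (max(1, midpoint - LD_FLANK_BP), midpoint + LD_FLANK_BP)
    ld = mean_ld(snps, list(carrier_ids), ld_region)
    return pi_ratio, d, ld


def background_distribution(
    pseudo_sites: Sequence[tuple[str, int]],
    snp_provider: SNPProvider,
    carrier_ids: Sequence[str],
    noncarrier_ids: Sequence[str],
    max_undefined_fraction: float = 0.5,
) -> pd.DataFrame:
    """The three statistics at every pseudo site with the focal labels.

    Returns a data frame with columns pi_ratio / tajima_d / mean_ld (nan rows
    dropped per column downstream); raises when more than half of the pseudo
    sites yield an undefined pi ratio, which makes the background unusable.
    """
    if not list(carrier_ids) or not list(noncarrier_ids):
        raise ValueError("carrier and non-carrier label sets must be non-empty")
    rows = []
    for chrom, pos in pseudo_sites:
        snps = snp_provider(chrom, pos)
        pi_ratio, d, ld = observed_statistics(snps, carrier_ids, noncarrier_ids, pos)
        rows.append({"chrom": chrom, "pos": pos, "pi_ratio": pi_ratio, "tajima_d": d, "mean_ld": ld})
    df = pd.DataFrame(rows)
    undef = df["pi_ratio"].isna().mean()
    if undef > max_undefined_fraction:
        raise ValueError(
            f"{undef:.0%} of pseudo sites have undefined pi ratio; background unusable"
        )
    return df


def _empirical_p(background: np.ndarray, observed: float, tail: str) -> float:
    """Add-one empirical tail probability; ties count as extreme."""
    bg = background[~np.isnan(background)]
    if math.isnan(observed) or bg.size == 0:
        return math.nan
    if tail == "lower":
        k = int((bg <= observed).sum())
    else:
        k = int((bg >= observed).sum())
    return (1.0 + k) / (1.0 + bg.size)


def selection_test(
    retrocnv_id: str,
    focal_snps: SNPMatrix,
    midpoint: int,
    carrier_ids: Sequence[str],
    noncarrier_ids: Sequence[str],
    genome: GenomeTable,
    gaps: GapSet,
    snp_provider: SNPProvider,
    n_background: int = 100,
    seed: int | None = None,
    mode: str = "empirical",
) -> SelectionTestResult:
    """Run the full three-statistic test for one retroCNV.

    ``mode="empirical"`` (default): one-sided add-one empirical p against the
    background scalars.  ``mode="ranksum"``: one-sided Wilcoxon rank-sum of
    the focal flank's window-level values against the pooled background
    windows (pi ratio and D in 10 kb / 5 kb sliding windows; LD on pair-level
    r^2 values).
    """
    obs_pi, obs_d, obs_ld = observed_statistics(
        focal_snps, carrier_ids, noncarrier_ids, midpoint
    )
    pseudo = draw_pseudo_sites(genome, gaps, n=n_background, seed=seed)
    bg = background_distribution(pseudo, snp_provider, carrier_ids, noncarrier_ids)

    if mode == "empirical":
        p_pi = _empirical_p(bg["pi_ratio"].to_numpy(), obs_pi, "lower")
        p_d = _empirical_p(bg["tajima_d"].to_numpy(), obs_d, "lower")
        p_ld = _empirical_p(bg["mean_ld"].to_numpy(), obs_ld, "upper")
    elif mode == "ranksum":
        p_pi, p_d, p_ld = _ranksum_ps(
            focal_snps, midpoint, carrier_ids, noncarrier_ids, pseudo, snp_provider
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SelectionTestResult(
        retrocnv_id=retrocnv_id,
        pi_ratio=obs_pi,
        tajima_d_carriers=obs_d,
        mean_ld_carriers=obs_ld,
        p_pi=p_pi,
        p_d=p_d,
        p_ld=p_ld,
        n_background=n_background,
    )


def _window_values(
    snps: SNPMatrix,
    midpoint: int,
    carrier_ids: Sequence[str],
    noncarrier_ids: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    region = (max(1, midpoint - FLANK_BP), midpoint + FLANK_BP)
    car_pi = windowed_pi(snps, list(carrier_ids), region)
    non_pi = windowed_pi(snps, list(noncarrier_ids), region)
    ratios = []
    for c, nc in zip(car_pi, non_pi):
        if nc.value and nc.value > 0:
            ratios.append(c.value / nc.value)
    ds = []
    for w in car_pi:
        d = tajimas_d(snps, list(carrier_ids), (w.window_start + 1, w.window_end))
        if not math.isnan(d):
            ds.append(d)
    flank = snps.subset_region(max(1, midpoint - LD_FLANK_BP), midpoint + LD_FLANK_BP)
    sub = flank.subset_samples(list(carrier_ids))
    from .popgen import _pairwise_r2

    r2 = _pairwise_r2(sub.dosages) if sub.n_sites >= 2 else np.empty(0)
    r2 = r2[~np.isnan(r2)]
    return np.asarray(ratios), np.asarray(ds), r2


def _ranksum_ps(focal_snps, midpoint, carrier_ids, noncarrier_ids, pseudo, provider):
    f_pi, f_d, f_r2 = _window_values(focal_snps, midpoint, carrier_ids, noncarrier_ids)
    bg_pi, bg_d, bg_r2 = [], [], []
    for chrom, pos in pseudo:
        snps = provider(chrom, pos)
        r, d, r2 = _window_values(snps, pos, carrier_ids, noncarrier_ids)
        bg_pi.append(r)
        bg_d.append(d)
        bg_r2.append(r2)
    bg_pi = np.concatenate(bg_pi) if bg_pi else np.empty(0)
    bg_d = np.concatenate(bg_d) if bg_d else np.empty(0)
    bg_r2 = np.concatenate(bg_r2) if bg_r2 else np.empty(0)

    def _p(f, bg, alternative):
        if f.size == 0 or bg.size == 0:
            return math.nan
        return float(mannwhitneyu(f, bg, alternative=alternative).pvalue)

    return _p(f_pi, bg_pi, "less"), _p(f_d, bg_d, "less"), _p(f_r2, bg_r2, "greater")


def complete_ld_report(
    snps: SNPMatrix,
    carrier_vector: np.ndarray,
    midpoint: int,
    flank: int = FLANK_BP,
) -> list[int]:
    """Positions of flanking SNPs in complete LD (r^2 = 1) with the carrier
    presence vector — expected empty for a directly selected insertion."""
    region = snps.subset_region(max(1, midpoint - flank), midpoint + flank)
    hits = []
    for pos, row in zip(region.positions, region.dosages):
        r2 = genotype_r2(row, np.asarray(carrier_vector))
        if not math.isnan(r2) and r2 >= 1.0 - 1e-12:
            hits.append(int(pos))
    return hits


class SelectionScan:
    """Model: three-statistic sweep scan over the eligible retroCNVs of one
    subspecies, with pseudo-insertion backgrounds.

    ``snp_provider`` maps (chrom, midpoint) to a SNPMatrix covering the
    +/- 50 kb flank for all cohort individuals; the same provider serves the
    focal sites and the pseudo background sites.
    """

    def __init__(
        self,
        presence: PresenceMatrix,
        genome: GenomeTable,
        gaps: GapSet,
        snp_provider: SNPProvider,
    ) -> None:
        self.presence = presence
        self.genome = genome
        self.gaps = gaps
        self.snp_provider = snp_provider

    def eligibility(self, subspecies: str) -> EligibilityReport:
        def _has_snps(rec: RetroCNVRecord) -> bool:
            snps = self.snp_provider(rec.insertion_chrom, rec.midpoint)
            return snps.n_sites > 0

        return eligibility_filter(self.presence, subspecies, snp_checker=_has_snps)

    def fit(
        self,
        subspecies: str,
        n_background: int = 100,
        seed: int | None = None,
        mode: str = "empirical",
        retrocnv_ids: Sequence[str] | None = None,
    ) -> "SelectionScanResults":
        report = self.eligibility(subspecies)
        ids = report.eligible_ids if retrocnv_ids is None else list(retrocnv_ids)
        sub_mask = self.presence.subspecies_of() == subspecies
        by_id = {r.retrocnv_id: r for r in self.presence.retrocnvs}
        results = []
        rng = np.random.default_rng(seed)
        for rid in ids:
            rec = by_id[rid]
            row = self.presence.row(rid)
            ind_ids = np.asarray(self.presence.individual_ids)
            carriers = list(ind_ids[sub_mask & (row == 1)])
            noncarriers = list(ind_ids[sub_mask & (row == 0)])
            snps = self.snp_provider(rec.insertion_chrom, rec.midpoint)
            results.append(
                selection_test(
                    rid,
                    snps,
                    rec.midpoint,
                    carriers,
                    noncarriers,
                    self.genome,
                    self.gaps,
                    self.snp_provider,
                    n_background=n_background,
                    seed=int(rng.integers(2**31)),
                    mode=mode,
                )
            )
        return SelectionScanResults(
            model=self, subspecies=subspecies, eligibility=report, results=results
        )


@dataclass
class SelectionScanResults:
    model: "SelectionScan"
    subspecies: str
    eligibility: EligibilityReport
    results: list[SelectionTestResult]

    _COLUMNS = (
        "retrocnv_id",
        "pi_ratio",
        "tajima_d_carriers",
        "mean_ld_carriers",
        "p_pi",
        "p_d",
        "p_ld",
        "significant",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "retrocnv_id": r.retrocnv_id,
                "pi_ratio": r.pi_ratio,
                "tajima_d_carriers": r.tajima_d_carriers,
                "mean_ld_carriers": r.mean_ld_carriers,
                "p_pi": r.p_pi,
                "p_d": r.p_d,
                "p_ld": r.p_ld,
                "significant": r.significant,
            }
            for r in self.results
        ]
        return pd.DataFrame(rows, columns=list(self._COLUMNS))

    @property
    def significant_ids(self) -> list[str]:
        return [r.retrocnv_id for r in self.results if r.significant]

    def summary(self) -> str:
        n_cand = len(self.eligibility.candidates)
        n_elig = len(self.eligibility.eligible_ids)
        lines = [
            f"Positive-selection scan - subspecies {self.subspecies}",
            "=" * 56,
            f"high-frequency candidates: {n_cand}",
            f"eligible for testing:      {n_elig}",
            f"tested:                    {len(self.results)}",
            f"significant (all 3 stats): {len(self.significant_ids)}",
        ]
        for r in self.results:
            if r.significant:
                lines.append(
                    f"  {r.retrocnv_id}: pi_ratio={r.pi_ratio:.3f} "
                    f"D={r.tajima_d_carriers:.2f} LD={r.mean_ld_carriers:.3f} "
                    f"(p={r.p_pi:.3f}/{r.p_d:.3f}/{r.p_ld:.3f})"
                )
        return "\n".join(lines)
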