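"""Nucleotide diversity, Tajima's D and linkage disequilibrium on dosages.

These are the three building blocks of the sweep scan: reduced nucleotide
diversity (pi) among carriers of an insertion relative to non-carriers,
negative Tajima's D among carriers, and elevated genotype r^2 among carriers
are the classic local signatures of a recent selective sweep.

All functions take unphased diploid dosage matrices (0/1/2, -1 missing) and
apply per-site pairwise deletion of missing data.  Windowed pi divides by
window length in bp (monomorphic positions contribute zero implicitly);
genotype r^2 is the squared Pearson correlation of dosage vectors, the
standard unphased LD measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import MISSING, SNPMatrix

__all__ = [
    "site_pi",
    "sites_pi",
    "windowed_pi",
    "TajimaComponents",
    "tajima_constants",
    "tajimas_d",
    "genotype_r2",
    "mean_ld",
    "ld_prune",
    "WindowStat",
]


@dataclass
class WindowStat:
    chrom: str
    window_start: int  # 0-based half-open
    window_end: int
    statistic: str
    value: float | None
    n_sites: int


def site_pi(dosages: np.ndarray) -> float:
    """Per-site nucleotide diversity from one site's dosage vector.

    With j alternate alleles among k non-missing chromosomes this is
    ``2 j (k - j) / (k (k - 1))`` — the fraction of mismatching chromosome
    pairs.  Undefined (nan) with fewer than two chromosomes.
    """
    d = np.asarray(dosages)
    ok = d != MISSING
    k = 2 * int(ok.sum())
    if k < 2:
        return math.nan
    j = int(d[ok].sum())
    return 2.0 * j * (k - j) / (k * (k - 1))


def sites_pi(dosages: np.ndarray) -> np.ndarray:
    """Vectorised :func:`site_pi` over a (n_sites, n_samples) matrix."""
    d = np.asarray(dosages)
    ok = d != MISSING
    k = 2.0 * ok.sum(axis=1)
    j = np.where(ok, d, 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (k - j) / (k * (k - 1.0))
    pi[k < 2] = np.nan
    return pi


def windowed_pi(
    snps: SNPMatrix,
    sample_subset: list[str] | None = None,
    region: tuple[int, int] | None = None,
    window: int = 10_000,
    step: int = 5_000,
) -> list[WindowStat]:
    """Sliding-window per-bp pi over a region (1-based inclusive bounds).

    Each window's value is the sum of per-site pi over contained sites divided
    by the window length in bp; an empty window has value 0 with n_sites 0.
    """
    if sample_subset is not None:
        snps = snps.subset_samples(sample_subset)
    if region is None:
        if snps.n_sites == 0:
            return []
        region = (int(snps.positions[0]), int(snps.positions[-1]))
    start1, end1 = region
    pi = sites_pi(snps.dosages)
    out: list[WindowStat] = []
    w_start = start1 - 1  # 0-based half-open windows
    region_end = end1
    while w_start < region_end:
        w_end = min(w_start + window, region_end)
        mask = (snps.positions > w_start) & (snps.positions <= w_end)
        vals = pi[mask]
        vals = vals[~np.isnan(vals)]
        out.append(
            WindowStat(
                chrom=snps.chrom,
                window_start=w_start,
                window_end=w_end,
                statistic="pi",
                value=float(vals.sum()) / (w_end - w_start),
                n_sites=int(vals.size),
            )
        )
        if w_start + window >= region_end:
            break
        w_start += step
    return out


@dataclass
class TajimaComponents:
    """Sample size, segregating sites, pairwise diversity and the canonical
    normalising constants a1, a2, b1, b2, c1, c2, e1, e2 derived from n."""

    n: int
    S: int
    pi_total: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> dict[str, float]:
    """The canonical constants for Tajima's D with n sampled chromosomes."""
    if n < 2:
        raise ValueError(f"need >= 2 chromosomes, got {n}")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_components(snps: SNPMatrix, sample_subset: list[str] | None = None) -> TajimaComponents | None:
    if sample_subset is not None:
        snps = snps.subset_samples(sample_subset)
    d = snps.dosages
    if d.shape[0] == 0:
        return None
    ok = d != MISSING
    k = 2 * ok.sum(axis=1)
    usable = k >= 4  # sites with < 4 non-missing chromosomes are skipped
    d = d[usable]
    ok = ok[usable]
    if d.shape[0] == 0:
        return None
    j = np.where(ok, d, 0).sum(axis=1)
    k = 2 * ok.sum(axis=1)
    seg = (j > 0) & (j < k)
    S = int(seg.sum())
    pi_vals = sites_pi(d)
    pi_total = float(np.nansum(pi_vals))
    # one n for the constants: the (rounded) mean non-missing chromosome count
    n = int(round(float(k.mean())))
    if n < 4:
        return None
    consts = tajima_constants(n)
    return TajimaComponents(n=n, S=S, pi_total=pi_total, **consts)


def tajimas_d(
    snps: SNPMatrix,
    sample_subset: list[str] | None = None,
    region: tuple[int, int] | None = None,
) -> float:
    """Tajima's D over the given region (1-based inclusive).

    ``D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S - 1))``; undefined (nan)
    when S = 0 or the variance term vanishes — never reported as 0.
    """
    if region is not None:
        snps = snps.subset_region(*region)
    comp = tajima_components(snps, sample_subset)
    if comp is None or comp.S == 0:
        return math.nan
    var = comp.e1 * comp.S + comp.e2 * comp.S * (comp.S - 1)
    if var <= 0:
        return math.nan
    return (comp.pi_total - comp.S / comp.a1) / math.sqrt(var)


def genotype_r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (unphased r^2).

    Missing entries are deleted pairwise; undefined (nan) with fewer than two
    complete pairs or zero variance at either site.
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return math.nan
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return math.nan
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov**2 / (va * vb))


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """All pairwise r^2 values (condensed) for a (n_sites, n_samples) block."""
    d = dosages.astype(float)
    if (d == MISSING).any():
        n = d.shape[0]
        vals = []
        for i in range(n):
            for j in range(i + 1, n):
                vals.append(genotype_r2(d[i], d[j]))
        return np.asarray(vals)
    sd = d.std(axis=1)
    keep = sd > 0
    d = d[keep]
    if d.shape[0] < 2:
        return np.empty(0)
    corr = np.corrcoef(d)
    iu = np.triu_indices(d.shape[0], k=1)
    return corr[iu] ** 2


def mean_ld(
    snps: SNPMatrix,
    sample_subset: list[str] | None = None,
    region: tuple[int, int] | None = None,
) -> float:
    """Mean genotype r^2 over all defined SNP pairs in the region."""
    if sample_subset is not None:
        snps = snps.subset_samples(sample_subset)
    if region is not None:
        snps = snps.subset_region(*region)
    if snps.n_sites < 2:
        return math.nan
    vals = _pairwise_r2(snps.dosages)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return math.nan
    return float(vals.mean())


def ld_prune(
    snps: SNPMatrix,
    window: int = 500,
    step: int = 100,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy LD pruning: indices of retained sites.

    Within each window of ``window`` consecutive sites (advancing by ``step``
    sites), pairs with r^2 >= threshold are resolved by removing the later
    (larger-index) site — the tie-break that keeps the leftmost of a duplicate
    pair.
    """
    n = snps.n_sites
    removed = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        idx = [i for i in range(start, min(start + window, n)) if not removed[i]]
        for ai in range(len(idx)):
            i = idx[ai]
            if removed[i]:
                continue
            for bi in range(ai + 1, len(idx)):
                j = idx[bi]
                if removed[j]:
                    continue
                r2 = genotype_r2(snps.dosages[i], snps.dosages[j])
                if not math.isnan(r2) and r2 >= r2_threshold:
                    removed[j] = True
        if start + window >= n:
            break
        start += step
    return np.flatnonzero(~removed)
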