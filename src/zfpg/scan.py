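"""Post-hoc genome scans around F_ST outlier loci.

Three scans: (1) a Poisson test for nonrandom clustering of outliers in
20 Mb genome bins; (2) a heterozygosity-valley scan comparing mean
expected heterozygosity in 10 Mb windows around each outlier to a
genome-wide distribution from non-outlier windows (selective-sweep
signal); (3) an analogous LD-elevation scan on the mean r^2 between the
focal locus and the other SNPs in its window.

All intervals are half-open [start, end) in basepairs, with bins tiled
from position 1 on each chromosome and partial terminal bins kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import ld as _ld
from .fdist import OutlierCall
from .popio import MISSING, GenotypeDataset, LocusRecord

log = logging.getLogger(__name__)


@dataclass
class GenomeBin:
    chrom: str
    start: int  # half-open [start, end)
    end: int
    n_outliers: int
    poisson_p: float | None = None


@dataclass
class WindowStat:
    focal_locus: str
    chrom: str
    start: int
    end: int
    n_snps: int
    statistic: float | None
    empirical_p: float | None = None
    significant: bool = False


# ---------------------------------------------------------------------------
# Outlier clustering in genome bins
# ---------------------------------------------------------------------------

def bin_outliers(
    loci: list[LocusRecord],
    outlier_mask,
    chrom_lengths: dict[str, int],
    bin_size: int = 20_000_000,
) -> list[GenomeBin]:
    """Tile each chromosome into ``bin_size`` bins from position 1 (final
    partial bin kept) and count outlier loci per bin."""
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    for loc in loci:
        if loc.chrom not in chrom_lengths:
            raise ValueError(f"locus {loc.locus_id}: no length for {loc.chrom}")
        if loc.pos > chrom_lengths[loc.chrom]:
            raise ValueError(
                f"locus {loc.locus_id} at {loc.pos} beyond {loc.chrom} "
                f"length {chrom_lengths[loc.chrom]}"
            )
    bins: list[GenomeBin] = []
    index: dict[tuple[str, int], int] = {}
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        start = 1
        k = 0
        while start <= length:
            end = min(start + bin_size, length + 1)
            index[(chrom, k)] = len(bins)
            bins.append(GenomeBin(chrom, start, end, 0))
            start = end
            k += 1
    for loc, is_out in zip(loci, outlier_mask):
        if is_out:
            k = (loc.pos - 1) // bin_size
            bins[index[(loc.chrom, k)]].n_outliers += 1
    return bins


def poisson_cluster_p(k: int, n_outliers: int, n_bins: int) -> float:
    """Poisson point probability P(X = k) of observing k outliers in one
    bin, with mean lambda = n_outliers / n_bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    lam = n_outliers / n_bins
    return float(stats.poisson.pmf(k, lam))


def annotate_bins(bins: list[GenomeBin], n_outliers: int | None = None) -> list[GenomeBin]:
    """Fill each bin's clustering P-value from the bin-set totals."""
    if n_outliers is None:
        n_outliers = sum(b.n_outliers for b in bins)
    for b in bins:
        b.poisson_p = poisson_cluster_p(b.n_outliers, n_outliers, len(bins))
    return bins


# ---------------------------------------------------------------------------
# Window scans
# ---------------------------------------------------------------------------

def _polymorphic_mask(g: np.ndarray) -> np.ndarray:
    usable = g != MISSING
    alt = np.where(usable, g, 0).sum(axis=0)
    n = 2 * usable.sum(axis=0)
    return (alt > 0) & (alt < n)


def _chrom_positions(ds: GenotypeDataset):
    pos = np.array([l.pos for l in ds.loci])
    chrom = np.array([l.chrom for l in ds.loci])
    return chrom, pos


def tile_null_windows(
    ds: GenotypeDataset,
    exclusion_zones: list[tuple[str, int, int]],
    window: int = 10_000_000,
    min_snps: int = 6,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Nonoverlapping windows tiled per chromosome, kept only if fully
    outside every exclusion zone and holding >= min_snps polymorphic SNPs.

    Exclusion zones are (chrom, start, end) half-open intervals.  The
    statistic field is left unfilled.  SNP counting uses polymorphism in
    the whole dataset (loci swept to monomorphism within one population
    still belong to their windows).
    """
    poly = _polymorphic_mask(ds.genotypes)
    chrom_arr, pos_arr = _chrom_positions(ds)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(pos_arr[chrom_arr == c].max()) for c in np.unique(chrom_arr)
        }
    out: list[WindowStat] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        start = 1
        while start <= length:
            end = min(start + window, length + 1)
            overlaps = any(
                zc == chrom and start < ze and zs < end
                for zc, zs, ze in exclusion_zones
            )
            if not overlaps:
                in_win = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end) & poly
                n = int(in_win.sum())
                if n >= min_snps:
                    mid = (start + end) // 2
                    focal = ""
                    if n:
                        cand = np.flatnonzero(in_win)
                        focal = ds.loci[cand[np.argmin(np.abs(pos_arr[cand] - mid))]].locus_id
                    out.append(WindowStat(focal, chrom, start, end, n, None))
            start += window
    return out


def _window_around(pos: int, window: int, chrom_len: int) -> tuple[int, int]:
    start = max(1, pos - window // 2)
    end = min(pos + window // 2, chrom_len + 1)
    return start, end


def _mean_het_in(ds, g, chrom_arr, pos_arr, poly, chrom, start, end, exclude_j=None):
    """Mean unbiased expected heterozygosity over polymorphic SNPs in a
    window, computed on the supplied genotype submatrix."""
    mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end) & poly
    if exclude_j is not None:
        mask[exclude_j] = False
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None, 0
    vals = []
    for j in idx:
        col = g[:, j]
        col = col[col != MISSING]
        n = col.size
        if n < 2:
            continue
        p = col.sum() / (2 * n)
        vals.append((2 * n / (2 * n - 1)) * (1 - p * p - (1 - p) ** 2))
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


def het_window_scan(
    ds: GenotypeDataset,
    population: str | None,
    outliers: list[OutlierCall],
    window: int = 10_000_000,
    min_snps: int = 6,
    alpha: float = 0.05,
    chrom_lengths: dict[str, int] | None = None,
    significant_classes: tuple[str, ...] = ("high",),
) -> list[WindowStat]:
    """Heterozygosity-valley scan around significant outlier loci.

    For each outlier of a class in ``significant_classes``, the window is
    [pos - w/2, pos + w/2) clipped to the chromosome, and the statistic is
    the mean expected heterozygosity over its polymorphic SNPs excluding
    the focal locus.  The null distribution is the set of tiled windows
    fully outside every outlier window; the empirical lower-tail P-value
    (add-one rule) is significant below ``alpha``.
    """
    if population is None:
        g = ds.genotypes
    else:
        g = ds.genotypes[ds.pop_indices(population), :]
    chrom_arr, pos_arr = _chrom_positions(ds)
    poly = _polymorphic_mask(ds.genotypes)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(pos_arr[chrom_arr == c].max()) for c in np.unique(chrom_arr)
        }
    focal = [o for o in outliers if o.classification in significant_classes]
    zones = []
    focal_info = []
    for o in focal:
        j = ds.locus_index(o.locus_id)
        chrom = ds.loci[j].chrom
        start, end = _window_around(ds.loci[j].pos, window, chrom_lengths[chrom])
        zones.append((chrom, start, end))
        focal_info.append((o, j, chrom, start, end))

    null = tile_null_windows(
        ds, zones, window=window, min_snps=min_snps,
        chrom_lengths=chrom_lengths,
    )
    null_means = []
    for w in null:
        m, _ = _mean_het_in(ds, g, chrom_arr, pos_arr, poly, w.chrom, w.start, w.end)
        if m is not None:
            w.statistic = m
            null_means.append(m)
    null_means = np.array(null_means)
    if null_means.size < 10:
        raise ValueError(
            f"only {null_means.size} null windows available; need >= 10"
        )

    out: list[WindowStat] = []
    for o, j, chrom, start, end in focal_info:
        m, n = _mean_het_in(
            ds, g, chrom_arr, pos_arr, poly, chrom, start, end, exclude_j=j
        )
        if m is None or n < min_snps:
            log.info("het_window_scan: window at %s has <%d SNPs", o.locus_id, min_snps)
            out.append(WindowStat(o.locus_id, chrom, start, end, n, None))
            continue
        p = (1 + int(np.sum(null_means <= m))) / (1 + null_means.size)
        out.append(
            WindowStat(o.locus_id, chrom, start, end, n, m, p, p < alpha)
        )
    return out


def ld_window_scan(
    ds: GenotypeDataset,
    population: str | None,
    outliers: list[OutlierCall],
    window: int = 10_000_000,
    min_snps: int = 6,
    alpha: float = 0.05,
    chrom_lengths: dict[str, int] | None = None,
    significant_classes: tuple[str, ...] = ("high",),
) -> list[WindowStat]:
    """LD-elevation scan: mean r^2 between each focal outlier and the other
    polymorphic SNPs in its window, against null windows whose focal locus
    is the SNP nearest the window midpoint (upper-tail empirical P)."""
    if population is None:
        g = ds.genotypes
    else:
        g = ds.genotypes[ds.pop_indices(population), :]
    chrom_arr, pos_arr = _chrom_positions(ds)
    poly = _polymorphic_mask(ds.genotypes)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(pos_arr[chrom_arr == c].max()) for c in np.unique(chrom_arr)
        }

    def mean_r2(j_focal: int, chrom: str, start: int, end: int):
        if not poly[j_focal]:
            return None, 0
        mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end) & poly
        mask[j_focal] = False
        idx = np.flatnonzero(mask)
        vals = []
        for j in idx:
            r2, _ = _ld.r2_pair(g[:, j_focal], g[:, j])
            if r2 is not None:
                vals.append(r2)
        if not vals:
            return None, 0
        return float(np.mean(vals)), len(vals)

    focal = [o for o in outliers if o.classification in significant_classes]
    zones = []
    focal_info = []
    for o in focal:
        j = ds.locus_index(o.locus_id)
        chrom = ds.loci[j].chrom
        start, end = _window_around(ds.loci[j].pos, window, chrom_lengths[chrom])
        zones.append((chrom, start, end))
        focal_info.append((o, j, chrom, start, end))

    null = tile_null_windows(
        ds, zones, window=window, min_snps=min_snps,
        chrom_lengths=chrom_lengths,
    )
    null_means = []
    for w in null:
        j_mid = ds.locus_index(w.focal_locus)
        m, _ = mean_r2(j_mid, w.chrom, w.start, w.end)
        if m is not None:
            w.statistic = m
            null_means.append(m)
    null_means = np.array(null_means)
    if null_means.size < 10:
        raise ValueError(
            f"only {null_means.size} null windows available; need >= 10"
        )

    out: list[WindowStat] = []
    for o, j, chrom, start, end in focal_info:
        m, n = mean_r2(j, chrom, start, end)
        if m is None:
            log.info("ld_window_scan: focal %s monomorphic or isolated", o.locus_id)
            out.append(WindowStat(o.locus_id, chrom, start, end, n, None))
            continue
        p = (1 + int(np.sum(null_means >= m))) / (1 + null_means.size)
        out.append(WindowStat(o.locus_id, chrom, start, end, n, m, p, p < alpha))
    return out
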