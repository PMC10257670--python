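"""FPKM quantification in genome bins and around anchors.

Covers the 10-kb binned mutant/WT change-ratio correlation between marks and
the +-10 kb / 100-bp meta-density profiles around peak centers or over gene
bodies. Correlations are computed on log2 ratios so up- and down-changes are
symmetric; bins undefined in either mark of a pair are pairwise-deleted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import ChromSizes, GenomicInterval, StrandedReadSet

__all__ = [
    "MetaProfile",
    "genome_bins",
    "region_fpkm",
    "binned_fpkm_matrix",
    "change_ratios",
    "pairwise_ratio_correlation",
    "meta_profile",
    "gene_body_profile",
]

DEFAULT_GENOME_BIN = 10_000
DEFAULT_PROFILE_WINDOW = 10_000
DEFAULT_PROFILE_BIN = 100
DEFAULT_RATIO_PSEUDOCOUNT = 0.1


def genome_bins(
    chrom_sizes: ChromSizes, bin_size: int = DEFAULT_GENOME_BIN
) -> list[GenomicInterval]:
    """Tile each chromosome with consecutive bins; the final partial bin is kept."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return bins


def region_fpkm(
    reads: StrandedReadSet,
    regions: Sequence[GenomicInterval],
    total_mapped: int | None = None,
) -> np.ndarray:
    """FPKM per region: count / ((length/1e3) * (total_mapped/1e6))."""
    if total_mapped is None:
        total_mapped = reads.total_count
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        if region.length == 0:
            raise ValueError("zero-length region")
        count = reads.count_in(region.chrom, region.start, region.end)
        out[i] = count / ((region.length / 1e3) * (total_mapped / 1e6))
    return out


def binned_fpkm_matrix(
    reads_by_sample: Mapping[str, StrandedReadSet],
    chrom_sizes: ChromSizes,
    bin_size: int = DEFAULT_GENOME_BIN,
) -> pd.DataFrame:
    """Genome-binned FPKM, bins as (chrom, start, end) MultiIndex x sample columns."""
    bins = genome_bins(chrom_sizes, bin_size)
    index = pd.MultiIndex.from_tuples(
        [(b.chrom, b.start, b.end) for b in bins], names=["chrom", "start", "end"]
    )
    data = {
        sample: region_fpkm(reads, bins) for sample, reads in reads_by_sample.items()
    }
    return pd.DataFrame(data, index=index)


def change_ratios(
    matrix: pd.DataFrame,
    mutant_sample: str,
    wt_sample: str,
    pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
) -> pd.Series:
    """Per-bin (mutant + eps)/(wt + eps); bins with both signals zero are NaN."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    mut = matrix[mutant_sample].to_numpy(dtype=float)
    wt = matrix[wt_sample].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (mut + pseudocount) / (wt + pseudocount)
    ratio[(mut == 0) & (wt == 0)] = np.nan
    return pd.Series(ratio, index=matrix.index, name="ratio")


def pairwise_ratio_correlation(
    ratios_by_mark: Mapping[str, pd.Series | np.ndarray],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of log2 change ratios for every pair of marks.

    A pair needs >=3 bins defined in both marks, else it is skipped with a
    warning. The 'displayed' flag marks pairs with two-sided p < alpha.
    """
    arrays = {
        mark: np.log2(np.asarray(series, dtype=float))
        for mark, series in ratios_by_mark.items()
    }
    rows = []
    for mark_a, mark_b in combinations(arrays, 2):
        a, b = arrays[mark_a], arrays[mark_b]
        if a.shape != b.shape:
            raise ValueError(f"bin count mismatch between {mark_a} and {mark_b}")
        shared = np.isfinite(a) & np.isfinite(b)
        n = int(shared.sum())
        if n < 3:
            warnings.warn(
                f"pair ({mark_a}, {mark_b}): only {n} shared bins, skipped",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(a[shared], b[shared])
        rows.append(
            {
                "mark_a": mark_a,
                "mark_b": mark_b,
                "r": float(r),
                "pvalue": float(p),
                "n_bins": n,
                "displayed": bool(p < alpha),
            }
        )
    return pd.DataFrame(
        rows, columns=["mark_a", "mark_b", "r", "pvalue", "n_bins", "displayed"]
    )


@dataclass
class MetaProfile:
    """Anchor-centered binned FPKM densities and their mean profile."""

    matrix: np.ndarray  # (n_anchors, n_bins)
    mean_profile: np.ndarray  # (n_bins,)
    bin_size: int
    half_window: int

    @property
    def n_anchors(self) -> int:
        return self.matrix.shape[0]


def meta_profile(
    reads: StrandedReadSet,
    anchors: Sequence[tuple[str, int]],
    half_window: int = DEFAULT_PROFILE_WINDOW,
    bin_size: int = DEFAULT_PROFILE_BIN,
    chrom_sizes: ChromSizes | None = None,
    total_mapped: int | None = None,
) -> MetaProfile:
    """Binned FPKM density around anchor points (e.g. peak centers).

    Anchors whose window would cross a chromosome edge are dropped with a
    warning. Densities are per-bin FPKM: count / ((bin_size/1e3) *
    (total_mapped/1e6)).
    """
    if not anchors:
        raise ValueError("empty anchor set")
    if half_window % bin_size != 0:
        raise ValueError("bin_size must divide half_window")
    if total_mapped is None:
        total_mapped = reads.total_count
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    kept = []
    for chrom, center in anchors:
        if center - half_window < 0:
            continue
        if chrom_sizes is not None and center + half_window > chrom_sizes[chrom]:
            continue
        kept.append((chrom, center))
    if len(kept) < len(anchors):
        warnings.warn(
            f"dropped {len(anchors) - len(kept)} anchor(s) at chromosome edges",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no anchor window fits inside the genome")
    n_bins = 2 * half_window // bin_size
    scale = (bin_size / 1e3) * (total_mapped / 1e6)
    matrix = np.zeros((len(kept), n_bins))
    for i, (chrom, center) in enumerate(kept):
        w_start = center - half_window
        counts = np.zeros(n_bins, dtype=np.int64)
        for strand in ("W", "C"):
            pos = reads.positions(chrom, strand)
            lo = np.searchsorted(pos, w_start)
            hi = np.searchsorted(pos, center + half_window)
            if hi > lo:
                offs = (pos[lo:hi] - w_start) // bin_size
                counts += np.bincount(offs, minlength=n_bins)
        matrix[i] = counts / scale
    return MetaProfile(matrix, matrix.mean(axis=0), bin_size, half_window)


def gene_body_profile(
    reads: StrandedReadSet,
    genes: Sequence[GenomicInterval],
    n_relative_bins: int = 100,
    total_mapped: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """TSS->TES densities on a length-relative scale.

    Each gene body is divided into n_relative_bins equal parts (oriented TSS to
    TES using the gene's strand), each bin scaled to FPKM by its own width.
    Returns (per-gene mean FPKM over the body, mean relative profile).
    """
    if not genes:
        raise ValueError("empty gene set")
    if total_mapped is None:
        total_mapped = reads.total_count
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    per_gene = np.empty(len(genes))
    profiles = np.zeros((len(genes), n_relative_bins))
    for g, gene in enumerate(genes):
        edges = np.linspace(gene.start, gene.end, n_relative_bins + 1)
        counts = np.zeros(n_relative_bins)
        for strand in ("W", "C"):
            pos = reads.positions(gene.chrom, strand)
            lo = np.searchsorted(pos, gene.start)
            hi = np.searchsorted(pos, gene.end)
            if hi > lo:
                idx = np.clip(
                    np.searchsorted(edges, pos[lo:hi], side="right") - 1,
                    0,
                    n_relative_bins - 1,
                )
                counts += np.bincount(idx, minlength=n_relative_bins)
        widths = np.diff(edges)
        dens = counts / ((widths / 1e3) * (total_mapped / 1e6))
        if gene.strand == "-":
            dens = dens[::-1]
        profiles[g] = dens
        total = counts.sum()
        per_gene[g] = total / ((gene.length / 1e3) * (total_mapped / 1e6))
    return per_gene, profiles.mean(axis=0)
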