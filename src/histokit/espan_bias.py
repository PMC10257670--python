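"""Strand-partition bias of nascent-chromatin reads around replication origins.

eSPAN (enrichment and sequencing of protein-associated nascent DNA) reads are
counted per strand into fixed-width bins around each origin and turned into the
per-bin statistic

    bias = (W - C) / (W + C)

where W and C are the Watson- and Crick-strand read counts in the bin. A
matched BrdU-IP-ssSeq control profile is subtracted bin-wise to remove additive
technical strand bias, profiles are smoothed with a centered moving average,
averaged over origins, and folded into a single signed leading-strand score.

Sign convention (also used by the simulator): leading-strand nascent reads map
to the Watson strand left of an origin and to the Crick strand right of it, so
a positive leading-strand score means a leading-strand preference and, under
the simulator, the folded score estimates 2*p_lead - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_core import ChromSizes, GenomicInterval, StrandedReadSet, read_bed

__all__ = [
    "OriginSet",
    "StrandBinCountMatrix",
    "BiasProfile",
    "BiasSummary",
    "count_strand_reads",
    "bias_profile",
    "normalize_to_control",
    "smooth_profile",
    "aggregate_origins",
    "leading_bias_score",
    "espan_bias_pipeline",
]

DEFAULT_BIN_SIZE = 100
DEFAULT_HALF_WINDOW = 250_000
DEFAULT_FLANK_BINS = 1000


@dataclass(frozen=True)
class OriginSet:
    """Replication origins as (chrom, center) midpoints."""

    origins: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("duplicate (chrom, center) origin pairs")

    def __len__(self) -> int:
        return len(self.origins)

    @classmethod
    def from_intervals(cls, intervals: list[GenomicInterval]) -> "OriginSet":
        return cls(tuple((iv.chrom, iv.midpoint) for iv in intervals))

    @classmethod
    def from_bed(cls, path: str | Path) -> "OriginSet":
        return cls.from_intervals(read_bed(path))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, center in self.origins:
                fh.write(f"{chrom}\t{center}\t{center + 1}\n")


@dataclass
class StrandBinCountMatrix:
    """Per-origin Watson/Crick read counts in bins spanning +-half_window.

    Rows are origins; the 2K columns cover bin offsets -K .. K-1 around the
    center (column 0 is the bin [-half_window, -half_window + bin_size)).
    """

    W: np.ndarray
    C: np.ndarray
    bin_size: int
    half_window: int
    origins: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.W.shape != self.C.shape:
            raise ValueError("W and C shapes differ")
        n_bins = 2 * self.half_window // self.bin_size
        if self.W.shape[1] != n_bins:
            raise ValueError(
                f"expected {n_bins} bins for half_window={self.half_window}, "
                f"bin_size={self.bin_size}"
            )
        if (self.W < 0).any() or (self.C < 0).any():
            raise ValueError("negative counts")

    @property
    def n_origins(self) -> int:
        return self.W.shape[0]

    @property
    def n_bins(self) -> int:
        return self.W.shape[1]


@dataclass
class BiasProfile:
    """Per-bin bias values; NaN marks bins with no coverage (undefined).

    values is (n_origins, n_bins) for per-origin profiles or (n_bins,) for an
    origin-averaged meta profile. n_per_bin (meta only) records how many
    origins contributed a defined value to each bin.
    """

    values: np.ndarray
    bin_size: int
    half_window: int
    normalized: bool = False
    smoothed: bool = False
    flank_bins: int | None = None
    n_per_bin: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return self.values.shape[-1]

    @property
    def is_meta(self) -> bool:
        return self.values.ndim == 1

    def bin_offsets(self) -> np.ndarray:
        """Genomic offset (bp) of each bin's left edge relative to the center."""
        k = self.n_bins // 2
        return (np.arange(self.n_bins) - k) * self.bin_size

    def _check_geometry(self, other: "BiasProfile") -> None:
        if (self.bin_size, self.half_window) != (other.bin_size, other.half_window):
            raise ValueError("bin_size/half_window mismatch")
        if self.values.shape != other.values.shape:
            raise ValueError("profile shape mismatch")


@dataclass(frozen=True)
class BiasSummary:
    """Folded leading-strand bias score with the data support behind it."""

    leading_bias_score: float
    n_origins_used: int
    n_bins_defined: int


def count_strand_reads(
    reads: StrandedReadSet,
    origins: OriginSet,
    half_window: int = DEFAULT_HALF_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom_sizes: ChromSizes | None = None,
) -> StrandBinCountMatrix:
    """Bin W/C read 5' ends into per-origin windows of +-half_window.

    Origins whose window would cross a chromosome boundary are dropped with a
    warning (windows are never clipped, keeping the matrix rectangular).
    """
    if len(origins) == 0:
        raise ValueError("empty origin set")
    if half_window % bin_size != 0:
        raise ValueError("bin_size must divide half_window")
    kept: list[tuple[str, int]] = []
    dropped = 0
    for chrom, center in origins.origins:
        if center - half_window < 0:
            dropped += 1
            continue
        if chrom_sizes is not None and center + half_window > chrom_sizes[chrom]:
            dropped += 1
            continue
        kept.append((chrom, center))
    if dropped:
        warnings.warn(
            f"dropped {dropped} origin(s) whose window crosses a chromosome edge",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no origin window fits inside the genome")
    n_bins = 2 * half_window // bin_size
    W = np.zeros((len(kept), n_bins), dtype=np.int64)
    C = np.zeros_like(W)
    for i, (chrom, center) in enumerate(kept):
        w_start = center - half_window
        w_end = center + half_window
        for strand, mat in (("W", W), ("C", C)):
            pos = reads.positions(chrom, strand)
            lo = np.searchsorted(pos, w_start)
            hi = np.searchsorted(pos, w_end)
            if hi > lo:
                offs = (pos[lo:hi] - w_start) // bin_size
                mat[i] = np.bincount(offs, minlength=n_bins)
    return StrandBinCountMatrix(W, C, bin_size, half_window, tuple(kept))


def bias_profile(counts: StrandBinCountMatrix) -> BiasProfile:
    """Per-origin, per-bin (W-C)/(W+C); zero-coverage bins are NaN."""
    W = counts.W.astype(np.float32)
    C = counts.C.astype(np.float32)
    total = W + C
    bias = np.full(total.shape, np.nan, dtype=np.float32)
    np.divide(W - C, total, out=bias, where=total > 0)
    return BiasProfile(bias, counts.bin_size, counts.half_window)


def normalize_to_control(espan: BiasProfile, control: BiasProfile) -> BiasProfile:
    """Subtract the control (BrdU-IP-ssSeq) bias bin-wise.

    A bin is defined in the output only where both operands are defined;
    values then lie in [-2, 2].
    """
    espan._check_geometry(control)
    return BiasProfile(
        espan.values - control.values,
        espan.bin_size,
        espan.half_window,
        normalized=True,
        smoothed=espan.smoothed,
        flank_bins=espan.flank_bins,
    )


def _windowed_sums(x: np.ndarray, flank: int) -> np.ndarray:
    """Sum of x over [i-flank, i+flank] per position, truncated at the edges."""
    n = x.shape[-1]
    cs = np.cumsum(x, axis=-1)
    idx = np.arange(n)
    hi = cs[..., np.minimum(idx + flank, n - 1)]
    lo_idx = idx - flank - 1
    lo = np.where(lo_idx >= 0, cs[..., np.maximum(lo_idx, 0)], 0.0)
    return hi - lo


def smooth_profile(profile: BiasProfile, flank_bins: int = DEFAULT_FLANK_BINS) -> BiasProfile:
    """Centered moving average over [k-flank, k+flank] per bin.

    Undefined (NaN) bins are ignored inside the window; windows are truncated
    at the array edges rather than padded. flank_bins=0 is the identity.
    """
    if flank_bins < 0:
        raise ValueError("flank_bins must be >= 0")
    if flank_bins == 0:
        smoothed = profile.values.copy()
    else:
        defined = np.isfinite(profile.values)
        vals = np.where(defined, profile.values, 0.0)
        sums = _windowed_sums(vals, flank_bins)
        ns = _windowed_sums(defined.astype(float), flank_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(ns > 0, sums / ns, np.nan)
    return BiasProfile(
        smoothed,
        profile.bin_size,
        profile.half_window,
        normalized=profile.normalized,
        smoothed=True,
        flank_bins=flank_bins,
        n_per_bin=profile.n_per_bin,
    )


def aggregate_origins(profiles: BiasProfile) -> BiasProfile:
    """Average per-origin profiles into a meta profile, ignoring NaNs per bin.

    A bin is undefined only when it is undefined in every origin.
    """
    if profiles.is_meta:
        raise ValueError("expected a per-origin (2-D) profile")
    if profiles.values.shape[0] == 0:
        raise ValueError("no origins to aggregate")
    defined = np.isfinite(profiles.values)
    n = defined.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(profiles.values, axis=0)
    return BiasProfile(
        mean,
        profiles.bin_size,
        profiles.half_window,
        normalized=profiles.normalized,
        smoothed=profiles.smoothed,
        flank_bins=profiles.flank_bins,
        n_per_bin=n,
    )


def leading_bias_score(meta: BiasProfile, n_origins: int | None = None) -> BiasSummary:
    """Fold a meta profile into (mean left-flank bias - mean right-flank bias)/2.

    When the profile was smoothed, bins within flank_bins of the origin are
    excluded from both flank means: the moving-average window there straddles
    the origin, mixing leading- and lagging-dominated bins and attenuating the
    fold. Under the simulator's strand convention the score estimates
    2*p_lead - 1.
    """
    if not meta.is_meta:
        raise ValueError("leading_bias_score expects an aggregated meta profile")
    k = meta.n_bins // 2
    excl = meta.flank_bins if (meta.smoothed and meta.flank_bins) else 0
    if excl >= k:
        raise ValueError(
            f"smoothing flank ({excl} bins) leaves no usable bins in a "
            f"{k}-bin flank"
        )
    left = meta.values[: k - excl]
    right = meta.values[k + excl :]
    n_left, n_right = np.isfinite(left).sum(), np.isfinite(right).sum()
    if n_left == 0 or n_right == 0:
        raise ValueError("a flank is entirely undefined")
    score = float((np.nanmean(left) - np.nanmean(right)) / 2.0)
    if n_origins is None:
        n_origins = int(meta.n_per_bin.max()) if meta.n_per_bin is not None else 0
    return BiasSummary(score, n_origins, int(n_left + n_right))


def espan_bias_pipeline(
    espan_reads: StrandedReadSet,
    control_reads: StrandedReadSet,
    origins: OriginSet,
    half_window: int = DEFAULT_HALF_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    flank_bins: int = DEFAULT_FLANK_BINS,
    chrom_sizes: ChromSizes | None = None,
) -> tuple[BiasProfile, BiasSummary]:
    """Full count -> bias -> normalize -> smooth -> aggregate -> fold pipeline."""
    e_counts = count_strand_reads(espan_reads, origins, half_window, bin_size, chrom_sizes)
    c_counts = count_strand_reads(control_reads, origins, half_window, bin_size, chrom_sizes)
    norm = normalize_to_control(bias_profile(e_counts), bias_profile(c_counts))
    meta = aggregate_origins(smooth_profile(norm, flank_bins))
    return meta, leading_bias_score(meta, n_origins=e_counts.n_origins)
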