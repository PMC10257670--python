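"""Differential-peak classification, annotation enrichment, compartments, enhancers.

The enrichment statistic compares how much of the differential peak set (DP)
falls into an annotation type versus the matched stable peak set (SP):

    enrichment_ratio = log2( (obs_d / exp_d) / (obs_s / exp_s) )
    exp              = (L_anno / L_g) * L_set

with obs the bp overlap between a peak set and the annotation track, L_anno
the track's merged length, L_g the genome length and L_set the peak set's
merged length. The genome-wide factor L_anno/L_g cancels between numerator and
denominator, so the ratio equals log2((obs_d/L_d)/(obs_s/L_s)); both forms are
computed and must agree.

The differential classifier is a deliberately simple stand-in for a
dispersion-modeling package: a pseudocount-stabilized log2 fold change on mean
FPKM plus a two-sample t-test on log2(FPKM + eps) across replicates, with the
conventional cutoffs |log2FC| > 1 and P < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import (
    ChromSizes,
    GenomicInterval,
    merge_intervals,
    merged_length,
    overlap_length,
    read_bed,
)

__all__ = [
    "PeakRecord",
    "AnnotationCatalog",
    "CompartmentTrack",
    "EnrichmentResult",
    "DEFAULT_ANNOTATION_PRIORITY",
    "classify_peaks",
    "annotate_peaks",
    "enrichment_ratio",
    "compartment_proportions",
    "classify_enhancers",
]

DEFAULT_PSEUDOCOUNT = 0.1

# Homer-like single-label priority for point (midpoint) annotation.
DEFAULT_ANNOTATION_PRIORITY = [
    "promoter",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "TTS",
    "CpG_island",
    "LINE",
    "SINE",
    "LTR",
    "simple_repeat",
    "satellite",
]


@dataclass(frozen=True)
class PeakRecord:
    """A called peak with per-condition replicate FPKM values."""

    interval: GenomicInterval
    signal: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        if not self.signal:
            raise ValueError("peak with no signal entries")
        for cond, values in self.signal.items():
            if len(values) < 1:
                raise ValueError(f"condition {cond!r} has no replicates")
            if any(v < 0 for v in values):
                raise ValueError(f"negative FPKM in condition {cond!r}")


def classify_peaks(
    peaks: Sequence[PeakRecord],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.01,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    condition_numerator: str = "mutant",
    condition_denominator: str = "wt",
) -> pd.DataFrame:
    """Label peaks up/stable/down between two conditions.

    Returns a DataFrame (one row per peak, in input order) with columns
    chrom/start/end/name, log2fc, pvalue, category. log2FC is computed on mean
    FPKM with a pseudocount; the p-value is a two-sided two-sample t-test on
    log2(FPKM + pseudocount) when both conditions have >=2 replicates, else 1.
    """
    rows = []
    for peak in peaks:
        try:
            num = np.asarray(peak.signal[condition_numerator], dtype=float)
            den = np.asarray(peak.signal[condition_denominator], dtype=float)
        except KeyError as exc:
            raise ValueError(f"peak missing condition {exc}") from exc
        log2fc = float(
            np.log2((num.mean() + pseudocount) / (den.mean() + pseudocount))
        )
        if len(num) >= 2 and len(den) >= 2:
            a = np.log2(num + pseudocount)
            b = np.log2(den + pseudocount)
            if a.std() == 0 and b.std() == 0:
                # degenerate noiseless replicates: the test statistic diverges
                pvalue = 1.0 if a.mean() == b.mean() else 0.0
            else:
                pvalue = float(stats.ttest_ind(a, b).pvalue)
        else:
            pvalue = 1.0
        if log2fc > lfc_threshold and pvalue < p_threshold:
            category = "up"
        elif log2fc < -lfc_threshold and pvalue < p_threshold:
            category = "down"
        else:
            category = "stable"
        iv = peak.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "log2fc": log2fc,
                "pvalue": pvalue,
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "log2fc", "pvalue", "category"],
    )


@dataclass
class AnnotationCatalog:
    """Named annotation tracks (merged per track) plus genome sizes and priority.

    Track names missing from the priority list are appended at lowest priority
    so the priority order always covers every track.
    """

    tracks: dict[str, dict[str, np.ndarray]]
    chrom_sizes: ChromSizes
    priority: list[str] = field(default_factory=lambda: list(DEFAULT_ANNOTATION_PRIORITY))

    def __post_init__(self) -> None:
        self.tracks = {
            name: merge_intervals(track) for name, track in self.tracks.items()
        }
        for name in self.tracks:
            if name not in self.priority:
                self.priority.append(name)

    @classmethod
    def from_tracks(
        cls,
        tracks: Mapping[str, Sequence[GenomicInterval]],
        chrom_sizes: ChromSizes,
        priority: list[str] | None = None,
    ) -> "AnnotationCatalog":
        merged = {name: merge_intervals(ivs) for name, ivs in tracks.items()}
        if priority is None:
            return cls(merged, chrom_sizes)
        return cls(merged, chrom_sizes, list(priority))

    @classmethod
    def from_config(cls, config_path: str | Path) -> "AnnotationCatalog":
        """Load from a YAML config: {chrom_sizes: path, tracks: {name: bed_path}}."""
        import yaml

        from .genomic_core import read_chrom_sizes

        base = Path(config_path).parent
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
        sizes = read_chrom_sizes(base / cfg["chrom_sizes"])
        tracks = {
            name: read_bed(base / path) for name, path in cfg["tracks"].items()
        }
        priority = cfg.get("priority")
        return cls.from_tracks(tracks, sizes, priority)

    def track_length(self, name: str) -> int:
        return merged_length(self.tracks[name])

    def contains_point(self, name: str, chrom: str, pos: int) -> bool:
        arr = self.tracks[name].get(chrom)
        if arr is None or arr.size == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]


def annotate_peaks(
    peaks: Sequence[GenomicInterval], catalog: AnnotationCatalog
) -> list[str]:
    """Assign each peak the highest-priority annotation containing its midpoint.

    Peaks hitting no track are labeled 'intergenic'.
    """
    labels = []
    for peak in peaks:
        mid = peak.midpoint
        for name in catalog.priority:
            if name in catalog.tracks and catalog.contains_point(
                name, peak.chrom, mid
            ):
                labels.append(name)
                break
        else:
            labels.append("intergenic")
    return labels


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected bp overlaps and the log2 enrichment ratio for one type."""

    annotation: str
    obs_d: int
    exp_d: float
    obs_s: int
    exp_s: float
    L_d: int
    L_s: int
    L_anno: int
    ratio: float
    defined: bool


def enrichment_ratio(
    diff_peaks: Sequence[GenomicInterval],
    stable_peaks: Sequence[GenomicInterval],
    catalog: AnnotationCatalog,
) -> dict[str, EnrichmentResult]:
    """Relative annotation enrichment of differential vs stable peaks, per type.

    Undefined (ratio NaN, defined=False) whenever obs_d or obs_s is zero; no
    pseudocount is applied.
    """
    L_g = catalog.chrom_sizes.total_length
    if L_g == 0:
        raise ValueError("genome length is zero")
    d_merged = merge_intervals(diff_peaks)
    s_merged = merge_intervals(stable_peaks)
    L_d = merged_length(d_merged)
    L_s = merged_length(s_merged)
    if L_d == 0 or L_s == 0:
        raise ValueError("differential and stable peak sets must be non-empty")
    out: dict[str, EnrichmentResult] = {}
    for name, track in catalog.tracks.items():
        L_anno = merged_length(track)
        obs_d = overlap_length(d_merged, track)
        obs_s = overlap_length(s_merged, track)
        exp_d = L_anno / L_g * L_d
        exp_s = L_anno / L_g * L_s
        defined = obs_d > 0 and obs_s > 0
        ratio = (
            float(np.log2((obs_d / exp_d) / (obs_s / exp_s))) if defined else float("nan")
        )
        out[name] = EnrichmentResult(
            name, obs_d, exp_d, obs_s, exp_s, L_d, L_s, L_anno, ratio, defined
        )
    return out


def enrichment_table(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "annotation": r.annotation,
                "obs_d": r.obs_d,
                "exp_d": r.exp_d,
                "obs_s": r.obs_s,
                "exp_s": r.exp_s,
                "ratio": r.ratio,
                "defined": r.defined,
            }
            for r in results.values()
        ]
    )


class CompartmentTrack:
    """Genome intervals labeled A (open) or B (closed), merged per label."""

    def __init__(self, a_intervals: Sequence[GenomicInterval], b_intervals: Sequence[GenomicInterval]):
        self.a = merge_intervals(a_intervals) if a_intervals else {}
        self.b = merge_intervals(b_intervals) if b_intervals else {}

    @classmethod
    def from_bed(cls, path: str | Path) -> "CompartmentTrack":
        """BED with 'A' or 'B' in the name column."""
        a, b = [], []
        for iv in read_bed(path):
            if iv.name == "A":
                a.append(iv)
            elif iv.name == "B":
                b.append(iv)
            else:
                raise ValueError(
                    f"compartment label must be 'A' or 'B', got {iv.name!r}"
                )
        return cls(a, b)

    def assign(self, peak: GenomicInterval) -> str:
        """Majority-bp-overlap label; zero overlap or an exact tie -> 'unassigned'."""
        single = {peak.chrom: np.array([[peak.start, peak.end]], dtype=np.int64)}
        ov_a = overlap_length(single, self.a)
        ov_b = overlap_length(single, self.b)
        if ov_a == ov_b:
            return "unassigned"
        return "A" if ov_a > ov_b else "B"


def compartment_proportions(
    peak_table: pd.DataFrame, compartments: CompartmentTrack
) -> pd.DataFrame:
    """Per peak category, the proportion of peaks assigned A / B / unassigned.

    peak_table needs chrom/start/end/category columns (classify_peaks output).
    Rows sum to 1 for every category with at least one peak.
    """
    labels = [
        compartments.assign(GenomicInterval(row.chrom, row.start, row.end))
        for row in peak_table.itertuples()
    ]
    df = peak_table.assign(compartment=labels)
    counts = (
        df.groupby(["category", "compartment"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["A", "B", "unassigned"], fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def classify_enhancers(
    k4me1_peaks: Sequence[GenomicInterval],
    k4me3_peaks: Sequence[GenomicInterval],
    k27ac_peaks: Sequence[GenomicInterval],
    k27me3_peaks: Sequence[GenomicInterval],
    tss_set: Sequence[tuple[str, int]],
    exclusion_bp: int = 2500,
) -> list[tuple[GenomicInterval, str]]:
    """Classify H3K4me1 peaks as enhancers by mark co-occupancy.

    Rule order per candidate H3K4me1 peak: overlapping any H3K4me3 peak ->
    'not_enhancer' (enhancers are H3K4me3-depleted); midpoint within
    exclusion_bp of a TSS -> 'excluded_near_TSS'; overlapping H3K27ac ->
    'active'; else overlapping H3K27me3 -> 'repressed'; else 'poised'.
    """
    k4me3 = merge_intervals(k4me3_peaks) if k4me3_peaks else {}
    k27ac = merge_intervals(k27ac_peaks) if k27ac_peaks else {}
    k27me3 = merge_intervals(k27me3_peaks) if k27me3_peaks else {}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in tss_set}:
        tss_by_chrom[chrom] = np.sort(
            np.array([p for c, p in tss_set if c == chrom], dtype=np.int64)
        )

    def overlaps(peak: GenomicInterval, track: Mapping[str, np.ndarray]) -> bool:
        single = {peak.chrom: np.array([[peak.start, peak.end]], dtype=np.int64)}
        return overlap_length(single, track) > 0

    out = []
    for peak in k4me1_peaks:
        if overlaps(peak, k4me3):
            out.append((peak, "not_enhancer"))
            continue
        mid = peak.midpoint
        tss = tss_by_chrom.get(peak.chrom)
        near_tss = False
        if tss is not None and tss.size:
            i = int(np.searchsorted(tss, mid))
            for j in (i - 1, i):
                if 0 <= j < tss.size and abs(int(tss[j]) - mid) <= exclusion_bp:
                    near_tss = True
        if near_tss:
            out.append((peak, "excluded_near_TSS"))
        elif overlaps(peak, k27ac):
            out.append((peak, "active"))
        elif overlaps(peak, k27me3):
            out.append((peak, "repressed"))
        else:
            out.append((peak, "poised"))
    return out
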