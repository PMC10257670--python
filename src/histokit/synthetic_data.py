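"""Seeded generators for every pipeline stage, with ground truth for recovery tests.

Each generator emulates the statistical structure one analysis stage assumes:

* strand-specific nascent reads around replication origins with a tunable
  leading-strand transfer probability p_lead plus a BrdU-like control,
* peak sets with planted up/stable/down fold changes and planted
  annotation-placement probabilities,
* genome-binned multi-mark FPKM with a planted log-ratio correlation matrix,
* (cell, UMI, lineage barcode) triples with planted clones and substitution
  errors,
* a toy annotation catalog (feature tracks, A/B compartments, genes).

All generators are deterministic given their seed; writing the same simulation
twice yields byte-identical files. The strand convention matches the bias
module: leading-strand reads map to Watson left of an origin and to Crick
right of it, so the folded bias score estimates 2*p_lead - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .espan_bias import DEFAULT_BIN_SIZE, DEFAULT_HALF_WINDOW, OriginSet
from .genomic_core import (
    ChromSizes,
    GenomicInterval,
    StrandedReadSet,
    write_bed,
    write_chrom_sizes,
)
from .peak_reprogramming import AnnotationCatalog, CompartmentTrack, PeakRecord

__all__ = [
    "EspanSimConfig",
    "PeakSimConfig",
    "BinnedMarkSimConfig",
    "BarcodeSimConfig",
    "GenomeSimConfig",
    "SimulationConfig",
    "EspanSimulation",
    "PeakSimulation",
    "BinnedMarkSimulation",
    "BarcodeSimulation",
    "GenomeAnnotationSimulation",
    "simulate_genome_annotation",
    "simulate_espan_experiment",
    "simulate_peak_experiment",
    "simulate_binned_marks",
    "simulate_barcode_data",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class EspanSimConfig:
    """Conditions for the strand-bias experiment simulator."""

    n_origins: int = 200
    reads_per_origin: int = 500
    p_lead: float = 0.875
    control_bias: float = 0.0
    half_window: int = DEFAULT_HALF_WINDOW
    bin_size: int = DEFAULT_BIN_SIZE
    origin_gap: int = 50_000  # spacing between adjacent origin windows

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_lead <= 1.0:
            raise ValueError("p_lead must lie in [0.5, 1]")
        eff = self.p_lead + self.control_bias / 2.0
        if not 0.0 <= eff <= 1.0:
            raise ValueError("p_lead + control_bias/2 outside [0, 1]")
        if not 0.0 <= 0.5 + self.control_bias / 2.0 <= 1.0:
            raise ValueError("control_bias outside [-1, 1]")


@dataclass(frozen=True)
class PeakSimConfig:
    """Planted differential/stable peak sets over a toy annotated genome."""

    n_up: int = 500
    n_down: int = 0
    n_stable: int = 500
    peak_length: int = 500
    annotation_fraction_diff: float = 0.5
    annotation_fraction_stable: float = 0.25
    planted_lfc_low: float = 1.5
    planted_lfc_high: float = 3.0
    base_fpkm: float = 10.0
    noise_sd: float = 0.1  # lognormal sigma on replicate FPKM
    n_replicates: int = 2


@dataclass(frozen=True)
class BinnedMarkSimConfig:
    """Genome-binned marks with a planted log2-ratio correlation matrix."""

    n_bins: int = 2000
    marks: tuple[str, ...] = ("H3K27me3", "H3K4me1")
    correlation: tuple[tuple[float, ...], ...] = ((1.0, 0.8), (0.8, 1.0))
    log_ratio_sd: float = 1.0
    base_fpkm: float = 10.0
    base_sd: float = 0.5  # lognormal sigma on the shared per-bin baseline
    bin_size: int = 10_000


@dataclass(frozen=True)
class BarcodeSimConfig:
    """Planted clones emitting (cell, UMI, lineage barcode) triples."""

    n_clones: int = 30
    mean_clone_size: float = 8.0  # geometric, truncated at 1
    barcode_length: int = 20
    umis_per_cell: int = 3
    reads_per_umi: int = 10
    substitution_rate: float = 0.1  # per emitted copy, at most one substitution
    umi_length: int = 10
    min_pairwise_hamming: int = 8  # collision control between clone barcodes


@dataclass(frozen=True)
class GenomeSimConfig:
    """Toy genome and annotation-catalog geometry."""

    chrom_sizes: tuple[tuple[str, int], ...] = (("chrS1", 2_000_000), ("chrS2", 1_000_000))
    track_fractions: tuple[tuple[str, float], ...] = (
        ("promoter", 0.05),
        ("exon", 0.10),
        ("intron", 0.20),
        ("LINE", 0.10),
        ("CpG_island", 0.02),
    )
    feature_length: int = 1000
    compartment_size: int = 100_000
    n_genes: int = 200
    gene_length: int = 5000


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of per-stage configurations plus the master seed."""

    seed: int = 0
    espan: EspanSimConfig = field(default_factory=EspanSimConfig)
    peaks: PeakSimConfig = field(default_factory=PeakSimConfig)
    binned_marks: BinnedMarkSimConfig = field(default_factory=BinnedMarkSimConfig)
    barcodes: BarcodeSimConfig = field(default_factory=BarcodeSimConfig)
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)


# ---------------------------------------------------------------------------
# eSPAN


@dataclass
class EspanSimulation:
    espan_reads: StrandedReadSet
    control_reads: StrandedReadSet
    origins: OriginSet
    chrom_sizes: ChromSizes
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.espan_reads.to_bed6(outdir / "espan_reads.bed")
        self.control_reads.to_bed6(outdir / "control_reads.bed")
        self.origins.to_bed(outdir / "origins.bed")
        write_chrom_sizes(self.chrom_sizes, outdir / "genome.chrom.sizes")


def _draw_stranded_reads(
    rng: np.random.Generator,
    centers: np.ndarray,
    chrom: str,
    reads_per_origin: int,
    half_window: int,
    p_watson_given_left: float,
) -> StrandedReadSet:
    """Reads uniform over each origin's two flanks with the stated strand rule.

    A read left of its origin is Watson with probability p (leading-type) and
    Crick otherwise; the right side is the mirror image.
    """
    n_origins = len(centers)
    n = n_origins * reads_per_origin
    origin_idx = np.repeat(np.arange(n_origins), reads_per_origin)
    left = rng.random(n) < 0.5
    offset = rng.integers(0, half_window, n)
    pos = np.where(
        left,
        centers[origin_idx] - half_window + offset,
        centers[origin_idx] + offset,
    )
    leading = rng.random(n) < p_watson_given_left
    watson = np.where(left, leading, ~leading)
    return StrandedReadSet(
        (chrom, int(p), "W" if w else "C") for p, w in zip(pos, watson)
    )


def simulate_espan_experiment(
    config: EspanSimConfig = EspanSimConfig(), seed: int = 0
) -> EspanSimulation:
    """Generate eSPAN + control reads around evenly spaced origins.

    The eSPAN reads use an effective leading probability p_lead +
    control_bias/2 and the control uses 0.5 + control_bias/2, so subtracting
    the control bias profile cancels the planted technical bias and the folded
    score targets 2*p_lead - 1.
    """
    rng = np.random.default_rng(seed)
    c = config
    pitch = 2 * c.half_window + c.origin_gap
    centers = c.origin_gap + c.half_window + pitch * np.arange(c.n_origins)
    chrom = "chrE"
    length = int(centers[-1] + c.half_window + c.origin_gap)
    sizes = ChromSizes({chrom: length})
    origins = OriginSet(tuple((chrom, int(x)) for x in centers))
    p_espan = c.p_lead + c.control_bias / 2.0
    p_control = 0.5 + c.control_bias / 2.0
    espan = _draw_stranded_reads(
        rng, centers, chrom, c.reads_per_origin, c.half_window, p_espan
    )
    control = _draw_stranded_reads(
        rng, centers, chrom, c.reads_per_origin, c.half_window, p_control
    )
    truth = {
        "p_lead": c.p_lead,
        "control_bias": c.control_bias,
        "expected_score": 2.0 * c.p_lead - 1.0,
        "origin_centers": [int(x) for x in centers],
    }
    return EspanSimulation(espan, control, origins, sizes, truth)


# ---------------------------------------------------------------------------
# genome annotation


@dataclass
class GenomeAnnotationSimulation:
    catalog: AnnotationCatalog
    compartments: CompartmentTrack
    compartment_intervals: list[GenomicInterval]
    genes: list[GenomicInterval]
    chrom_sizes: ChromSizes

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.chrom_sizes, outdir / "genome.chrom.sizes")
        for name, track in self.catalog.tracks.items():
            ivs = [
                GenomicInterval(chrom, int(s), int(e))
                for chrom, arr in sorted(track.items())
                for s, e in arr
            ]
            write_bed(ivs, outdir / f"{name}.bed")
        write_bed(self.compartment_intervals, outdir / "compartments.bed")
        write_bed(self.genes, outdir / "genes.bed")


def _place_disjoint_features(
    rng: np.random.Generator, chrom: str, chrom_len: int, fraction: float, feat_len: int
) -> list[GenomicInterval]:
    """Place non-overlapping fixed-length features covering ~fraction of the chromosome."""
    n_features = int(round(fraction * chrom_len / feat_len))
    if n_features == 0:
        return []
    # choose starts on a lattice twice the feature length, guaranteeing disjointness
    pitch = 2 * feat_len
    n_slots = chrom_len // pitch
    if n_features > n_slots:
        raise ValueError(
            f"fraction {fraction} with feature length {feat_len} does not fit "
            f"disjointly on {chrom}"
        )
    slots = rng.choice(n_slots, size=n_features, replace=False)
    slots.sort()
    return [
        GenomicInterval(chrom, int(s * pitch), int(s * pitch + feat_len))
        for s in slots
    ]


def simulate_genome_annotation(
    config: GenomeSimConfig = GenomeSimConfig(), seed: int = 0
) -> GenomeAnnotationSimulation:
    """Toy annotation catalog, alternating A/B compartments, and gene models."""
    rng = np.random.default_rng(seed)
    c = config
    sizes = ChromSizes(dict(c.chrom_sizes))
    for name, fraction in c.track_fractions:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"track {name!r}: fraction {fraction} outside [0, 1]")
    tracks: dict[str, list[GenomicInterval]] = {}
    for name, fraction in c.track_fractions:
        ivs: list[GenomicInterval] = []
        for chrom, chrom_len in sizes.items():
            ivs.extend(
                _place_disjoint_features(rng, chrom, chrom_len, fraction, c.feature_length)
            )
        tracks[name] = ivs
    comp_ivs: list[GenomicInterval] = []
    a_ivs, b_ivs = [], []
    for chrom, chrom_len in sizes.items():
        for i, start in enumerate(range(0, chrom_len, c.compartment_size)):
            end = min(start + c.compartment_size, chrom_len)
            label = "A" if i % 2 == 0 else "B"
            iv = GenomicInterval(chrom, start, end, name=label)
            comp_ivs.append(iv)
            (a_ivs if label == "A" else b_ivs).append(iv)
    genes: list[GenomicInterval] = []
    chroms = list(sizes)
    for g in range(c.n_genes):
        chrom = chroms[g % len(chroms)]
        start = int(rng.integers(0, sizes[chrom] - c.gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GenomicInterval(chrom, start, start + c.gene_length, strand, f"gene{g}")
        )
    catalog = AnnotationCatalog.from_tracks(tracks, sizes)
    return GenomeAnnotationSimulation(
        catalog, CompartmentTrack(a_ivs, b_ivs), comp_ivs, genes, sizes
    )


# ---------------------------------------------------------------------------
# peaks


@dataclass
class PeakSimulation:
    peaks: list[PeakRecord]
    catalog: AnnotationCatalog
    chrom_sizes: ChromSizes
    truth: pd.DataFrame  # peak name, true category, planted lfc, in_annotation

    def records_by_category(self, category: str) -> list[PeakRecord]:
        names = set(self.truth[self.truth["category"] == category]["name"])
        return [p for p in self.peaks if p.interval.name in names]

    def intervals_by_category(self, category: str) -> list[GenomicInterval]:
        return [p.interval for p in self.records_by_category(category)]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed([p.interval for p in self.peaks], outdir / "peaks.bed")
        rows = []
        for p in self.peaks:
            for cond, reps in p.signal.items():
                for i, fpkm in enumerate(reps):
                    rows.append(
                        {
                            "peak_id": p.interval.name,
                            "condition": cond,
                            "replicate": i + 1,
                            "fpkm": fpkm,
                        }
                    )
        pd.DataFrame(rows).to_csv(outdir / "signal.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_peak_experiment(
    config: PeakSimConfig = PeakSimConfig(), seed: int = 0
) -> PeakSimulation:
    """Plant peaks with known categories and annotation-overlap probabilities.

    A single 'promoter' annotation track is laid out on a 10-Mb toy
    chromosome; each peak lands fully inside the track with its category's
    planted probability and fully outside otherwise. Replicate FPKM values are
    the planted condition mean times lognormal noise.
    """
    rng = np.random.default_rng(seed)
    c = config
    chrom = "chrP"
    chrom_len = 10_000_000
    sizes = ChromSizes({chrom: chrom_len})
    # promoters every 5 kb: feature [i*5000, i*5000+1000)
    feat_len, pitch = 1000, 5000
    promoters = [
        GenomicInterval(chrom, s, s + feat_len)
        for s in range(0, chrom_len - feat_len, pitch)
    ]
    catalog = AnnotationCatalog.from_tracks({"promoter": promoters}, sizes)
    n_slots = chrom_len // pitch - 1

    def place(inside: bool) -> GenomicInterval:
        slot = int(rng.integers(0, n_slots))
        base = slot * pitch
        if inside:
            start = base + int(rng.integers(0, feat_len - c.peak_length + 1))
        else:
            # the [base+feat_len, base+pitch) gap, clear of the track
            start = (
                base
                + feat_len
                + int(rng.integers(0, pitch - feat_len - c.peak_length + 1))
            )
        return GenomicInterval(chrom, start, start + c.peak_length)

    specs = (
        [("up", c.annotation_fraction_diff)] * c.n_up
        + [("down", c.annotation_fraction_diff)] * c.n_down
        + [("stable", c.annotation_fraction_stable)] * c.n_stable
    )
    peaks: list[PeakRecord] = []
    truth_rows = []
    for i, (category, frac) in enumerate(specs):
        inside = bool(rng.random() < frac)
        iv = place(inside)
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak{i}")
        if category == "stable":
            lfc = 0.0
        else:
            mag = float(rng.uniform(c.planted_lfc_low, c.planted_lfc_high))
            lfc = mag if category == "up" else -mag
        wt_mean = c.base_fpkm
        mut_mean = c.base_fpkm * 2.0**lfc
        noise = lambda: float(rng.lognormal(0.0, c.noise_sd)) if c.noise_sd > 0 else 1.0
        signal = {
            "wt": [wt_mean * noise() for _ in range(c.n_replicates)],
            "mutant": [mut_mean * noise() for _ in range(c.n_replicates)],
        }
        peaks.append(PeakRecord(iv, signal))
        truth_rows.append(
            {
                "name": f"peak{i}",
                "category": category,
                "planted_lfc": lfc,
                "in_annotation": inside,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return PeakSimulation(peaks, catalog, sizes, truth)


# ---------------------------------------------------------------------------
# binned marks


@dataclass
class BinnedMarkSimulation:
    matrices: dict[str, pd.DataFrame]  # mark -> bins x {wt, mutant} FPKM
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for mark, df in self.matrices.items():
            df.reset_index().to_csv(outdir / f"{mark}.binned_fpkm.tsv", sep="\t", index=False)


def simulate_binned_marks(
    config: BinnedMarkSimConfig = BinnedMarkSimConfig(), seed: int = 0
) -> BinnedMarkSimulation:
    """Per-bin log2 change ratios from a multivariate normal with planted correlation.

    Each bin carries a shared lognormal WT baseline per mark; the mutant signal
    is the baseline scaled by 2**z with z drawn from N(0, sd^2 * correlation).
    """
    rng = np.random.default_rng(seed)
    c = config
    corr = np.asarray(c.correlation, dtype=float)
    if corr.shape != (len(c.marks), len(c.marks)):
        raise ValueError("correlation matrix shape does not match the mark list")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    cov = corr * c.log_ratio_sd**2
    z = rng.multivariate_normal(
        np.zeros(len(c.marks)), cov, size=c.n_bins, method="svd"
    )
    index = pd.MultiIndex.from_tuples(
        [("chrB", i * c.bin_size, (i + 1) * c.bin_size) for i in range(c.n_bins)],
        names=["chrom", "start", "end"],
    )
    matrices = {}
    for m, mark in enumerate(c.marks):
        wt = c.base_fpkm * rng.lognormal(0.0, c.base_sd, size=c.n_bins)
        mut = wt * 2.0 ** z[:, m]
        matrices[mark] = pd.DataFrame({"wt": wt, "mutant": mut}, index=index)
    truth = {"correlation": corr, "log_ratios": z, "marks": list(c.marks)}
    return BinnedMarkSimulation(matrices, truth)


# ---------------------------------------------------------------------------
# barcodes


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class BarcodeSimulation:
    triples: pd.DataFrame
    truth_clones: pd.DataFrame  # clone_id (planted barcode), cell_barcode
    truth_sizes: pd.Series  # clone_id -> planted size (incl. singleton lineages)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.triples.to_csv(outdir / "triples.tsv", sep="\t", index=False)
        self.truth_clones.to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, length)]).decode()


def simulate_barcode_data(
    config: BarcodeSimConfig = BarcodeSimConfig(), seed: int = 0
) -> BarcodeSimulation:
    """Planted clones emitting noisy (cell, UMI, lineage barcode) triples.

    Clone sizes are geometric (truncated at 1). Each cell carries
    umis_per_cell UMIs; each emitted barcode copy independently carries at
    most one substitution, with the configured probability. Clone barcodes are
    redrawn until pairwise hamming >= min_pairwise_hamming (a warning is
    emitted if that takes many attempts, indicating a collision-prone
    length/count combination).
    """
    rng = np.random.default_rng(seed)
    c = config
    clone_barcodes: list[str] = []
    attempts = 0
    while len(clone_barcodes) < c.n_clones:
        candidate = _random_barcode(rng, c.barcode_length)
        attempts += 1
        cand_vec = np.frombuffer(candidate.encode(), dtype=np.uint8)
        ok = all(
            (np.frombuffer(bc.encode(), dtype=np.uint8) != cand_vec).sum()
            >= c.min_pairwise_hamming
            for bc in clone_barcodes
        )
        if ok:
            clone_barcodes.append(candidate)
    if attempts > 2 * c.n_clones:
        warnings.warn(
            "barcode collisions frequent at configured length/count",
            stacklevel=2,
        )
    sizes = rng.geometric(1.0 / c.mean_clone_size, size=c.n_clones)
    rows = []
    truth_rows = []
    cell_counter = 0
    for clone_id, (barcode, size) in enumerate(zip(clone_barcodes, sizes)):
        for _ in range(int(size)):
            cell = f"CELL{cell_counter:06d}"
            cell_counter += 1
            truth_rows.append({"clone_id": barcode, "cell_barcode": cell})
            umis: set[str] = set()
            while len(umis) < c.umis_per_cell:
                umis.add(_random_barcode(rng, c.umi_length))
            for umi in sorted(umis):
                emitted = barcode
                if rng.random() < c.substitution_rate:
                    pos = int(rng.integers(0, c.barcode_length))
                    current = emitted[pos]
                    choices = [b for b in "ACGT" if b != current]
                    emitted = (
                        emitted[:pos]
                        + choices[int(rng.integers(0, 3))]
                        + emitted[pos + 1 :]
                    )
                rows.append(
                    {
                        "cell_barcode": cell,
                        "umi": umi,
                        "lineage_barcode": emitted,
                        "read_count": c.reads_per_umi,
                    }
                )
    triples = pd.DataFrame(
        rows, columns=["cell_barcode", "umi", "lineage_barcode", "read_count"]
    )
    truth_clones = pd.DataFrame(truth_rows, columns=["clone_id", "cell_barcode"])
    truth_sizes = pd.Series(
        sizes.astype(int), index=pd.Index(clone_barcodes, name="clone_id"), name="size"
    )
    return BarcodeSimulation(triples, truth_clones, truth_sizes)
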