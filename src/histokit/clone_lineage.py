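"""Lineage-barcode clone calling from (cell barcode, UMI, lineage barcode) triples.

The pipeline mirrors LARRY-style clonal annotation: keep triples supported by
at least 10 reads, collapse lineage barcodes within hamming distance 3 by
greedy abundance-ranked clustering, assign each cell to the lineage backed by
at least 3 distinct UMIs, and call every lineage with >=2 assigned cells a
clone. Clones are grouped by size (2-10, 11-20, >20) and clones with more than
20 cells are flagged dominant.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "load_triples",
    "filter_triples",
    "collapse_lineage_barcodes",
    "apply_collapse",
    "assign_cells",
    "clone_statistics",
    "dominant_clone_cluster_density",
    "hamming_distance",
    "size_group",
]

DEFAULT_MIN_READS = 10
DEFAULT_MAX_HAMMING = 3
DEFAULT_MIN_UMIS = 3
DOMINANT_SIZE = 20  # strictly greater-than

TRIPLE_COLUMNS = ["cell_barcode", "umi", "lineage_barcode", "read_count"]


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("barcodes of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _validate_triples(df: pd.DataFrame) -> None:
    missing = [c for c in TRIPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    if len(df):
        lengths = df["lineage_barcode"].str.len().unique()
        if len(lengths) > 1:
            raise ValueError(
                f"lineage barcodes of unequal length: {sorted(lengths)}"
            )
        if (df["read_count"] < 1).any():
            raise ValueError("read_count must be >= 1")


def load_triples(path: str | Path) -> pd.DataFrame:
    """Read a (cell_barcode, umi, lineage_barcode, read_count) TSV.

    Duplicate triples have their read counts summed.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "cell_barcode": str,
            "umi": str,
            "lineage_barcode": str,
        },
    )
    _validate_triples(df)
    df = (
        df.groupby(["cell_barcode", "umi", "lineage_barcode"], as_index=False, sort=True)
        .agg(read_count=("read_count", "sum"))
    )
    return df[TRIPLE_COLUMNS]


def filter_triples(triples: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Keep triples supported by at least min_reads reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    _validate_triples(triples)
    return triples[triples["read_count"] >= min_reads].reset_index(drop=True)


def collapse_lineage_barcodes(
    triples: pd.DataFrame, max_hamming: int = DEFAULT_MAX_HAMMING
) -> dict[str, str]:
    """Greedy abundance-ranked barcode clustering.

    Barcodes are sorted by total read support descending (lexicographic
    tie-break); each joins the first (highest-ranked) existing representative
    within hamming <= max_hamming, else becomes a representative itself.
    Representatives map to themselves.
    """
    _validate_triples(triples)
    if not len(triples):
        return {}
    support = (
        triples.groupby("lineage_barcode")["read_count"].sum().sort_index()
    )
    order = support.sort_values(ascending=False, kind="stable").index.tolist()
    length = len(order[0])
    codes = {bc: np.frombuffer(bc.encode(), dtype=np.uint8) for bc in order}
    reps: list[str] = []
    rep_matrix = np.empty((0, length), dtype=np.uint8)
    mapping: dict[str, str] = {}
    for bc in order:
        vec = codes[bc]
        if rep_matrix.shape[0]:
            dists = (rep_matrix != vec).sum(axis=1)
            hits = np.nonzero(dists <= max_hamming)[0]
            if hits.size:
                mapping[bc] = reps[int(hits[0])]
                continue
        mapping[bc] = bc
        reps.append(bc)
        rep_matrix = np.vstack([rep_matrix, vec])
    return mapping


def apply_collapse(triples: pd.DataFrame, collapse_map: Mapping[str, str]) -> pd.DataFrame:
    """Replace lineage barcodes by their representatives and re-aggregate."""
    df = triples.assign(
        lineage_barcode=triples["lineage_barcode"].map(collapse_map)
    )
    if df["lineage_barcode"].isna().any():
        raise ValueError("collapse map does not cover all barcodes")
    return (
        df.groupby(["cell_barcode", "umi", "lineage_barcode"], as_index=False, sort=True)
        .agg(read_count=("read_count", "sum"))
    )[TRIPLE_COLUMNS]


def assign_cells(
    collapsed_triples: pd.DataFrame, min_umis: int = DEFAULT_MIN_UMIS
) -> pd.DataFrame:
    """Assign each cell to the lineage with maximal distinct-UMI support.

    A cell is assigned only if its best support is >= min_umis and the maximum
    is unique; exact ties leave the cell unassigned. Returns a DataFrame with
    columns cell_barcode, lineage (NaN when unassigned), n_umis.
    """
    _validate_triples(collapsed_triples)
    rows = []
    if len(collapsed_triples):
        support = (
            collapsed_triples.groupby(["cell_barcode", "lineage_barcode"])["umi"]
            .nunique()
            .rename("n_umis")
            .reset_index()
        )
        for cell, grp in support.groupby("cell_barcode", sort=True):
            best = grp["n_umis"].max()
            winners = grp[grp["n_umis"] == best]
            if best >= min_umis and len(winners) == 1:
                rows.append(
                    {
                        "cell_barcode": cell,
                        "lineage": winners["lineage_barcode"].iloc[0],
                        "n_umis": int(best),
                    }
                )
            else:
                rows.append(
                    {"cell_barcode": cell, "lineage": np.nan, "n_umis": int(best)}
                )
    return pd.DataFrame(rows, columns=["cell_barcode", "lineage", "n_umis"])


def size_group(size: int) -> str:
    if size > 20:
        return ">20"
    if size > 10:
        return "11-20"
    return "2-10"


def clone_statistics(
    assignments: pd.DataFrame,
    sample_labels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call clones (lineages with >=2 assigned cells) and size-group summaries.

    Returns (clone_table, group_percentages). clone_table has one row per
    clone: clone_id, size, size_group, dominant (size > 20). group_percentages
    gives, per sample (or 'all'), the percentage of clone-member cells in each
    size group; rows sum to 100.
    """
    assigned = assignments.dropna(subset=["lineage"])
    sizes = assigned.groupby("lineage").size()
    clones = sizes[sizes >= 2].sort_values(ascending=False, kind="stable")
    clone_table = pd.DataFrame(
        {
            "clone_id": clones.index,
            "size": clones.to_numpy(),
            "size_group": [size_group(s) for s in clones],
            "dominant": clones.to_numpy() > DOMINANT_SIZE,
        }
    ).reset_index(drop=True)

    members = assigned[assigned["lineage"].isin(clone_table["clone_id"])].copy()
    group_of = dict(zip(clone_table["clone_id"], clone_table["size_group"]))
    members["size_group"] = members["lineage"].map(group_of)
    if sample_labels is not None:
        members["sample"] = members["cell_barcode"].map(sample_labels)
    else:
        members["sample"] = "all"
    counts = (
        members.groupby(["sample", "size_group"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["2-10", "11-20", ">20"], fill_value=0)
    )
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return clone_table, percentages


def dominant_clone_cluster_density(
    assignments: pd.DataFrame,
    cell_cluster_labels: Mapping[str, object],
) -> pd.DataFrame:
    """Per dominant clone, the count and fraction of its cells in each cluster."""
    clone_table, _ = clone_statistics(assignments)
    dominant = clone_table[clone_table["dominant"]]["clone_id"]
    assigned = assignments.dropna(subset=["lineage"])
    members = assigned[assigned["lineage"].isin(dominant)]
    missing = [
        c for c in members["cell_barcode"] if c not in cell_cluster_labels
    ]
    if missing:
        raise ValueError(f"cells without cluster labels: {missing}")
    rows = []
    for clone_id, grp in members.groupby("lineage", sort=True):
        clusters = pd.Series(
            [cell_cluster_labels[c] for c in grp["cell_barcode"]]
        ).value_counts()
        for cluster, count in clusters.items():
            rows.append(
                {
                    "clone_id": clone_id,
                    "cluster": cluster,
                    "count": int(count),
                    "fraction": count / len(grp),
                }
            )
    return pd.DataFrame(rows, columns=["clone_id", "cluster", "count", "fraction"])
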