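"""Lineage-barcode clone calling: filtering, collapse, assignment, statistics."""

import numpy as np
import pandas as pd
import pytest

from histokit.clone_lineage import (
    apply_collapse,
    assign_cells,
    clone_statistics,
    collapse_lineage_barcodes,
    dominant_clone_cluster_density,
    filter_triples,
    hamming_distance,
    load_triples,
    size_group,
)
from histokit.synthetic_data import BarcodeSimConfig, simulate_barcode_data


def triples_df(rows):
    return pd.DataFrame(
        rows, columns=["cell_barcode", "umi", "lineage_barcode", "read_count"]
    )


def brute_force_greedy_collapse(triples, max_hamming):
    """Independent re-implementation of the greedy collapse definition."""
    support = {}
    for row in triples.itertuples():
        support[row.lineage_barcode] = (
            support.get(row.lineage_barcode, 0) + row.read_count
        )
    order = sorted(support, key=lambda bc: (-support[bc], bc))
    reps, mapping = [], {}
    for bc in order:
        for rep in reps:
            if sum(x != y for x, y in zip(bc, rep)) <= max_hamming:
                mapping[bc] = rep
                break
        else:
            mapping[bc] = bc
            reps.append(bc)
    return mapping


class TestLoadTriples:
    def test_duplicate_rows_summed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "cell_barcode\tumi\tlineage_barcode\tread_count\n"
            "c1\tu1\tAAAA\t6\n"
            "c1\tu1\tAAAA\t5\n"
        )
        df = load_triples(path)
        assert len(df) == 1
        assert df.iloc[0].read_count == 11

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("cell_barcode\tumi\tlineage_barcode\tread_count\n")
        assert len(load_triples(path)) == 0

    def test_unequal_barcode_lengths_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "cell_barcode\tumi\tlineage_barcode\tread_count\n"
            "c1\tu1\tAAAA\t10\n"
            "c2\tu2\tAAA\t10\n"
        )
        with pytest.raises(ValueError, match="unequal length"):
            load_triples(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("cell_barcode\tumi\tread_count\nc1\tu1\t10\n")
        with pytest.raises(ValueError, match="missing column"):
            load_triples(path)


class TestFilterTriples:
    def test_threshold_boundary(self):
        df = triples_df(
            [("c1", "u1", "AAAA", 10), ("c2", "u2", "AAAA", 9)]
        )
        kept = filter_triples(df, min_reads=10)
        assert kept["cell_barcode"].tolist() == ["c1"]

    def test_empty_input(self):
        assert len(filter_triples(triples_df([]), 10)) == 0


class TestCollapse:
    def test_identical_barcodes_one_representative(self):
        df = triples_df([("c1", "u1", "AAAA", 10), ("c2", "u2", "AAAA", 10)])
        assert collapse_lineage_barcodes(df) == {"AAAA": "AAAA"}

    def test_beyond_radius_stays_separate(self):
        df = triples_df([("c1", "u1", "AAAAAA", 10), ("c2", "u2", "TTTTAA", 9)])
        cmap = collapse_lineage_barcodes(df, max_hamming=3)
        assert cmap["TTTTAA"] == "TTTTAA"

    def test_minor_variant_joins_major(self):
        df = triples_df([("c1", "u1", "AAAA", 100), ("c2", "u2", "AAAT", 5)])
        cmap = collapse_lineage_barcodes(df, max_hamming=3)
        assert cmap["AAAT"] == "AAAA"

    def test_idempotent_on_representatives(self):
        df = triples_df(
            [("c1", "u1", "AAAAAAAA", 100), ("c2", "u2", "AAAAAAAT", 5),
             ("c3", "u3", "GGGGGGGG", 50)]
        )
        cmap = collapse_lineage_barcodes(df)
        collapsed = apply_collapse(df, cmap)
        cmap2 = collapse_lineage_barcodes(collapsed)
        assert all(cmap2[bc] == bc for bc in cmap2)

    def test_every_barcode_within_radius_of_representative(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        df = triples_df(
            [
                (f"c{i}", f"u{i}", "".join(rng.choice(bases, 6)), int(rng.integers(1, 100)))
                for i in range(60)
            ]
        )
        cmap = collapse_lineage_barcodes(df, max_hamming=3)
        for bc, rep in cmap.items():
            assert hamming_distance(bc, rep) <= 3
            assert cmap[rep] == rep

    def test_matches_brute_force_oracle_small_instances(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            n = int(rng.integers(1, 13))
            df = triples_df(
                [
                    (
                        f"c{i}",
                        f"u{i}",
                        "".join(rng.choice(bases, 5)),
                        int(rng.integers(1, 50)),
                    )
                    for i in range(n)
                ]
            )
            assert collapse_lineage_barcodes(df, 3) == brute_force_greedy_collapse(df, 3)
            assert collapse_lineage_barcodes(df, 1) == brute_force_greedy_collapse(df, 1)


class TestAssignCells:
    def test_three_umis_assigned(self):
        df = triples_df(
            [("c1", f"u{i}", "AAAA", 10) for i in range(3)]
        )
        row = assign_cells(df, min_umis=3).iloc[0]
        assert row.lineage == "AAAA"
        assert row.n_umis == 3

    def test_two_umis_unassigned(self):
        df = triples_df([("c1", "u1", "AAAA", 10), ("c1", "u2", "AAAA", 10)])
        assert pd.isna(assign_cells(df, min_umis=3).iloc[0].lineage)

    def test_exact_tie_unassigned(self):
        rows = [("c1", f"u{i}", "AAAA", 10) for i in range(5)]
        rows += [("c1", f"v{i}", "TTTT", 10) for i in range(5)]
        assert pd.isna(assign_cells(triples_df(rows), min_umis=3).iloc[0].lineage)

    def test_max_support_wins(self):
        rows = [("c1", f"u{i}", "AAAA", 10) for i in range(5)]
        rows += [("c1", f"v{i}", "TTTT", 10) for i in range(3)]
        assert assign_cells(triples_df(rows), 3).iloc[0].lineage == "AAAA"


class TestCloneStatistics:
    def make_assignments(self, sizes):
        rows = []
        cell = 0
        for i, size in enumerate(sizes):
            for _ in range(size):
                rows.append({"cell_barcode": f"c{cell}", "lineage": f"L{i}", "n_umis": 3})
                cell += 1
        return pd.DataFrame(rows)

    def test_hand_example_sizes_25_5_2(self):
        clone_table, percentages = clone_statistics(self.make_assignments([25, 5, 2]))
        assert clone_table["size"].tolist() == [25, 5, 2]
        assert clone_table["dominant"].tolist() == [True, False, False]
        assert clone_table["size_group"].tolist() == [">20", "2-10", "2-10"]
        assert percentages.loc["all", ">20"] == pytest.approx(100 * 25 / 32)
        assert percentages.loc["all"].sum() == pytest.approx(100.0)

    def test_singletons_are_not_clones(self):
        clone_table, _ = clone_statistics(self.make_assignments([1, 1, 1]))
        assert len(clone_table) == 0

    def test_empty_input(self):
        clone_table, _ = clone_statistics(
            pd.DataFrame(columns=["cell_barcode", "lineage", "n_umis"])
        )
        assert len(clone_table) == 0

    @pytest.mark.parametrize(
        "size, expected", [(2, "2-10"), (10, "2-10"), (11, "11-20"), (20, "11-20"), (21, ">20")]
    )
    def test_size_group_boundaries(self, size, expected):
        assert size_group(size) == expected

    def test_per_sample_percentages(self):
        assignments = self.make_assignments([3, 2])
        labels = {f"c{i}": ("mutant" if i < 3 else "wt") for i in range(5)}
        _, percentages = clone_statistics(assignments, labels)
        assert percentages.loc["mutant", "2-10"] == pytest.approx(100.0)
        assert percentages.loc["wt", "2-10"] == pytest.approx(100.0)


class TestDominantCloneClusterDensity:
    def test_split_clone_fractions(self):
        rows = [
            {"cell_barcode": f"c{i}", "lineage": "L0", "n_umis": 3} for i in range(21)
        ]
        assignments = pd.DataFrame(rows)
        labels = {f"c{i}": (2 if i < 14 else 1) for i in range(21)}
        table = dominant_clone_cluster_density(assignments, labels)
        fractions = dict(zip(table["cluster"], table["fraction"]))
        assert fractions[2] == pytest.approx(2 / 3)
        assert fractions[1] == pytest.approx(1 / 3)
        assert table.groupby("clone_id")["fraction"].sum().iloc[0] == pytest.approx(1.0)

    def test_missing_label_raises(self):
        rows = [
            {"cell_barcode": f"c{i}", "lineage": "L0", "n_umis": 3} for i in range(21)
        ]
        with pytest.raises(ValueError, match="c20"):
            dominant_clone_cluster_density(
                pd.DataFrame(rows), {f"c{i}": 1 for i in range(20)}
            )

    def test_no_dominant_clones_empty(self):
        rows = [
            {"cell_barcode": f"c{i}", "lineage": "L0", "n_umis": 3} for i in range(5)
        ]
        assert len(dominant_clone_cluster_density(pd.DataFrame(rows), {})) == 0


class TestEndToEndRecovery:
    def run_pipeline(self, triples, min_reads=10, max_hamming=3, min_umis=3):
        kept = filter_triples(triples, min_reads)
        cmap = collapse_lineage_barcodes(kept, max_hamming)
        if not cmap:
            return assign_cells(kept.iloc[0:0], min_umis)
        return assign_cells(apply_collapse(kept, cmap), min_umis)

    def test_noiseless_exact_recovery(self):
        cfg = BarcodeSimConfig(n_clones=10, substitution_rate=0.0)
        sim = simulate_barcode_data(cfg, seed=2)
        assignments = self.run_pipeline(sim.triples)
        clone_table, _ = clone_statistics(assignments)
        truth_sizes = sim.truth_sizes[sim.truth_sizes >= 2]
        assert sorted(clone_table["size"]) == sorted(truth_sizes)
        got = {
            frozenset(grp["cell_barcode"])
            for _, grp in assignments.dropna(subset=["lineage"]).groupby("lineage")
            if len(grp) >= 2
        }
        expected = {
            frozenset(grp["cell_barcode"])
            for _, grp in sim.truth_clones.groupby("clone_id")
            if len(grp) >= 2
        }
        assert got == expected

    def test_read_threshold_sharpness(self):
        sim = simulate_barcode_data(
            BarcodeSimConfig(n_clones=10, reads_per_umi=9), seed=3
        )
        assignments = self.run_pipeline(sim.triples)
        clone_table, _ = clone_statistics(assignments)
        assert len(clone_table) == 0

    def test_umi_threshold_sharpness(self):
        sim = simulate_barcode_data(
            BarcodeSimConfig(n_clones=10, umis_per_cell=2), seed=4
        )
        assignments = self.run_pipeline(sim.triples)
        clone_table, _ = clone_statistics(assignments)
        assert len(clone_table) == 0
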