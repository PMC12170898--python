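"""Tracking-table IO: assembly, validation, labels, Newick, round trips."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from lineagemotility import synthetic_data, tracking_io
from lineagemotility.model import FateLabel, MovieMeta
from lineagemotility.tracking_io import (FormatError, IntegrityError,
                                         assemble_forest, count_forest,
                                         export_newick, generation_labels,
                                         read_tracking_table, validate_forest,
                                         write_tracking_table)

from conftest import forest_from


def spots_df(rows):
    return pd.DataFrame(rows, columns=tracking_io.SPOT_COLUMNS)


def links_df(rows):
    return pd.DataFrame(rows, columns=tracking_io.LINK_COLUMNS)


META = MovieMeta(movie_id="t", frame_interval_min=2.0)


def single_division_tables():
    spots = spots_df([
        (0, "m", 0, 0.0, 0.0, 0.0, 1.0, 1.0),
        (1, "m", 1, 1.0, 0.0, 0.0, 1.0, 1.0),
        (2, "d1", 2, 2.0, 1.0, 0.0, 1.0, 1.0),
        (3, "d2", 2, 2.0, -1.0, 0.0, 1.0, 1.0),
    ])
    links = links_df([(0, 1), (1, 2), (1, 3)])
    return spots, links


class TestAssembly:
    def test_single_spot_no_links(self, tmp_path):
        sp, lk = tmp_path / "s.csv", tmp_path / "l.csv"
        spots_df([(0, "c0", 0, 1.0, 2.0, 3.0, 5.0, 1.0)]).to_csv(sp, index=False)
        links_df([]).to_csv(lk, index=False)
        forest = read_tracking_table(sp, lk, META)
        assert len(forest.roots) == 1
        assert forest.roots[0].generation_label == "M"
        assert len(forest.roots[0].spots) == 1

    def test_single_division_labels(self, tmp_path):
        spots, links = single_division_tables()
        sp, lk = tmp_path / "s.csv", tmp_path / "l.csv"
        spots.to_csv(sp, index=False)
        links.to_csv(lk, index=False)
        forest = read_tracking_table(sp, lk, META)
        labels = sorted(c.generation_label for c in forest.cells.values())
        assert labels == ["D1", "D2", "M"]
        # smaller first-spot id gets suffix 1
        assert forest.cells["d1"].generation_label == "D1"

    def test_missing_column_names_the_column(self, tmp_path):
        sp = tmp_path / "s.csv"
        spots, links = single_division_tables()
        spots.drop(columns=["gfp"]).to_csv(sp, index=False)
        lk = tmp_path / "l.csv"
        links.to_csv(lk, index=False)
        with pytest.raises(FormatError, match="gfp"):
            read_tracking_table(sp, lk, META)

    def test_dangling_link_lists_offending_ids(self):
        spots, _ = single_division_tables()
        with pytest.raises(IntegrityError, match="99"):
            assemble_forest(spots, links_df([(0, 99)]), META)

    def test_one_child_rejected(self):
        spots, _ = single_division_tables()
        with pytest.raises(IntegrityError, match="m"):
            assemble_forest(spots, links_df([(1, 2)]), META)

    def test_column_mapping_adapts_schema(self, tmp_path):
        spots, links = single_division_tables()
        spots = spots.rename(columns={"gfp": "GFP_CH1", "x_um": "POS_X"})
        sp, lk = tmp_path / "s.csv", tmp_path / "l.csv"
        spots.to_csv(sp, index=False)
        links.to_csv(lk, index=False)
        forest = read_tracking_table(
            sp, lk, META, column_map={"gfp": "GFP_CH1", "x_um": "POS_X"})
        assert len(forest) == 3


class TestValidation:
    def test_valid_forest_empty_report(self, worked_forest):
        assert validate_forest(worked_forest) == []

    def test_three_children_reported(self):
        spots, links = single_division_tables()
        forest = assemble_forest(spots, links, META)
        forest.cells["m"].children.append("d1")  # corrupt in memory
        report = validate_forest(forest)
        assert any("children" in r for r in report)

    def test_time_inversion_reported(self):
        spots, links = single_division_tables()
        forest = assemble_forest(spots, links, META)
        forest.cells["m"].spots[1].frame = 0
        assert any("increasing" in r for r in validate_forest(forest))


class TestLabelsAndCounts:
    def test_two_generation_tree_labels(self, worked_forest):
        labels = {c.generation_label for c in worked_forest.cells.values()
                  if c.cell_id.startswith("a")}
        assert labels == {"M", "D1", "D2", "D11", "D12"}

    def test_three_generation_synthetic_tree_has_unique_labels(self, small_forest):
        for root in small_forest.roots:
            labels = [c.generation_label for c in small_forest.subtree(root)]
            assert len(labels) == len(set(labels))
            assert labels[0] == "M"

    def test_label_assignment_invariant_to_row_order(self, rng):
        spots, links = single_division_tables()
        shuffled = spots.sample(frac=1.0, random_state=3).reset_index(drop=True)
        f1 = assemble_forest(spots, links, META)
        f2 = assemble_forest(shuffled, links, META)
        for cid in f1.cells:
            assert f1.cells[cid].generation_label == f2.cells[cid].generation_label

    def test_counts(self, worked_forest):
        assert count_forest(worked_forest) == (2, 6)

    def test_descendants_equals_nodes_minus_roots(self, small_forest):
        n_mothers, n_desc = count_forest(small_forest)
        assert n_mothers + n_desc == len(small_forest)


class TestNewick:
    def test_single_division_format(self):
        spots = spots_df([
            (0, "m", 0, 0, 0, 0, 1, 1),
            (1, "m", 9, 0, 0, 0, 1, 1),
            (2, "d1", 10, 0, 0, 0, 1, 1),
            (3, "d1", 70, 0, 0, 0, 1, 1),
            (4, "d2", 10, 0, 0, 0, 1, 1),
            (5, "d2", 70, 0, 0, 0, 1, 1),
        ])
        links = links_df([(1, 2), (1, 4)])
        forest = assemble_forest(spots, links, META)
        assert export_newick(forest) == "(D1:120,D2:120)M;"

    def test_leaf_root(self):
        forest = assemble_forest(
            spots_df([(0, "m", 0, 0, 0, 0, 1, 1)]), links_df([]), META)
        assert export_newick(forest) == "M;"

    def test_round_trip_topology_and_durations(self, small_forest):
        text = export_newick(small_forest)
        trees = dendropy.TreeList.get(data=text, schema="newick")
        assert len(trees) == len(small_forest.roots)
        for tree, root in zip(trees, sorted(small_forest.roots,
                                            key=lambda c: c.cell_id)):
            n_leaves = len(small_forest.leaves(root))
            assert len(tree.leaf_nodes()) == n_leaves
            for leaf in tree.leaf_nodes():
                label = leaf.taxon.label
                cell = next(c for c in small_forest.subtree(root)
                            if c.generation_label == label)
                if cell.parent is not None:
                    assert leaf.edge.length == pytest.approx(cell.cycle_length_min)


class TestRoundTrip:
    def test_write_read_identity(self, small_movie, tmp_path):
        forest = forest_from(small_movie)
        sp, lk, ft = (tmp_path / n for n in ("s.csv", "l.csv", "f.csv"))
        write_tracking_table(forest, sp, lk, ft)
        back = read_tracking_table(sp, lk, small_movie.meta, fates_path=ft)
        assert set(back.cells) == set(forest.cells)
        for cid, cell in forest.cells.items():
            other = back.cells[cid]
            assert other.parent == cell.parent
            assert other.children == cell.children
            assert other.fate == cell.fate
            assert other.generation_label == cell.generation_label
            assert len(other.spots) == len(cell.spots)
            np.testing.assert_allclose(other.positions(), cell.positions())
            np.testing.assert_allclose(
                [s.gfp_raw for s in other.spots],
                [s.gfp_raw for s in cell.spots])
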