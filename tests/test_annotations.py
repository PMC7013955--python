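"""Annotation table I/O, hierarchy queries, summaries and splits."""

import numpy as np
import pandas as pd
import pytest

from kelpcover.annotations import (
    ANNOTATION_COLUMNS,
    AnnotationTable,
    HierarchyNode,
    HierarchyTree,
    PointAnnotation,
    SplitSpec,
    load_annotations,
    make_split,
    save_annotations,
    summarize,
)
from kelpcover.errors import (
    ConfigurationError,
    HierarchyLookupError,
    ValidationError,
)


def _csv(tmp_path, rows, header=",".join(ANNOTATION_COLUMNS)):
    path = tmp_path / "ann.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestLoadSave:
    def test_well_formed_round_trip_preserves_order(self, tmp_path):
        rows = [
            "img1,10,20,kelp,s1,2013,15.0",
            "img1,30,40,sand,s1,2013,15.0",
            "img2,10,20,turf,s2,2013,",
        ]
        table = load_annotations(_csv(tmp_path, rows))
        assert len(table) == 3
        assert list(table.labels) == ["kelp", "sand", "turf"]
        assert table.row(2).depth_m is None

    def test_duplicate_point_rejected_with_culprit(self, tmp_path):
        rows = [
            "img1,10,10,kelp,s1,2013,",
            "img1,10,10,sand,s1,2013,",
        ]
        with pytest.raises(ValidationError, match=r"img1.*10.*10"):
            load_annotations(_csv(tmp_path, rows))

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("image_id,x,y\nimg1,1,2\n")
        with pytest.raises(ConfigurationError, match="label"):
            load_annotations(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "foreign.csv"
        path.write_text(
            "Image Name,col,row,Label,site,year,depth_m\nIMG_1,5,6,kelp,s1,2012,10\n"
        )
        table = load_annotations(
            path, dialect={"image_id": "Image Name", "x": "col", "y": "row", "label": "Label"}
        )
        assert table.row(0) == PointAnnotation("IMG_1", 5, 6, "kelp", "s1", 2012, 10.0)

    def test_thousand_row_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        points = [
            PointAnnotation(
                f"img{i // 50}", x=int(rng.integers(0, 500)), y=i % 50,
                label=rng.choice(["kelp", "sand", "turf"]),
                site=f"s{i % 3}", year=2010 + i % 4,
            )
            for i in range(1000)
        ]
        table = AnnotationTable.from_points(points)
        path = tmp_path / "big.csv"
        save_annotations(table, path)
        assert load_annotations(path) == table


class TestHierarchy:
    def test_subtree_labels_root_and_leaf(self, toy_tree):
        assert toy_tree.subtree_labels("1") == {"kelp", "scytothalia", "turf", "coral", "sand"}
        assert toy_tree.subtree_labels("1.1.1") == {"kelp"}

    def test_subtree_labels_internal_node(self, toy_tree):
        assert toy_tree.subtree_labels("1.1") == {"kelp", "scytothalia", "turf"}

    def test_unknown_node_raises(self, toy_tree):
        with pytest.raises(HierarchyLookupError):
            toy_tree.subtree_labels("9.9")

    def test_sibling_subtrees_disjoint_and_cover_parent(self, toy_tree):
        for nid in toy_tree.nodes:
            children = toy_tree.node(nid).children
            sets = [toy_tree.subtree_labels(c) for c in children]
            union = set(toy_tree.node(nid).leaf_labels)
            for i, s in enumerate(sets):
                union |= s
                for t in sets[i + 1:]:
                    assert not (s & t)
            assert union == toy_tree.subtree_labels(nid)

    def test_duplicate_label_mapping_rejected(self):
        with pytest.raises(ValidationError, match="kelp"):
            HierarchyTree(
                [
                    HierarchyNode("r", "root"),
                    HierarchyNode("a", "a", "r", leaf_labels={"kelp"}),
                    HierarchyNode("b", "b", "r", leaf_labels={"kelp"}),
                ]
            )

    def test_json_round_trip(self, toy_tree, tmp_path):
        path = tmp_path / "tree.json"
        toy_tree.save(path)
        loaded = HierarchyTree.load(path)
        assert loaded.root_id == toy_tree.root_id
        assert {n: loaded.subtree_labels(n) for n in loaded.nodes} == {
            n: toy_tree.subtree_labels(n) for n in toy_tree.nodes
        }


class TestSummarize:
    def test_single_image_counts(self):
        points = [
            PointAnnotation("im0", x=i, y=0, label="kelp" if i < 30 else "sand")
            for i in range(50)
        ]
        (total,) = summarize(AnnotationTable.from_points(points))
        assert (total.n_points, total.n_images, total.n_classes) == (50, 1, 2)
        assert total.group_key == ("__all__",)

    def test_group_conservation(self, toy_table):
        summaries = summarize(toy_table, group_by=["image_id"])
        groups, total = summaries[:-1], summaries[-1]
        assert sum(s.n_points for s in groups) == total.n_points == len(toy_table)
        assert total.n_images == len(groups)

    def test_empty_table_gives_zero_total(self):
        empty = AnnotationTable(pd.DataFrame(columns=list(ANNOTATION_COLUMNS)))
        (total,) = summarize(empty, group_by=["site"])
        assert total.n_points == 0 and total.n_images == 0


class TestSplits:
    @staticmethod
    def _table(n_images=10, per_image=5, site="s1"):
        points = [
            PointAnnotation(f"{site}-im{i}", x=j, y=0, label="kelp", site=site, year=2010 + i % 4)
            for i in range(n_images)
            for j in range(per_image)
        ]
        return AnnotationTable.from_points(points)

    def test_fraction_split_image_counts(self):
        table = self._table(10)
        train, test = make_split(table, SplitSpec(seed=1))
        assert train.df["image_id"].nunique() == 7
        assert test.df["image_id"].nunique() == 3

    def test_partition_property(self):
        table = self._table(10)
        train, test = make_split(table, SplitSpec(seed=3))
        assert len(train) + len(test) == len(table)
        train_imgs = set(train.image_ids)
        test_imgs = set(test.image_ids)
        assert not (train_imgs & test_imgs)
        merged = pd.concat([train.df, test.df]).sort_values(["image_id", "x", "y"])
        original = table.df.sort_values(["image_id", "x", "y"])
        assert merged.reset_index(drop=True).equals(original.reset_index(drop=True))

    def test_by_year_split_filters_exactly(self):
        table = self._table(12)
        spec = SplitSpec(
            strategy="by_year",
            train_years=frozenset({2010, 2011, 2012}),
            test_years=frozenset({2013}),
        )
        train, test = make_split(table, spec)
        assert set(test.df["year"]) == {2013}
        assert set(train.df["year"]) == {2010, 2011, 2012}

    def test_same_seed_reproduces_different_seed_varies(self):
        table = self._table(30)
        a1 = make_split(table, SplitSpec(seed=7))[0]
        a2 = make_split(table, SplitSpec(seed=7))[0]
        b = make_split(table, SplitSpec(seed=8))[0]
        assert a1 == a2
        assert set(a1.image_ids) != set(b.image_ids)

    def test_single_image_site_goes_to_train_with_warning(self):
        points = [
            PointAnnotation("lonely", x=i, y=0, label="kelp", site="solo") for i in range(3)
        ]
        table = AnnotationTable.from_points(points)
        with pytest.warns(UserWarning, match="solo"):
            train, test = make_split(table, SplitSpec(seed=0))
        assert len(train) == 3 and len(test) == 0

    def test_overlapping_year_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitSpec(strategy="by_year", train_years=frozenset({2010}), test_years=frozenset({2010}))
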