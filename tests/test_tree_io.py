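"""Newick parsing/writing, metadata joins, polytomy resolution, annotation."""

import math

import pytest
from hypothesis import given, strategies as st

from phylozoom import (MetadataTable, NewickParseError, annotate,
                       attach_metadata, parse_newick, resolve_polytomies,
                       write_newick)
from phylozoom.simulate import SimParams, simulate_yule

from conftest import make_yule


def trees_equal(a, b, tol=1e-9):
    """Iterative structural equality: topology, labels, lengths."""
    stack = [(a.root, b.root)]
    while stack:
        x, y = stack.pop()
        if x.label != y.label or len(x.children) != len(y.children):
            return False
        if (x.length is None) != (y.length is None):
            return False
        if x.length is not None and abs(x.length - y.length) > tol:
            return False
        stack.extend(zip(x.children, y.children))
    return True


class TestParse:
    def test_lengths_and_tips(self):
        t = parse_newick("(A:1.0,B:2.0):0.5;")
        assert t.n_tips == 2
        assert t.root.length == 0.5
        assert [c.label for c in t.root.children] == ["A", "B"]
        assert t.has_lengths

    def test_polytomy_without_lengths(self):
        t = parse_newick("(A,B,C);")
        assert len(t.root.children) == 3
        assert not t.has_lengths

    def test_internal_labels_quotes_comments(self):
        t = parse_newick("((A:1,'sp. nov':2)anc:1,[a comment]C:3)root;")
        assert t.root.label == "root"
        assert t.root.children[0].label == "anc"
        assert t.root.children[0].children[1].label == "sp. nov"

    def test_quoted_label_preserved_verbatim(self):
        t = parse_newick("('He''s a_b c',B);")
        assert t.root.children[0].label == "He's a_b c"

    @pytest.mark.parametrize("bad,fragment", [
        ("(A,B;", "unbalanced"),
        ("(A,B))C;", "unbalanced"),
        ("(A,B)", "terminator"),
        ("(A:-1,B:1);", "negative"),
        ("", "empty"),
    ])
    def test_errors_name_character_offset(self, bad, fragment):
        with pytest.raises(NewickParseError) as err:
            parse_newick(bad)
        assert fragment in str(err.value)
        assert "character" in str(err.value)

    def test_deep_tree_is_stack_safe(self):
        n = 100_000
        text = "(" * (n - 1) + "t1:1" + "".join(
            f",t{i}:1)" for i in range(2, n + 1)) + ";"
        t = parse_newick(text)
        assert t.n_tips == n
        # writing back must be stack-safe too
        assert write_newick(t).count(",") == n - 1


class TestWrite:
    def test_single_leaf(self):
        t = parse_newick("A;")
        assert write_newick(t) == "A;"

    def test_reserved_label_is_quoted(self):
        t = parse_newick("('sp. nov',B);")
        assert "'sp. nov'" in write_newick(t)

    def test_roundtrip_200_random_yule_trees(self):
        for seed in range(200):
            t = simulate_yule(SimParams(n_tips=3 + seed % 30, seed=seed))
            again = parse_newick(write_newick(t))
            assert trees_equal(t, again)

    @given(st.text(alphabet="ab _'(),:;[]", min_size=1, max_size=12))
    def test_roundtrip_hostile_labels(self, label):
        t = parse_newick("(A,B);")
        t.root.children[0].label = label
        again = parse_newick(write_newick(t))
        assert again.root.children[0].label == label

    def test_agrees_with_dendropy_on_distances(self):
        dendropy = pytest.importorskip("dendropy")
        nwk = write_newick(simulate_yule(SimParams(n_tips=32, seed=7)))
        ours = annotate(parse_newick(nwk))
        theirs = dendropy.Tree.get(data=nwk, schema="newick")
        their_depths = {leaf.taxon.label: leaf.distance_from_root()
                        for leaf in theirs.leaf_node_iter()}
        # dendropy's distance_from_root includes the seed edge, i.e. it is
        # measured from the stem origin — exactly our (stem age - tip date)
        root_age = ours.root.date + ours.root.length
        for tip in ours.leaves():
            assert math.isclose(root_age - tip.date, their_depths[tip.label],
                                rel_tol=1e-9)


class TestMetadata:
    def test_direct_join(self):
        t = parse_newick("(Homo_sapiens:1,Pan:1);")
        table = MetadataTable("label", {"Homo_sapiens": {"iucn": "LC",
                                                         "common": "Human"}})
        t, orphans = attach_metadata(t, table)
        tip = t.root.children[0]
        assert tip.metadata == {"iucn": "LC", "common": "Human"}
        assert orphans == []

    def test_empty_table_is_identity(self):
        t = parse_newick("(A,B);")
        t, orphans = attach_metadata(t, MetadataTable("label", {}))
        assert all(tip.metadata == {} for tip in t.leaves())
        assert orphans == []

    def test_unmatched_key_reported_not_fatal(self):
        t = parse_newick("(A,B);")
        t, orphans = attach_metadata(
            t, MetadataTable("label", {"Zz": {"iucn": "EN"}}))
        assert orphans == ["Zz"]
        assert all(tip.metadata == {} for tip in t.leaves())

    def test_duplicate_csv_keys_raise(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("label,iucn\nA,LC\nA,EN\n")
        with pytest.raises(ValueError, match="duplicate.*A"):
            MetadataTable.from_csv(p)

    def test_tsv_autodetect(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("label\tiucn\tcommon\nA\tLC\tAardvark\n")
        table = MetadataTable.from_csv(p)
        assert table.records["A"] == {"iucn": "LC", "common": "Aardvark"}


class TestResolvePolytomies:
    def test_k3_left_leaning_chain(self):
        t = resolve_polytomies(parse_newick("(A,B,C);"))
        assert len(t.root.children) == 2
        wrap = t.root.children[0]
        assert wrap.polytomy_flag == "break"
        assert [c.label for c in wrap.children] == ["A", "B"]
        assert t.root.children[1].label == "C"
        flags = sum(1 for nd in t.nodes if nd.polytomy_flag)
        assert flags == 1

    def test_binary_input_unchanged(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        before = write_newick(t)
        resolve_polytomies(t)
        assert write_newick(t) == before
        assert sum(1 for nd in t.nodes if nd.polytomy_flag) == 0

    def test_k5_preserves_path_lengths(self):
        t = parse_newick("(A:1,B:2,C:3,D:4,E:5):1;")

        def tip_dists(tree):
            out = {}
            stack = [(tree.root, tree.root.length or 0.0)]
            while stack:
                nd, d = stack.pop()
                if nd.is_leaf:
                    out[nd.label] = d
                for c in nd.children:
                    stack.append((c, d + (c.length or 0.0)))
            return out

        before = tip_dists(t)
        resolve_polytomies(t, mode="highlight")
        assert sum(1 for nd in t.nodes if nd.polytomy_flag == "highlight") == 3
        assert tip_dists(t) == before
        assert all(len(nd.children) in (0, 2) for nd in t.nodes)

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="break"):
            resolve_polytomies(parse_newick("(A,B,C);"), mode="nope")


class TestAnnotate:
    def test_balanced_counts(self):
        t = annotate(parse_newick("((A,B),(C,D));"))
        assert t.root.tip_count == 4
        assert [c.tip_count for c in t.root.children] == [2, 2]

    def test_dates_from_lengths(self):
        t = annotate(parse_newick("(A:1,B:3):1;"))
        tips = {nd.label: nd.date for nd in t.leaves()}
        assert tips == {"A": 2.0, "B": 0.0}
        assert t.root.date == 3.0
        assert t.root.date + t.root.length == 4.0  # stem-origin age

    def test_conservation_on_yule(self):
        t = make_yule(128, seed=3)
        for nd in t.nodes:
            if nd.children:
                assert nd.tip_count == sum(c.tip_count for c in nd.children)
        assert min(nd.date for nd in t.leaves()) == pytest.approx(0.0, abs=1e-9)
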