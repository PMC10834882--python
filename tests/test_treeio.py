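"""Newick/NEXUS parsing and writing, round trips, error offsets."""

import math

import dendropy
import numpy as np
import pytest

from phylopipe import (ParseError, clade_signature, parse_newick,
                       parse_nexus, read_nexus_pipeline, sniff_format,
                       traverse, write_newick, write_nexus, TreeCollection)
from phylopipe.io import iter_nexus_trees
from conftest import random_rooted_tree

MINIMAL_NEXUS = """#NEXUS
BEGIN TAXA;
    DIMENSIONS NTAX=3;
    TAXLABELS A B C;
END;
BEGIN TREES;
    TRANSLATE
        1 A,
        2 B,
        3 C;
    TREE tree1 = [&R] ((1:1,2:1):1,3:2);
END;
"""


class TestSniff:
    def test_nexus_sentinel(self):
        descriptor = sniff_format("#NEXUS\nbegin trees; tree t = (A,B); end;")
        assert descriptor.format == "nexus"

    def test_newick(self):
        descriptor = sniff_format("((A,B),C);")
        assert descriptor.format == "newick"
        assert descriptor.tree_count == 1

    def test_case_and_whitespace(self):
        text = "  \n\t#nexus\nbegin trees; tree t = (A,B); end;"
        assert sniff_format(text).format == "nexus"

    def test_empty_is_error(self):
        with pytest.raises(ParseError):
            sniff_format("   ")


class TestParseNewick:
    def test_lengths(self):
        tree = parse_newick("(A:1,B:2);").trees[0]
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_numeric_internal_label_is_support(self):
        tree = parse_newick("((A:1,B:1)0.95:1,C:2);").trees[0]
        internal = tree.root.children[0]
        assert internal.attributes["Support"] == 0.95

    def test_text_internal_label_is_name(self):
        tree = parse_newick("((A,B)Ingroup,C);").trees[0]
        assert tree.root.children[0].name == "Ingroup"

    def test_attribute_comment_numeric(self):
        tree = parse_newick("((A:1,B:1)[&rate=2.5]:1,C:2);").trees[0]
        assert tree.root.children[0].attributes["rate"] == 2.5

    def test_beast_range_kept_verbatim(self):
        text = "((A:1,B:1)[&height_95%_HDI={0.8,1.2},rate=2.5]:1,C:2);"
        node = parse_newick(text).trees[0].root.children[0]
        assert node.attributes["height_95%_HDI"] == "{0.8,1.2}"
        assert node.attributes["rate"] == 2.5

    def test_quoted_label_with_specials_and_escape(self):
        tree = parse_newick("('sp. nov':1,'O''Brien':2);").trees[0]
        assert [l.name for l in tree.leaves()] == ["sp. nov", "O'Brien"]

    def test_underscores_preserved_by_default(self):
        tree = parse_newick("(Homo_sapiens:1,B:1);").trees[0]
        assert tree.leaves()[0].name == "Homo_sapiens"
        classic = parse_newick("(Homo_sapiens:1,B:1);",
                               underscore_to_space=True).trees[0]
        assert classic.leaves()[0].name == "Homo sapiens"

    @pytest.mark.parametrize("bad, fragment", [
        ("((A,B,C;", "unbalanced"),
        ("(A:,B);", "dangling"),
        ("('A,B);", "unterminated"),
    ])
    def test_errors_carry_offsets(self, bad, fragment):
        with pytest.raises(ParseError) as info:
            parse_newick(bad)
        assert fragment in str(info.value)
        assert info.value.offset >= 0


class TestWriteNewick:
    def test_canonical_round_trip_string(self):
        assert write_newick(parse_newick("(A:1,B:2);").trees[0]) == \
            "(A:1,B:2);"

    def test_quoting_rule(self):
        tree = parse_newick("('sp. nov':1,B:2);").trees[0]
        assert write_newick(tree) == "('sp. nov':1,B:2);"

    def test_attribute_emission_round_trip(self):
        text = "((A:1,B:1)[&rate=2.5]:1,C:2);"
        tree = parse_newick(text).trees[0]
        rewritten = write_newick(tree, attributes=True)
        reparsed = parse_newick(rewritten).trees[0]
        assert reparsed.root.children[0].attributes["rate"] == 2.5

    @pytest.mark.parametrize("seed", range(10))
    def test_random_round_trip(self, seed):
        tree = random_rooted_tree(np.random.default_rng(seed),
                                  [f"t{i}" for i in range(12)])
        reparsed = parse_newick(write_newick(tree)).trees[0]
        assert {clade_signature(n).canonical_key
                for n in traverse(tree, "preorder")} == \
            {clade_signature(n).canonical_key
             for n in traverse(reparsed, "preorder")}
        original = {clade_signature(n).canonical_key: n.length
                    for n in traverse(tree, "preorder")}
        for node in traverse(reparsed, "preorder"):
            key = clade_signature(node).canonical_key
            if original[key] is not None:
                assert node.length == pytest.approx(original[key], abs=1e-9)

    def test_dendropy_reads_our_newick(self, random_tree_factory):
        """Independent reader oracle: dendropy agrees on taxa and lengths."""
        tree = random_tree_factory(15, seed=42)
        text = write_newick(tree)
        oracle = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(l.taxon.label for l in oracle.leaf_node_iter()) == \
            sorted(tree.leaf_names())
        assert oracle.length() == pytest.approx(
            sum(n.length or 0 for n in traverse(tree, "preorder")), abs=1e-9)


class TestNexus:
    def test_translate_applied(self):
        collection = parse_nexus(MINIMAL_NEXUS)
        assert sorted(collection.trees[0].leaf_names()) == ["A", "B", "C"]
        assert collection.translate == {"1": "A", "2": "B", "3": "C"}

    def test_multiple_trees_in_order(self):
        text = ("#NEXUS\nbegin trees;\n"
                "tree a = ((A,B),C);\n"
                "tree b = ((A,C),B);\n"
                "tree c = ((B,C),A);\nend;\n")
        collection = parse_nexus(text)
        assert len(collection) == 3
        first = clade_signature(collection.trees[0].root.children[0]).leaves
        assert first == frozenset({"A", "B"})

    def test_streaming_iterator(self):
        trees = iter_nexus_trees(MINIMAL_NEXUS)
        first = next(trees)
        assert sorted(first.leaf_names()) == ["A", "B", "C"]

    def test_missing_trees_block(self):
        with pytest.raises(ParseError):
            parse_nexus("#NEXUS\nbegin taxa; end;")

    def test_unresolved_token_named_in_error(self):
        bad = MINIMAL_NEXUS.replace("3 C;", "4 C;")
        with pytest.raises(ParseError) as info:
            parse_nexus(bad)
        assert "'3'" in str(info.value)

    def test_rooting_comment_stripped(self):
        text = "#NEXUS\nbegin trees;\ntree t = [&U] ((A:1,B:1):1,C:2);\nend;"
        tree = parse_nexus(text).trees[0]
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]

    def test_write_read_round_trip_with_translate(self):
        collection = parse_nexus(MINIMAL_NEXUS)
        text = write_nexus(collection)
        again = parse_nexus(text)
        assert sorted(again.trees[0].leaf_names()) == ["A", "B", "C"]
        assert again.translate == collection.translate

    def test_pipeline_block_round_trip(self):
        collection = parse_nexus(MINIMAL_NEXUS)
        payload = '{"format_version": 1, "x": [1, 2, ["nested"]]}'
        text = write_nexus(collection, pipeline_json=payload)
        assert read_nexus_pipeline(text) == payload
        # standard NEXUS readers must still accept the file
        oracle = dendropy.TreeList.get(data=text, schema="nexus")
        assert len(oracle) == 1

    def test_no_pipeline_block_when_absent(self):
        collection = parse_nexus(MINIMAL_NEXUS)
        assert read_nexus_pipeline(write_nexus(collection)) is None


class TestCollectionProperties:
    def test_file_order_preserved(self):
        text = "((A,B),C);\n((A,C),B);\n"
        collection = parse_newick(text)
        assert len(collection) == 2
        first = clade_signature(collection.trees[0].root.children[0]).leaves
        second = clade_signature(collection.trees[1].root.children[0]).leaves
        assert first == frozenset({"A", "B"})
        assert second == frozenset({"A", "C"})
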