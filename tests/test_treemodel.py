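import itertools
import random

import pytest

from phyloconflict import treemodel as tm
from phyloconflict.treemodel import (
    Clade,
    NewickParseError,
    NonMonophyleticOutgroupError,
    NotRootableError,
    TreeValidationError,
    clades_conflict,
    clades_of,
    parse_newick,
    reroot_on_outgroup,
    restrict,
    tip_to_tip_depth,
    write_newick,
)

from conftest import random_tree


def pairwise_path_lengths(tree):
    out = []
    leaves = tree.leaves()
    for x, y in itertools.combinations(leaves, 2):
        anc = {}
        node, dist = x, 0.0
        while node is not None:
            anc[id(node)] = dist
            dist += node.length or 0.0
            node = node.parent
        node, dist = y, 0.0
        while id(node) not in anc:
            dist += node.length or 0.0
            node = node.parent
        out.append(round(dist + anc[id(node)], 9))
    return sorted(out)


class TestParseNewick:
    def test_support_on_internal_label(self):
        tree = parse_newick("(A:1,(B:1,C:1)90:1);")
        (clade,) = clades_of(tree)
        assert clade.taxa == frozenset("BC")
        assert clade.support == 90

    def test_fractional_support_rescaled(self):
        tree = parse_newick("(A:1,(B:1,C:1)0.9:1);")
        (clade,) = clades_of(tree)
        assert clade.support == pytest.approx(90.0)

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("(A,(A,B));")

    def test_malformed_reports_offset(self):
        with pytest.raises(NewickParseError) as exc:
            parse_newick("(A,(B,C)")
        assert exc.value.offset >= 0
        with pytest.raises(NewickParseError):
            parse_newick("")

    def test_polytomy_parsed_as_unrooted(self):
        tree = parse_newick("(A,B,C,D);")
        assert not tree.rooted
        assert len(tree.root.children) == 4

    def test_quoted_labels(self):
        tree = parse_newick("('sp one':1,'sp two':2);")
        assert tree.taxa() == {"sp one", "sp two"}

    def test_support_in_comment_syntax(self):
        tree = parse_newick("(A:1,(B:1,C:1):1[95]);", support_in_comments=True)
        (clade,) = clades_of(tree)
        assert clade.support == 95

    def test_mixed_supports_not_rescaled_when_any_above_one(self):
        tree = parse_newick("((A,B)0.5,((C,D)88,E)90);")
        supports = sorted(c.support for c in clades_of(tree))
        assert supports == [0.5, 88, 90]


class TestWriteNewick:
    def test_round_trip_example(self):
        text = "(A:1,(B:1,C:1)90:1);"
        again = write_newick(parse_newick(text))
        assert tm.trees_isomorphic(parse_newick(text), parse_newick(again))

    def test_no_supports_no_internal_labels(self):
        out = write_newick(parse_newick("(A:1,(B:1,C:1):1);"))
        assert out == "(A:1,(B:1,C:1):1);"

    def test_polytomy_preserved(self):
        out = write_newick(parse_newick("(A,B,C,(D,E));"))
        assert out == "(A,B,C,(D,E));"

    def test_round_trip_1000_random_trees(self):
        rng = random.Random(7)
        for i in range(1000):
            n = rng.randint(5, 50)
            tree = random_tree(rng, n)
            text = write_newick(tree)
            back = parse_newick(text)
            assert tm.trees_isomorphic(tree, back)
            assert write_newick(back) == text
            assert pairwise_path_lengths(back) == pairwise_path_lengths(tree)

    def test_round_trip_against_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(3)
        for _ in range(25):
            tree = random_tree(rng, rng.randint(4, 20))
            text = write_newick(tree)
            dt = dendropy.Tree.get(data=text, schema="newick")
            assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == set(
                tree.taxa()
            )
            assert len(dt.leaf_nodes()) == len(tree.leaves())


class TestReroot:
    def test_roots_between_outgroup_and_ingroup(self):
        tree = parse_newick("(A,B,(C,(O1,O2)));")
        rooted = reroot_on_outgroup(tree, {"O1", "O2"})
        sides = sorted(
            rooted.cluster_map()[id(c)] for c in rooted.root.children
        )
        assert frozenset({"O1", "O2"}) in sides
        assert frozenset({"A", "B", "C"}) in sides

    def test_single_outgroup_roots_on_pendant_edge(self):
        rooted = reroot_on_outgroup(parse_newick("(A,B,(C,O1));"), {"O1", "O2"})
        sides = {rooted.cluster_map()[id(c)] for c in rooted.root.children}
        assert frozenset({"O1"}) in sides

    def test_non_monophyletic_outgroup(self):
        with pytest.raises(NonMonophyleticOutgroupError):
            reroot_on_outgroup(parse_newick("(A,B,(O1,(C,O2)));"), {"O1", "O2"})

    def test_no_outgroup_present(self):
        with pytest.raises(NotRootableError):
            reroot_on_outgroup(parse_newick("(A,B,(C,D));"), {"O1", "O2"})

    def test_idempotent_and_preserves_path_lengths(self, rng):
        for _ in range(50):
            n = rng.randint(5, 15)
            tree = random_tree(rng, n)
            outgroup = {tree.leaves()[0].label}
            once = reroot_on_outgroup(tree, outgroup)
            twice = reroot_on_outgroup(once, outgroup)
            assert pairwise_path_lengths(once) == pairwise_path_lengths(tree)
            assert write_newick(twice) == write_newick(once)


class TestClades:
    def test_clades_of_examples(self):
        tree = parse_newick("((A,B)80,(C,D)60);")
        got = {(c.sort_key(), c.support) for c in clades_of(tree)}
        assert got == {(("A", "B"), 80), (("C", "D"), 60)}

    def test_star_tree_has_no_clades(self):
        tree = parse_newick("(A,B,C,D);")
        tree.rooted = True  # rooted star: internal structure absent
        assert clades_of(tree) == set()

    def test_caterpillar(self):
        tree = parse_newick("(((A,B),C),D);")
        got = {c.sort_key() for c in clades_of(tree)}
        assert got == {("A", "B"), ("A", "B", "C")}

    def test_unrooted_input_rejected(self):
        with pytest.raises(ValueError):
            clades_of(parse_newick("(A,B,(C,D));"))

    def test_restrict(self):
        assert restrict(Clade(frozenset("ABC")), "ABD").taxa == frozenset("AB")
        assert restrict(Clade(frozenset("AB")), "CD") is None
        assert restrict(Clade(frozenset("AB")), "AB").taxa == frozenset("AB")

    def test_restrict_carries_support(self):
        assert restrict(Clade(frozenset("ABC"), support=77), "AB").support == 77

    def test_conflict_examples(self):
        assert clades_conflict(Clade(frozenset("AB")), Clade(frozenset("AC")))
        assert not clades_conflict(Clade(frozenset("AB")), Clade(frozenset("ABC")))
        assert not clades_conflict(Clade(frozenset("AB")), Clade(frozenset("CD")))

    def test_conflict_properties(self, rng):
        universe = list("ABCDEFGH")
        for _ in range(200):
            x = Clade(frozenset(rng.sample(universe, rng.randint(1, 7))))
            y = Clade(frozenset(rng.sample(universe, rng.randint(1, 7))))
            assert clades_conflict(x, y) == clades_conflict(y, x)
            assert not clades_conflict(x, x)
            assert not clades_conflict(x, Clade(frozenset(universe)))


class TestDepth:
    def test_path_arithmetic(self):
        tree = parse_newick("(A:0.30,B:0.05,(C:0.05,D:0.05):0.05);")
        assert tip_to_tip_depth(tree) == pytest.approx(0.40)

    def test_two_leaves(self):
        assert tip_to_tip_depth(parse_newick("(A:1,B:1);")) == pytest.approx(2.0)

    def test_ultrametric_depth(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert tip_to_tip_depth(tree) == pytest.approx(4.0)
        assert tm.root_to_tip_depth(tree) == pytest.approx(2.0)

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError):
            tip_to_tip_depth(parse_newick("(A,B,(C,D));"))


class TestTaxonMap:
    def test_identity_default(self):
        m = tm.TaxonMap()
        assert m("acc1") == "acc1"

    def test_many_to_one(self):
        m = tm.TaxonMap({"acc1": "sp1", "acc2": "sp1"})
        assert m.map_set({"acc1", "acc2", "other"}) == {"sp1", "other"}

    def test_from_tsv(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("acc1\tsp1\nacc2\tsp1\n")
        m = tm.TaxonMap.from_tsv(p)
        assert m("acc2") == "sp1"
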