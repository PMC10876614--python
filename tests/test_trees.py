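"""Tree space: Newick I/O, backbone enumeration, monophyly, constrained
construction, and NJ within-clade resolution."""

import itertools

import pytest

import phylosignal as ps
from phylosignal.trees import (
    TreeFormatError,
    canonical_newick,
    cluster_distance,
    leaf_labels,
    resolve_group,
)


class TestNewickIO:
    def test_parse_basic_shape(self):
        t = ps.parse_newick("((A,B),(C,D));")
        assert leaf_labels(t) == {"A", "B", "C", "D"}
        assert ps.is_monophyletic(t, {"A", "B"})

    def test_round_trip_idempotent(self):
        s = "((A:0.1,B:0.2):0.05,C:0.3);"
        once = ps.write_newick(ps.parse_newick(s))
        twice = ps.write_newick(ps.parse_newick(once))
        assert once == twice

    def test_branch_lengths_preserved(self):
        t = ps.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        out = ps.write_newick(t)
        for tag in ("A:0.1", "B:0.2", "C:0.3"):
            assert tag in out

    def test_malformed_input_rejected(self):
        with pytest.raises(TreeFormatError):
            ps.parse_newick("((A,B),(C,D);")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeFormatError):
            ps.parse_newick("((A,B),(A,C));")


class TestEnumerateBackbones:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_double_factorial_counts(self, k, expected):
        labels = [f"L{i}" for i in range(k)]
        trees = ps.enumerate_backbones(labels)
        assert len(trees) == expected

    def test_no_canonical_duplicates_k6(self):
        labels = list("ABCDEF")
        trees = ps.enumerate_backbones(labels)
        canon = {canonical_newick(t) for t in trees}
        assert len(canon) == len(trees) == 945  # (2*6-3)!!

    def test_k3_exhaustive_listing(self):
        canon = {canonical_newick(t) for t in ps.enumerate_backbones(list("ABC"))}
        assert canon == {"((A,B),C);", "((A,C),B);", "((B,C),A);"}

    def test_deterministic_order(self):
        a = [canonical_newick(t) for t in ps.enumerate_backbones(list("ABCD"))]
        b = [canonical_newick(t) for t in ps.enumerate_backbones(list("ABCD"))]
        assert a == b == sorted(a)

    def test_too_few_labels_rejected(self):
        with pytest.raises(ValueError):
            ps.enumerate_backbones(["only"])


class TestMonophyly:
    @pytest.mark.parametrize("taxa,expected", [
        ({"A", "B"}, True),
        ({"C", "D"}, True),
        ({"B", "C"}, False),
        ({"A"}, True),  # a leaf is trivially a clade
    ])
    def test_rooted_monophyly(self, taxa, expected):
        t = ps.parse_newick("((A,B),(C,D));")
        assert ps.is_monophyletic(t, taxa) is expected

    def test_unknown_taxon_rejected(self):
        t = ps.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            ps.is_monophyletic(t, {"A", "Z"})


class TestBuildConstrainedTree:
    def test_singleton_clades_reproduce_backbone(self):
        bb = ps.parse_newick("((C1,C2),(C3,C4));")
        subtrees = {c: ps.parse_newick(f"{c.lower()};") for c in
                    ("C1", "C2", "C3", "C4")}
        full = ps.build_constrained_tree(bb, subtrees)
        assert canonical_newick(full) == "((c1,c2),(c3,c4));"

    def test_leaf_count_conservation_and_monophyly(self, four_clade_constraints):
        ccs = four_clade_constraints
        backbones = ps.enumerate_backbones(ccs.clade_labels)
        subtrees = {
            label: ps.parse_newick("(" + ",".join(sorted(taxa)) + ");")
            for label, taxa in ccs.clades.items()
        }
        og = ps.parse_newick("(OUT_1,OUT_2);")
        for bb in backbones[:4]:
            full = ps.build_constrained_tree(bb, subtrees, og)
            assert len(leaf_labels(full)) == len(ccs.all_taxa)
            for taxa in ccs.clades.values():
                assert ps.is_monophyletic(full, taxa)
            assert ps.is_monophyletic(full, ccs.outgroup)

    def test_all_fifteen_expansions_pairwise_distinct(self, four_clade_constraints):
        ccs = four_clade_constraints
        subtrees = {
            label: ps.parse_newick("(" + ",".join(sorted(taxa)) + ");")
            for label, taxa in ccs.clades.items()
        }
        og = ps.parse_newick("(OUT_1,OUT_2);")
        fulls = [
            ps.build_constrained_tree(bb, subtrees, og)
            for bb in ps.enumerate_backbones(ccs.clade_labels)
        ]
        for a, b in itertools.combinations(fulls, 2):
            assert cluster_distance(a, b) > 0

    def test_missing_subtree_rejected(self):
        bb = ps.parse_newick("(C1,C2);")
        with pytest.raises(ValueError):
            ps.build_constrained_tree(bb, {"C1": ps.parse_newick("x;")})


class TestWithinCladeResolution:
    def test_singleton_and_pair_shapes(self, gene_set):
        loci, _, _, _ = gene_set
        sm, _ = ps.concatenate(loci)
        one = resolve_group(sm, ["C1_1"])
        assert leaf_labels(one) == {"C1_1"}
        two = resolve_group(sm, ["C1_1", "C1_2"])
        assert canonical_newick(two) == "(C1_1,C1_2);"

    def test_nj_recovers_generating_subtree(self, jc):
        # 4-taxon caterpillar with clean additive distances, long alignment
        truth = ps.parse_newick(
            "(((p:0.05,q:0.05):0.1,r:0.15):0.05,s:0.2);"
        )
        aln = ps.simulate_alignment(truth, jc, 20_000, seed=77)
        got = resolve_group(aln, ["p", "q", "r", "s"])
        # NJ on consistent distances recovers the unique split {p,q} | {r,s}
        assert ps.is_monophyletic(got, {"p", "q"})

    def test_deterministic(self, gene_set):
        loci, _, _, _ = gene_set
        sm, _ = ps.concatenate(loci)
        taxa = ["C1_1", "C1_2", "C1_3", "C2_1"]
        a = ps.write_newick(resolve_group(sm, taxa))
        b = ps.write_newick(resolve_group(sm, taxa))
        assert a == b
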