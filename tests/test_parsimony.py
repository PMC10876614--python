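"""Fitch parsimony: trivial cases, independent oracles, invariances, and
constraint-preserving NNI refinement."""

import numpy as np
import pytest

import phylosignal as ps
from phylosignal.parsimony import MorphMatrix, read_morph_nexus, read_morph_tsv
from phylosignal.trees import CladeConstraintSet, canonical_newick
from oracle_utils import brute_force_parsimony, sankoff_length


def random_instance(seed, n_taxa=6, n_chars=12, n_states=3, missing=0.1):
    rng = np.random.default_rng(seed)
    tree = ps.simulate_yule_tree(n_taxa, seed=seed, branch_scale=1.0)
    mat = rng.integers(0, n_states, size=(n_taxa, n_chars)).astype("<U1")
    mask = rng.random(mat.shape) < missing
    mat[mask] = "?"
    taxa = sorted(f"t{i + 1}" for i in range(n_taxa))
    return tree, MorphMatrix(taxa, mat)


class TestFitchBasics:
    def test_invariant_characters_zero_length(self):
        t = ps.parse_newick("((A,B),(C,D));")
        m = MorphMatrix.from_rows([("A", "000"), ("B", "000"),
                                   ("C", "000"), ("D", "000")])
        assert ps.fitch_length(t, m) == 0

    @pytest.mark.parametrize("newick", [
        "((A,B),(C,D));", "((A,C),(B,D));", "(((A,B),C),D);",
    ])
    def test_single_derived_leaf_costs_one_anywhere(self, newick):
        t = ps.parse_newick(newick)
        m = MorphMatrix.from_rows([("A", "1"), ("B", "0"),
                                   ("C", "0"), ("D", "0")])
        assert ps.fitch_length(t, m) == 1

    def test_missing_state_never_forces_a_step(self):
        t = ps.parse_newick("((A,B),(C,D));")
        m = MorphMatrix.from_rows([("A", "?"), ("B", "0"),
                                   ("C", "0"), ("D", "-")])
        assert ps.fitch_length(t, m) == 0

    def test_multifurcation_rejected(self):
        t = ps.parse_newick("(A,B,C);")
        m = MorphMatrix.from_rows([("A", "0"), ("B", "0"), ("C", "1")])
        with pytest.raises(ValueError):
            ps.fitch_length(t, m)

    def test_leaf_without_data_rejected(self):
        t = ps.parse_newick("((A,B),(C,D));")
        m = MorphMatrix.from_rows([("A", "0"), ("B", "0"), ("C", "0")])
        with pytest.raises(ValueError):
            ps.fitch_length(t, m)


class TestFitchOracles:
    @pytest.mark.parametrize("seed", range(30))
    def test_fitch_equals_sankoff_and_brute_force(self, seed):
        tree, morph = random_instance(seed)
        fitch = ps.fitch_length(tree, morph)
        assert fitch == sankoff_length(tree, morph)
        assert fitch == brute_force_parsimony(tree, morph)


class TestFitchInvariances:
    def test_invariant_to_rerooting(self):
        tree, morph = random_instance(101)
        base = ps.fitch_length(tree, morph)
        # reroot on several edges of the same unrooted topology
        import dendropy

        for k in (1, 3, 5):
            t2 = ps.parse_newick(ps.write_newick(tree))
            edges = [e for e in t2.preorder_edge_iter()
                     if e.head_node.parent_node is not None
                     and e.head_node.parent_node.parent_node is not None]
            t2.reroot_at_edge(edges[k % len(edges)], update_bipartitions=False)
            t2.suppress_unifurcations()
            assert ps.fitch_length(t2, morph) == base

    def test_additive_over_characters(self):
        tree, m1 = random_instance(102, n_chars=8)
        _, m2 = random_instance(103, n_chars=5)
        joint = MorphMatrix(m1.taxa, np.hstack([m1.matrix, m2.matrix]))
        assert ps.fitch_length(tree, joint) == \
            ps.fitch_length(tree, m1) + ps.fitch_length(tree, m2)


class TestMorphIO:
    def test_tsv_round_trip(self, tmp_path):
        _, morph = random_instance(104)
        p = tmp_path / "m.tsv"
        from phylosignal.parsimony import write_morph_tsv

        write_morph_tsv(morph, p)
        back = read_morph_tsv(p)
        assert back.taxa == morph.taxa
        assert np.array_equal(back.matrix, morph.matrix)

    def test_nexus_reader(self, tmp_path):
        nexus = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=3 NCHAR=4;
FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
MATRIX
taxA 0102
taxB 01?2
taxC 1102
;
END;
"""
        p = tmp_path / "m.nex"
        p.write_text(nexus)
        morph = read_morph_nexus(p)
        assert morph.n_taxa == 3 and morph.n_chars == 4
        t = ps.parse_newick("((taxA,taxB),taxC);")
        assert ps.fitch_length(t, morph) == 1


class TestConstrainedRefinement:
    @pytest.fixture()
    def scenario(self):
        clades = {"L": frozenset({"a", "b", "c"}), "R": frozenset({"d", "e"}),
                  "M": frozenset({"f", "g"})}
        ccs = CladeConstraintSet(clades, frozenset({"o1"}))
        subtrees = {
            "L": ps.parse_newick("((a,b),c);"),
            "R": ps.parse_newick("(d,e);"),
            "M": ps.parse_newick("(f,g);"),
        }
        og = ps.parse_newick("o1;")
        return ccs, subtrees, og

    def test_refinement_never_worse_than_start(self, scenario):
        ccs, subtrees, og = scenario
        backbone = ps.enumerate_backbones(ccs.clade_labels)[0]
        start = ps.build_constrained_tree(backbone, subtrees, og)
        rng = np.random.default_rng(7)
        taxa = sorted(ccs.all_taxa)
        mat = rng.integers(0, 2, size=(len(taxa), 20)).astype("<U1")
        morph = MorphMatrix(taxa, mat)
        best, _ = ps.constrained_best_length(morph, ccs, backbone, subtrees, og)
        assert best <= ps.fitch_length(start, morph)

    def test_constraints_hold_at_optimum(self, scenario):
        ccs, subtrees, og = scenario
        backbone = ps.enumerate_backbones(ccs.clade_labels)[1]
        rng = np.random.default_rng(8)
        taxa = sorted(ccs.all_taxa)
        mat = rng.integers(0, 3, size=(len(taxa), 25)).astype("<U1")
        morph = MorphMatrix(taxa, mat)
        _, tree = ps.constrained_best_length(morph, ccs, backbone, subtrees, og)
        for taxa_set in ccs.clades.values():
            assert ps.is_monophyletic(tree, taxa_set)

    def test_generating_backbone_usually_shortest(self, four_clade_constraints):
        """Matrices evolved on one backbone score it at or below a rival."""
        ccs = four_clade_constraints
        backbones = ps.enumerate_backbones(ccs.clade_labels)
        subtrees = {
            label: ps.parse_newick("((%s,%s),%s);" % tuple(sorted(taxa)))
            for label, taxa in ccs.clades.items()
        }
        og = ps.parse_newick("(OUT_1,OUT_2);")
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            truth = ps.build_constrained_tree(backbones[0], subtrees, og)
            for e in truth.preorder_edge_iter():
                if e.head_node is not truth.seed_node:
                    e.length = 0.4
            morph = ps.simulate_morph_matrix(truth, 150, 3, seed=seed)
            l_true, _ = ps.constrained_best_length(
                morph, ccs, backbones[0], subtrees, og, seed=seed)
            l_alt, _ = ps.constrained_best_length(
                morph, ccs, backbones[5], subtrees, og, seed=seed)
            wins += l_true <= l_alt
        assert wins >= 0.9 * n_rep
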