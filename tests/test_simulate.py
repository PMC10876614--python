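"""Synthetic-data generator: determinism, distributional checks, occupancy,
and mixture composition."""

import numpy as np
import pytest
from scipy import stats

import phylosignal as ps
from phylosignal.trees import canonical_newick, leaf_labels


class TestYuleTree:
    def test_two_taxa_single_cherry(self):
        t = ps.simulate_yule_tree(2, seed=0)
        assert len(leaf_labels(t)) == 2
        assert len(list(t.preorder_internal_node_iter())) == 1

    def test_determinism(self):
        a = ps.write_newick(ps.simulate_yule_tree(8, seed=123))
        b = ps.write_newick(ps.simulate_yule_tree(8, seed=123))
        assert a == b

    def test_strictly_positive_branch_lengths(self):
        for seed in range(5):
            t = ps.simulate_yule_tree(10, seed=seed)
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length > 0

    def test_four_taxon_shapes_cover_enumeration(self):
        """Over many draws every rooted 4-leaf shape appears."""
        expected = {
            canonical_newick(t)
            for t in ps.enumerate_backbones(["t1", "t2", "t3", "t4"])
        }
        seen = set()
        for seed in range(400):
            seen.add(canonical_newick(ps.simulate_yule_tree(4, seed=seed)))
        assert seen == expected

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            ps.simulate_yule_tree(1, seed=0)


class TestSimulateAlignment:
    def test_zero_branch_lengths_give_identical_sequences(self, jc):
        t = ps.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = ps.simulate_alignment(t, jc, 50, seed=1)
        assert len({aln.sequence(x) for x in "ABCD"}) == 1

    def test_jc_pairwise_divergence_matches_closed_form(self, jc):
        t = 0.1
        tree = ps.parse_newick(f"(A:{t / 2},B:{t / 2});")
        n = 100_000
        aln = ps.simulate_alignment(tree, jc, n, seed=42)
        p_obs = np.mean(
            np.array(list(aln.sequence("A"))) != np.array(list(aln.sequence("B")))
        )
        p_exp = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) < 3 * se

    def test_stationary_base_composition(self):
        freqs = np.array([0.4, 0.3, 0.2, 0.1])
        model = ps.SubstitutionModel.gtr(np.ones(6), freqs)
        tree = ps.parse_newick("(A:0.5,B:0.5);")
        aln = ps.simulate_alignment(tree, model, 50_000, seed=7)
        counts = np.array([
            (aln.matrix == s).mean() for s in "ACGT"
        ])
        assert np.allclose(counts, freqs, atol=0.01)

    def test_determinism(self, jc):
        t = ps.simulate_yule_tree(5, seed=3)
        a = ps.simulate_alignment(t, jc, 100, seed=9)
        b = ps.simulate_alignment(t, jc, 100, seed=9)
        assert a == b


class TestGeneSet:
    def test_determinism_byte_level(self, clade_tree_pair, tmp_path):
        t1, t2 = clade_tree_pair
        config = ps.SimConfig(n_taxa=14, n_genes=3, sites_per_gene=100,
                              occupancy_range=(0.5, 1.0), seed=4)
        out = []
        for sub in ("a", "b"):
            loci, scheme, truths = ps.simulate_gene_set(t1, t2, config)
            d = tmp_path / sub
            from phylosignal.simulate import export_gene_set
            export_gene_set(d, loci, scheme, truths, t1, t2, config)
            out.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
        assert out[0] == out[1]

    def test_pure_mixture_degenerate(self, clade_tree_pair):
        t1, t2 = clade_tree_pair
        config = ps.SimConfig(n_taxa=14, n_genes=10, sites_per_gene=50,
                              prop_tree1=1.0, occupancy_range=(1.0, 1.0), seed=2)
        _, _, truths = ps.simulate_gene_set(t1, t2, config)
        assert all(t.source_topology == "T1" for t in truths)

    def test_full_occupancy_means_no_masking(self, clade_tree_pair):
        t1, t2 = clade_tree_pair
        config = ps.SimConfig(n_taxa=14, n_genes=5, sites_per_gene=50,
                              occupancy_range=(1.0, 1.0), seed=2)
        loci, _, truths = ps.simulate_gene_set(t1, t2, config)
        for (_, aln), truth in zip(loci, truths):
            assert truth.realized_occupancy == 1.0
            assert not aln.missing_mask().all(axis=1).any()

    def test_occupancy_enforced_per_gene(self, gene_set):
        loci, _, truths, config = gene_set
        lo, hi = config.occupancy_range
        for truth in truths:
            assert lo <= truth.realized_occupancy <= hi

    def test_infeasible_occupancy_rejected(self, clade_tree_pair):
        t1, t2 = clade_tree_pair
        with pytest.raises(ValueError):
            config = ps.SimConfig(n_taxa=14, n_genes=2, sites_per_gene=50,
                                  occupancy_range=(0.001, 0.02), seed=0)
            ps.simulate_gene_set(t1, t2, config)

    def test_mixture_composition_binomial(self, six_taxon_pair):
        """T1 gene fraction consistent with prop_tree1 at n=1000 (alpha=0.01)."""
        t1, t2 = six_taxon_pair
        config = ps.SimConfig(n_taxa=6, n_genes=1000, sites_per_gene=1,
                              prop_tree1=0.7, occupancy_range=(1.0, 1.0), seed=8)
        _, _, truths = ps.simulate_gene_set(t1, t2, config)
        k = sum(t.source_topology == "T1" for t in truths)
        p = stats.binomtest(k, 1000, 0.7).pvalue
        assert p > 0.01


class TestMorphMatrix:
    def test_zero_rate_invariant_characters(self):
        t = ps.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        morph = ps.simulate_morph_matrix(t, 30, 2, seed=1)
        assert ps.fitch_length(t, morph) == 0

    def test_generating_tree_usually_shorter_than_alternative(self):
        truth = ps.parse_newick(
            "(((a:0.3,b:0.3):0.3,(c:0.3,d:0.3):0.3):0.2,(e:0.3,f:0.3):0.2);"
        )
        alt = ps.parse_newick(
            "(((a:0.3,e:0.3):0.3,(c:0.3,b:0.3):0.3):0.2,(d:0.3,f:0.3):0.2);"
        )
        wins = 0
        for seed in range(20):
            m = ps.simulate_morph_matrix(truth, 200, 3, seed=seed)
            if ps.fitch_length(truth, m) <= ps.fitch_length(alt, m):
                wins += 1
        assert wins >= 17

    def test_model_agreement_with_likelihood(self, jc):
        """Mean site lnL is higher under the generating tree than a perturbed one."""
        truth = ps.parse_newick(
            "(((a:0.2,b:0.2):0.15,(c:0.2,d:0.2):0.15):0.1,(e:0.2,f:0.2):0.1);"
        )
        wrong = ps.parse_newick(
            "(((a:0.2,c:0.2):0.15,(b:0.2,d:0.2):0.15):0.1,(e:0.2,f:0.2):0.1);"
        )
        aln = ps.simulate_alignment(truth, jc, 5000, seed=33)
        assert (
            ps.site_log_likelihoods(truth, aln, jc).mean()
            > ps.site_log_likelihoods(wrong, aln, jc).mean()
        )
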