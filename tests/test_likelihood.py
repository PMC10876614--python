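"""Likelihood core: pruning against closed forms and the exhaustive-state
oracle, branch-length optimization, and partitioned candidate fitting."""

import numpy as np
import pytest

import phylosignal as ps
from phylosignal.likelihood import (
    PruningEngine,
    SiteLnLMatrix,
    TreeIndex,
    empirical_base_frequencies,
)
from oracle_utils import brute_force_site_lnl


def total_tree_length(tree):
    return sum(e.length for e in tree.preorder_edge_iter() if e.length)


class TestClosedForms:
    def test_identical_pair_zero_distance(self, jc):
        tree = ps.parse_newick("(A:0,B:0);")
        aln = ps.Alignment.from_sequences([("A", "A"), ("B", "A")])
        lnl = ps.site_log_likelihoods(tree, aln, jc)
        assert lnl[0] == pytest.approx(np.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("t", [0.05, 0.2, 1.0])
    def test_jc_pair_matching_site(self, jc, t):
        tree = ps.parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = ps.Alignment.from_sequences([("A", "C"), ("B", "C")])
        expected = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3)))
        lnl = ps.site_log_likelihoods(tree, aln, jc)
        assert lnl[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("t", [0.05, 0.2, 1.0])
    def test_jc_pair_mismatching_site(self, jc, t):
        tree = ps.parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = ps.Alignment.from_sequences([("A", "C"), ("B", "G")])
        expected = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3)))
        lnl = ps.site_log_likelihoods(tree, aln, jc)
        assert lnl[0] == pytest.approx(expected, rel=1e-12)


class TestExhaustiveStateOracle:
    @pytest.mark.parametrize("seed,n_taxa,gamma", [
        (0, 4, None), (1, 4, 0.5), (2, 5, None), (3, 5, 1.2),
        (4, 6, None), (5, 6, 0.8), (6, 3, 2.0), (7, 6, 0.3),
    ])
    def test_pruning_matches_brute_force(self, seed, n_taxa, gamma):
        rng = np.random.default_rng(seed)
        tree = ps.simulate_yule_tree(n_taxa, seed=seed, branch_scale=0.5)
        model = ps.SubstitutionModel.gtr(
            rng.uniform(0.3, 3.0, 6),
            rng.dirichlet([8, 8, 8, 8]),
            gamma_shape=gamma,
            n_rate_categories=4,
        )
        aln = ps.simulate_alignment(tree, model, 12, seed=seed + 100)
        # sprinkle ambiguity to exercise partial-likelihood handling
        mat = aln.matrix.copy()
        mat[0, 0] = "?"
        mat[1, 1] = "-"
        mat[0, 2] = "N"
        aln = ps.Alignment(aln.taxa, mat)
        got = ps.site_log_likelihoods(tree, aln, model)
        expected = brute_force_site_lnl(tree, aln, model)
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)


class TestLikelihoodProperties:
    def test_per_site_lnl_nonpositive_and_sums_to_total(self, jc):
        tree = ps.simulate_yule_tree(8, seed=2, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 300, seed=5)
        site = ps.site_log_likelihoods(tree, aln, jc)
        assert (site <= 0).all()
        assert site.sum() == pytest.approx(
            ps.total_log_likelihood(tree, aln, jc), abs=1e-8
        )

    def test_invariant_to_leaf_order_permutation(self, jc):
        tree = ps.simulate_yule_tree(6, seed=3, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 100, seed=6)
        shuffled = aln.subset_taxa(list(reversed(aln.taxa)))
        a = ps.site_log_likelihoods(tree, aln, jc)
        b = ps.site_log_likelihoods(tree, shuffled, jc)
        assert np.allclose(a, b, rtol=1e-12)

    def test_deep_divergence_stays_finite(self, jc):
        """Per-node rescaling keeps long-branch likelihoods representable."""
        tree = ps.simulate_yule_tree(24, seed=4, branch_scale=4.0)
        aln = ps.simulate_alignment(tree, jc, 60, seed=7)
        site = ps.site_log_likelihoods(tree, aln, jc)
        assert np.isfinite(site).all()
        assert (site <= 0).all()

    def test_missing_taxon_rejected(self, jc):
        tree = ps.parse_newick("((A:0.1,B:0.1):0.1,Z:0.1);")
        aln = ps.Alignment.from_sequences([("A", "AC"), ("B", "AC")])
        with pytest.raises(ValueError):
            ps.site_log_likelihoods(tree, aln, jc)


class TestBranchOptimization:
    def test_jc_distance_mle_closed_form(self, jc):
        tree = ps.parse_newick("(A:0.05,B:0.05);")
        aln = ps.simulate_alignment(tree, jc, 20_000, seed=3)
        p = np.mean(
            np.array(list(aln.sequence("A"))) != np.array(list(aln.sequence("B")))
        )
        expected = -0.75 * np.log(1 - 4 * p / 3)
        opt, _ = ps.optimize_branch_lengths(
            ps.parse_newick("(A:0.05,B:0.05);"), aln, jc
        )
        assert total_tree_length(opt) == pytest.approx(expected, abs=1e-5)

    def test_lnl_never_decreases_from_start(self, jc):
        tree = ps.simulate_yule_tree(7, seed=9, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 200, seed=10)
        initial = ps.total_log_likelihood(tree, aln, jc)
        _, final = ps.optimize_branch_lengths(tree, aln, jc, tol=1e-5)
        assert final >= initial - 1e-9

    def test_fixed_point_at_optimum(self, jc):
        tree = ps.simulate_yule_tree(5, seed=11, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 500, seed=12)
        t1, l1 = ps.optimize_branch_lengths(tree, aln, jc, tol=1e-8)
        t2, l2 = ps.optimize_branch_lengths(t1, aln, jc, tol=1e-8)
        assert l2 == pytest.approx(l1, abs=1e-4)


class TestModelEstimation:
    def test_empirical_frequencies_reflect_composition(self):
        aln = ps.Alignment.from_sequences([("A", "AAAC"), ("B", "AAGC")])
        freqs = empirical_base_frequencies(aln)
        assert freqs[0] > freqs[2]  # A dominates
        assert freqs.sum() == pytest.approx(1.0)

    def test_gtr_estimation_recovers_transition_bias(self):
        truth = ps.SubstitutionModel.gtr(
            [1, 6, 1, 1, 6, 1], [0.25, 0.25, 0.25, 0.25]
        )
        tree = ps.simulate_yule_tree(6, seed=21, branch_scale=0.4)
        aln = ps.simulate_alignment(tree, truth, 4000, seed=22)
        fitted, _ = ps.estimate_model(aln, tree, family="GTR", gamma=False)
        ex = fitted.exchangeabilities
        # transitions (AG, CT) should clearly exceed transversions
        assert ex[1] > 2 * ex[0] and ex[4] > 2 * ex[3]


class TestFitCandidates:
    def test_row_sum_matches_direct_optimization(self, jc):
        tree = ps.simulate_yule_tree(5, seed=30, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 300, seed=31)
        matrix = ps.fit_candidates(aln, None, {"t": tree},
                                   model_family="JC", gamma=False, tol=1e-5)
        _, direct = ps.optimize_branch_lengths(
            ps.parse_newick(ps.write_newick(tree)), aln, jc, tol=1e-6
        )
        assert matrix.total_lnl()[0] == pytest.approx(direct, abs=0.05)

    def test_identical_candidates_identical_rows(self, jc):
        tree = ps.simulate_yule_tree(5, seed=32, branch_scale=0.3)
        aln = ps.simulate_alignment(tree, jc, 200, seed=33)
        nwk = ps.write_newick(tree)
        matrix = ps.fit_candidates(
            aln, None,
            {"a": ps.parse_newick(nwk), "b": ps.parse_newick(nwk)},
            model_family="JC", gamma=False,
        )
        assert np.allclose(matrix.site_lnl[0], matrix.site_lnl[1], atol=1e-6)

    def test_generating_tree_beats_wrong_tree(self, six_taxon_pair, jc):
        t1, t2 = six_taxon_pair
        aln = ps.simulate_alignment(t1, jc, 3000, seed=34)
        matrix = ps.fit_candidates(aln, None, {"T1": t1, "T2": t2},
                                   model_family="JC", gamma=False)
        totals = dict(zip(matrix.tree_ids, matrix.total_lnl()))
        assert totals["T1"] > totals["T2"]

    def test_sitelh_round_trip(self, tmp_path):
        matrix = SiteLnLMatrix(["x", "y"], np.array([[-1.0, -2.5], [-1.5, -2.0]]))
        p = tmp_path / "out.sitelh"
        matrix.write_sitelh(p)
        back = SiteLnLMatrix.read_sitelh(p)
        assert back.tree_ids == ["x", "y"]
        assert np.allclose(back.site_lnl, matrix.site_lnl)
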