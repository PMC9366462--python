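import numpy as np
import pytest

import nonrev as nv
from nonrev.estimation import (EstimationConfig, assign_best_models,
                               estimate_tree, neighbor_joining_tree,
                               nqmaker_estimate, optimize_branch_lengths,
                               optimize_q_nonreversible)
from nonrev.likelihood import TreeLikelihood


class TestOptimizeBranchLengths:
    def test_two_taxon_jc_closed_form(self, jc20):
        """ML distance between two sequences under the 20-state JC analogue
        has the closed form -(19/20) ln(1 - (20/19) p)."""
        tree = nv.parse_newick("(A:0.05,B:0.05);")
        aln = nv.simulate_alignment(jc20, nv.UNIFORM_RATES, tree, 50_000, 3)
        p = np.mean([a != b for a, b in zip(aln.sequence("A"),
                                            aln.sequence("B"))])
        opt, _ = optimize_branch_lengths(jc20, nv.UNIFORM_RATES, tree, aln)
        fitted = sum(c.length for c in opt.root.children)
        expected = -(19 / 20) * np.log(1 - (20 / 19) * p)
        assert fitted == pytest.approx(expected, abs=1e-4)

    def test_identical_sequences_hit_lower_bound(self, jc20, tree6):
        aln = nv.Alignment([l.label for l in tree6.leaves()],
                           ["ARNDARND"] * 6)
        opt, _ = optimize_branch_lengths(jc20, nv.UNIFORM_RATES, tree6, aln)
        for n in opt.postorder():
            if n.parent is not None:
                assert n.length < 1e-6

    def test_idempotent(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 500, 4)
        t1, l1 = optimize_branch_lengths(nq_strong, nv.UNIFORM_RATES, tree6,
                                         aln)
        t2, l2 = optimize_branch_lengths(nq_strong, nv.UNIFORM_RATES, t1, aln)
        assert l2 - l1 < 1e-4 and l2 >= l1 - 1e-9


class TestOptimizeQ:
    def test_ascent_guarantee(self, lg, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 800, 5)
        eng = TreeLikelihood(lg, nv.UNIFORM_RATES, tree6.copy(), aln)
        start_ll = eng.log_likelihood()
        est, info = optimize_q_nonreversible([eng], lg, max_iter=30, tol=0.05)
        assert info["log_likelihood"] >= start_ll - 1e-6
        assert np.all(np.diff(info["history"]) >= -1e-6)
        assert abs(est.mean_rate - 1.0) < 1e-10  # normalized on exit

    def test_self_consistency(self, nq_strong):
        """Fixed-point stability: restarted at its own optimum, the
        estimator returns an essentially identical matrix."""
        tree = nv.random_rooted_tree(12, 7)
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree,
                                    20_000, 11)
        eng = TreeLikelihood(nq_strong, nv.UNIFORM_RATES, tree.copy(), aln)
        first, _ = optimize_q_nonreversible([eng], nv.load_builtin("LG"),
                                            max_iter=80, tol=0.01)
        second, _ = optimize_q_nonreversible([eng], first, max_iter=80,
                                             tol=0.01)
        assert nv.matrix_correlation(first, second) >= 0.999
        # and both stay close to the generating truth on this much data
        assert nv.matrix_correlation(first, nq_strong) >= 0.95


@pytest.fixture(scope="module")
def resolvable_tree():
    # all internal edges long enough to be recoverable from 2000 sites
    return nv.random_rooted_tree(6, 7)


class TestStartingTrees:
    def test_nj_recovers_topology(self, nq_strong, resolvable_tree):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES,
                                    resolvable_tree, 2000, 13)
        nj = neighbor_joining_tree(aln)
        assert nv.normalized_rf(nj, resolvable_tree) == 0.0

    def test_estimate_tree_rooted_under_nonreversible(self, nq_strong,
                                                      resolvable_tree):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES,
                                    resolvable_tree, 2000, 13)
        tree, logl = estimate_tree(nq_strong, nv.UNIFORM_RATES, aln)
        assert tree.rooted
        assert nv.normalized_rf(tree, resolvable_tree) == 0.0
        assert np.isfinite(logl)


class TestAssignBestModels:
    def test_single_candidate_always_chosen(self, lg, tree6):
        aln = nv.simulate_alignment(lg, nv.UNIFORM_RATES, tree6, 300, 2)
        out = assign_best_models([aln], [lg], rate_model_names=("",),
                                 nni=False)
        assert out[0].matrix.name == "LG"

    def test_lg_data_prefers_lg(self, lg):
        """Matrix selection on 50 LG-simulated loci of 200 sites: LG must
        beat WAG and JTT on at least 90% of loci."""
        cands = [nv.load_builtin(n) for n in ("LG", "WAG", "JTT")]
        wins = 0
        n_loci = 50
        for i in range(n_loci):
            tree = nv.random_rooted_tree(6, 500 + i)
            aln = nv.simulate_alignment(lg, nv.UNIFORM_RATES, tree, 200,
                                        600 + i)
            out = assign_best_models([aln], cands, rate_model_names=("",),
                                     nni=False)
            wins += out[0].matrix.name == "LG"
        assert wins >= 0.9 * n_loci

    def test_nonreversible_candidate_wins_on_long_loci(self, lg, nq_strong):
        tree = nv.random_rooted_tree(8, 31)
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree,
                                    5000, 32)
        out = assign_best_models([aln], [lg, nq_strong],
                                 rate_model_names=("",), nni=False)
        assert out[0].matrix.name == nq_strong.name
        assert out[0].tree.rooted

    def test_tiny_alignment_skipped(self, lg):
        aln = nv.Alignment(["A", "B"], ["ARND", "ARND"])
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            assign_best_models([aln], [lg], rate_model_names=("",))


class TestConfig:
    def test_config_file_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text(
            "logl_epsilon = 0.2\ncorr_threshold = 0.99\n"
            "max_outer_iterations = 4\nrate_models = ,+G4\n"
            "mode = edge-linked\nnni = false\nseed = 3\n")
        cfg = EstimationConfig.from_file(path)
        assert cfg.logl_epsilon == 0.2
        assert cfg.corr_threshold == 0.99
        assert cfg.max_outer_iterations == 4
        assert cfg.rate_model_names == ("", "+G4")
        assert cfg.mode == "edge-linked"
        assert cfg.nni is False and cfg.seed == 3

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.txt"
        path.write_text("not_a_key = 1\n")
        with pytest.raises(KeyError):
            EstimationConfig.from_file(path)




@pytest.fixture(scope="module")
def small_run(nq_strong):
    trees = [nv.random_rooted_tree(6, 100 + i) for i in range(2)]
    loci = [nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, t, 1500,
                                  200 + i, name=f"loc{i}")
            for i, t in enumerate(trees)]
    cfg = EstimationConfig(rate_model_names=("",), nni=False,
                           em_max_iter=50, max_outer_iterations=6)
    return loci, cfg, nqmaker_estimate(loci, config=cfg)


class TestEstimationLoop:
    def test_converges(self, small_run):
        _, _, (est, state) = small_run
        assert state.converged
        assert state.iteration <= 5

    def test_history_monotone_within_iterations(self, small_run):
        _, _, (est, state) = small_run
        for rec in state.history:
            lls = [v for _, v in rec["cycles"]]
            assert np.all(np.diff(lls) >= -1e-6)

    def test_final_matrix_normalized_nonreversible(self, small_run):
        _, _, (est, state) = small_run
        assert abs(est.mean_rate - 1.0) < 1e-10
        assert not est.is_reversible
        assert nv.free_parameter_count(est) == 379

    def test_deterministic(self, small_run):
        loci, cfg, (est, _) = small_run
        est2, _ = nqmaker_estimate(loci, config=cfg)
        assert np.array_equal(est.rates, est2.rates)

    def test_edge_linked_mode(self, nq_strong):
        tree = nv.random_rooted_tree(6, 300)
        loci = [nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree,
                                      800, 400 + i, name=f"p{i}")
                for i in range(2)]
        cfg = EstimationConfig(rate_model_names=("",), nni=False,
                               mode="edge-linked", em_max_iter=30,
                               max_outer_iterations=3)
        est, state = nqmaker_estimate(loci, config=cfg)
        assert abs(est.mean_rate - 1.0) < 1e-10
        for rec in state.history:
            lls = [v for _, v in rec["cycles"]]
            assert np.all(np.diff(lls) >= -1e-6)
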