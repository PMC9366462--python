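import numpy as np
import pytest

import nonrev as nv
from nonrev.likelihood import TreeLikelihood

from helpers import brute_force_site_likelihood, pruning_longdouble


class TestSiteLikelihood:
    def test_degenerate_branches(self, jc20):
        """Two tips in the same state joined by zero-length branches: the
        site likelihood collapses to the stationary frequency."""
        tree = nv.parse_newick("(A:0,B:0);")
        ll = nv.site_log_likelihood(jc20, nv.UNIFORM_RATES, tree,
                                    {"A": "R", "B": "R"})
        assert ll == pytest.approx(np.log(0.05), abs=1e-12)

    def test_two_taxon_direct_summation(self, nq_strong):
        t1, t2 = 0.3, 0.7
        tree = nv.parse_newick(f"(A:{t1},B:{t2});")
        pi = nq_strong.frequencies
        p1 = nq_strong.transition(t1).probs
        p2 = nq_strong.transition(t2).probs
        ia, ib = 0, 4  # A and C in PAML order
        expected = float(np.sum(pi * p1[:, ia] * p2[:, ib]))
        ll = nv.site_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree,
                                    {"A": "A", "B": "C"})
        assert ll == pytest.approx(np.log(expected), abs=1e-12)

    def test_all_missing_column_is_certain(self, nq_strong, tree6):
        pattern = {leaf.label: "?" for leaf in tree6.leaves()}
        ll = nv.site_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, pattern)
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_five_taxon_exhaustive_oracle(self, nq_strong):
        tree = nv.parse_newick(
            "((A:0.2,B:0.4):0.1,((C:0.3,D:0.1):0.2,E:0.5):0.15);")
        rm = nv.discretize_gamma(0.8, 2)
        pattern = {"A": "A", "B": "R", "C": "N", "D": "A", "E": "B"}
        expected = brute_force_site_likelihood(nq_strong, rm, tree, pattern)
        ll = nv.site_log_likelihood(nq_strong, rm, tree, pattern)
        assert ll == pytest.approx(np.log(expected), rel=1e-10)

    def test_unrooted_tree_rejected(self, nq_strong):
        tree = nv.parse_newick("((A:1,B:1):0.5,C:1,D:1);")
        with pytest.raises(ValueError):
            nv.site_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree,
                                   {"A": "A", "B": "A", "C": "A", "D": "A"})

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            nv.Alignment(["A", "B"], ["AO", "AA"])


class TestTreeLikelihood:
    def test_duplicated_alignment_doubles_logl(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 80, 3)
        doubled = nv.Alignment(aln.taxa,
                               [aln.sequence(t) * 2 for t in aln.taxa])
        l1 = nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, aln)
        l2 = nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, doubled)
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_saturated_branches_destroy_signal(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 200, 3)
        stretched = tree6.copy()
        for n in stretched.postorder():
            if n.parent is not None:
                n.length *= 1e6
        l0 = nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, aln)
        l1 = nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, stretched, aln)
        assert l1 < l0

    def test_taxon_order_invariance(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 60, 5)
        rev = nv.Alignment(aln.taxa[::-1],
                           [aln.sequence(t) for t in aln.taxa[::-1]])
        assert (nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, rev)
                == pytest.approx(nv.tree_log_likelihood(
                    nq_strong, nv.UNIFORM_RATES, tree6, aln), abs=1e-9))

    def test_pattern_compression_lossless(self, jc20, tree6):
        rng = np.random.default_rng(0)
        cols = rng.choice(list("ARND"), size=(6, 30))
        seqs = ["".join(cols[i]) * 3 for i in range(6)]  # heavy duplication
        aln = nv.Alignment([l.label for l in tree6.leaves()], seqs)
        assert aln.n_patterns < aln.n_sites
        # sum of per-column site likelihoods must equal the engine total
        taxa = aln.taxa
        total = sum(nv.site_log_likelihood(
            jc20, nv.UNIFORM_RATES, tree6,
            {t: aln.sequence(t)[i] for t in taxa}) for i in range(aln.n_sites))
        assert nv.tree_log_likelihood(jc20, nv.UNIFORM_RATES, tree6, aln) == \
            pytest.approx(total, abs=1e-9)

    def test_root_invariance_reversible_only(self, lg, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 400, 9)
        un = tree6.unrooted()
        spreads = {}
        for model in (lg, nq_strong):
            lls = [nv.tree_log_likelihood(model, nv.UNIFORM_RATES,
                                          un.reroot_on_edge(s, 0.4), aln)
                   for s in un.edge_splits()]
            spreads[model.name] = max(lls) - min(lls)
        assert spreads[lg.name] < 1e-8
        assert spreads[nq_strong.name] > 1e-3

    def test_underflow_protection_matches_longdouble(self, nq_strong):
        tree = nv.random_rooted_tree(8, 21, branch_length_mean=0.4)
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree, 40, 22)
        rm = nv.discretize_gamma(0.6, 2)
        fast = nv.tree_log_likelihood(nq_strong, rm, tree, aln)
        slow = pruning_longdouble(nq_strong, rm, tree, aln)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_large_tree_no_underflow(self, jc20):
        tree = nv.random_rooted_tree(120, 33)
        aln = nv.simulate_alignment(jc20, nv.UNIFORM_RATES, tree, 30, 34)
        ll = nv.tree_log_likelihood(jc20, nv.UNIFORM_RATES, tree, aln)
        assert np.isfinite(ll) and ll < 0


class TestPartitioned:
    def test_single_locus_reduces(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 100, 3)
        data = nv.PartitionedData([aln], models=[nq_strong])
        assert nv.partitioned_log_likelihood(data, tree6) == pytest.approx(
            nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, aln))

    def test_two_identical_loci_double(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 100, 3)
        data = nv.PartitionedData([aln, aln], models=[nq_strong] * 2)
        assert nv.partitioned_log_likelihood(data, tree6) == pytest.approx(
            2 * nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES, tree6, aln),
            abs=1e-9)

    def test_scales_match_rescaled_trees(self, nq_strong, tree6):
        alns = [nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6,
                                      100, s) for s in (3, 4)]
        data = nv.PartitionedData(alns, models=[nq_strong] * 2,
                                  scales=[0.5, 2.0])
        expected = 0.0
        for aln, scale in zip(alns, (0.5, 2.0)):
            private = tree6.copy()
            for n in private.postorder():
                if n.parent is not None:
                    n.length *= scale
            expected += nv.tree_log_likelihood(nq_strong, nv.UNIFORM_RATES,
                                               private, aln)
        assert nv.partitioned_log_likelihood(data, tree6) == pytest.approx(
            expected, abs=1e-8)

    def test_missing_taxon_rejected(self, nq_strong, tree6):
        aln = nv.Alignment(["T1", "T2"], ["AA", "AA"])
        data = nv.PartitionedData([aln], models=[nq_strong])
        with pytest.raises(ValueError):
            nv.partitioned_log_likelihood(data, tree6)


class TestCaching:
    def test_results_identical_with_cache_cleared(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 50, 3)
        eng = TreeLikelihood(nq_strong, nv.discretize_gamma(1.0, 4), tree6, aln)
        l1 = eng.log_likelihood()
        eng._pcache.clear()
        assert eng.log_likelihood() == l1

    def test_length_update_invalidates(self, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 50, 3)
        eng = TreeLikelihood(nq_strong, nv.UNIFORM_RATES, tree6, aln)
        l1 = eng.log_likelihood()
        x = eng.get_lengths()
        eng.set_lengths(x * 2)
        l2 = eng.log_likelihood()
        eng.set_lengths(x)
        assert eng.log_likelihood() == l1 and l2 != l1


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path, nq_strong, tree6):
        aln = nv.simulate_alignment(nq_strong, nv.UNIFORM_RATES, tree6, 73, 3)
        path = tmp_path / "a.fasta"
        nv.write_fasta(aln, path)
        back = nv.read_fasta(path)
        assert back.taxa == aln.taxa
        assert all(back.sequence(t) == aln.sequence(t) for t in aln.taxa)

    def test_phylip_reader(self, tmp_path):
        path = tmp_path / "a.phy"
        path.write_text(" 2 5\nTaxonOne  ARND-\nTaxonTwo  ARNDC\n")
        aln = nv.read_phylip(path)
        assert aln.taxa == ["TaxonOne", "TaxonTwo"]
        assert aln.sequence("TaxonOne") == "ARND-"
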