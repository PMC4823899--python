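"""ML engine checks: pruning against exhaustive ancestral-state enumeration,
likelihood invariances, branch-length recovery, NJ and topology search."""

import itertools

import numpy as np
import pytest

from ucatest.io_formats import SequenceSet
from ucatest.models import AMINO_ACIDS, get_model
from ucatest.phylo import (
    MAX_BRANCH_LENGTH,
    ModelPrep,
    Tree,
    log_likelihood,
    ml_tree,
    nj_tree,
    optimize_branch_lengths,
    optimize_model,
    tree_length,
)
from ucatest.phylo.tree import Node
from ucatest.simulate import simulate_on_tree, simulate_star_io


def brute_force_loglik(aln: SequenceSet, tree: Tree, model) -> float:
    """Independent oracle: sum over all joint ancestral-state assignments."""
    prep = ModelPrep(model)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    seqd = dict(aln.records)
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    pmats = {id(n): prep.transition_matrices(n.length) for n in nodes if n.parent}
    total = 0.0
    n_cols = len(aln.records[0][1])
    for site in range(n_cols):
        lik = 0.0
        for k, w in enumerate(prep.weights):
            for assign in itertools.product(range(20), repeat=len(internal)):
                amap = {id(n): s for n, s in zip(internal, assign)}
                p = prep.pi[amap[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    a = amap[id(n.parent)]
                    if n.is_leaf:
                        c = seqd[n.label][site]
                        if c == "-":
                            continue
                        b = idx[c]
                    else:
                        b = amap[id(n)]
                    p *= pmats[id(n)][k, a, b]
                lik += w * p
        total += np.log(lik)
    return total


def random_alignment(labels, n_cols, rng, gap_rate=0.0):
    rows = []
    for lab in labels:
        chars = rng.choice(list(AMINO_ACIDS), size=n_cols)
        if gap_rate:
            mask = rng.random(n_cols) < gap_rate
            chars = np.where(mask, "-", chars)
        rows.append((lab, "".join(chars)))
    return SequenceSet(rows)


class TestPruningOracle:
    def test_two_taxa_single_site(self):
        aln = SequenceSet([("a", "A"), ("b", "A")])
        root = Node()
        root.add(Node("a", 0.0))
        root.add(Node("b", 0.0))
        ll = log_likelihood(aln, Tree(root), get_model("Poisson"))
        assert ll == pytest.approx(np.log(1 / 20), abs=1e-12)

    @pytest.mark.parametrize("name", ["Poisson", "Poisson+F", "LG", "LG+G", "LG+I+G"])
    def test_three_taxon_star(self, name, rng):
        aln = random_alignment("abc", 6, rng, gap_rate=0.15)
        tree = Tree.star("abc", 0.5)
        model = get_model(name)
        assert log_likelihood(aln, tree, model) == pytest.approx(
            brute_force_loglik(aln, tree, model), abs=1e-8
        )

    @pytest.mark.parametrize("name", ["Poisson+F", "LG+G", "LG+I+G+F"])
    def test_quartet(self, name, rng):
        aln = random_alignment("abcd", 5, rng, gap_rate=0.1)
        tree = Tree.quartet(list("abcd"), 0.4, 0.15)
        model = get_model(name)
        assert log_likelihood(aln, tree, model) == pytest.approx(
            brute_force_loglik(aln, tree, model), abs=1e-8
        )

    def test_saturated_independence_limit(self, rng):
        """With every branch at the cap the likelihood factorises into
        per-leaf stationary terms."""
        aln = random_alignment("abcd", 40, rng)
        tree = Tree.star("abcd", MAX_BRANCH_LENGTH)
        model = get_model("LG")
        pi = model.frequencies
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        expect = sum(
            np.log(pi[idx[c]]) for _, seq in aln for c in seq
        )
        assert log_likelihood(aln, tree, model) == pytest.approx(expect, abs=1e-6)


class TestLikelihoodInvariances:
    def test_root_placement(self, rng):
        """The same unrooted quartet scored from a binary root and from a
        trifurcating root gives identical likelihoods."""
        aln = random_alignment("abcd", 30, rng)
        t1 = Tree.quartet(list("abcd"), 0.3, 0.2)  # internal edge split 0.1+0.1
        root = Node()
        cherry = root.add(Node(length=0.2))
        cherry.add(Node("a", 0.3))
        cherry.add(Node("b", 0.3))
        root.add(Node("c", 0.3))
        root.add(Node("d", 0.3))
        t2 = Tree(root)
        m = get_model("LG+G")
        assert log_likelihood(aln, t1, m) == pytest.approx(
            log_likelihood(aln, t2, m), abs=1e-8
        )

    def test_leaf_order_and_column_order(self, rng):
        aln = random_alignment("abcd", 25, rng, gap_rate=0.1)
        tree = Tree.quartet(list("abcd"), 0.4, 0.1)
        m = get_model("Poisson+F")
        base = log_likelihood(aln, tree, m)
        reordered = SequenceSet(list(reversed(aln.records)))
        assert log_likelihood(reordered, tree, m) == pytest.approx(base, abs=1e-8)
        perm = rng.permutation(25)
        mat = aln.to_matrix()[:, perm]
        shuffled = SequenceSet.from_matrix(aln.ids, mat)
        assert log_likelihood(shuffled, tree, m) == pytest.approx(base, abs=1e-8)

    def test_duplicated_columns_double_loglik(self, rng):
        """Pattern compression: repeating every column doubles the LnL."""
        aln = random_alignment("abc", 15, rng)
        mat = aln.to_matrix()
        doubled = SequenceSet.from_matrix(aln.ids, np.hstack([mat, mat]))
        tree = Tree.star("abc", 0.6)
        m = get_model("LG")
        assert log_likelihood(doubled, tree, m) == pytest.approx(
            2 * log_likelihood(aln, tree, m), abs=1e-7
        )


class TestBranchOptimization:
    def test_two_taxon_recovery(self):
        root = Node()
        root.add(Node("a", 0.1))
        root.add(Node("b", 0.1))
        sim = simulate_on_tree(Tree(root), get_model("LG"), 10000, seed=5)
        start = Tree(root).copy().set_lengths(0.5)
        fitted = optimize_branch_lengths(sim.true_alignment, start, get_model("LG"))
        assert fitted.tree_length() == pytest.approx(0.2, abs=0.02)

    def test_identical_sequences_collapse(self):
        aln = SequenceSet([("a", "ARNDCQ" * 10), ("b", "ARNDCQ" * 10)])
        root = Node()
        root.add(Node("a", 1.0))
        root.add(Node("b", 1.0))
        fitted = optimize_branch_lengths(aln, Tree(root), get_model("LG"))
        assert fitted.tree_length() < 1e-4

    def test_saturated_pair_effectively_stationary(self):
        """For independently originated sequences the estimated path length
        is effectively saturated: the transition matrix at the estimate is
        within noise of the stationary one.  (A chance excess of matches can
        stop the estimate at a large finite value rather than the cap.)"""
        sim = simulate_star_io(2, 2000, 2500.0, seed=9)
        root = Node()
        for lab in sim.unaligned.ids:
            root.add(Node(lab, 1.0))
        fit = optimize_model(sim.true_alignment, Tree(root), sim.models[0])
        # exp(-t_total) < 1%: start-state information is gone
        assert fit.tree.tree_length() >= 4.6

    def test_zero_identity_pair_hits_cap(self):
        """With fewer matches than the stationary expectation the optimum is
        at infinite length; the fit stops at the bound and is flagged."""
        aln = SequenceSet([("a", "AR" * 100), ("b", "ND" * 100)])
        root = Node()
        root.add(Node("a", 1.0))
        root.add(Node("b", 1.0))
        fit = optimize_model(aln, Tree(root), get_model("Poisson"))
        assert fit.tree.tree_length() >= MAX_BRANCH_LENGTH - 1e-3
        assert fit.saturated

    def test_alpha_recovery(self):
        """Gamma-shape recovery on an 8-taxon simulation with alpha = 1."""
        labels = [f"s{i}" for i in range(8)]
        tree = Tree.star(labels, 0.25)
        sim = simulate_on_tree(tree, get_model("LG+G"), 5000, seed=21)
        fit = optimize_model(sim.true_alignment, tree, get_model("LG+G"))
        assert 0.7 <= fit.model.alpha <= 1.4

    def test_freq_floor_for_absent_residue(self):
        aln = SequenceSet([("a", "ARNDARND"), ("b", "ARNDARDN")])
        root = Node()
        root.add(Node("a", 0.1))
        root.add(Node("b", 0.1))
        fit = optimize_model(aln, Tree(root), get_model("Poisson+F"))
        w = AMINO_ACIDS.index("W")
        assert 0 < fit.model.frequencies[w] <= 2e-6
        assert fit.model.frequencies.sum() == pytest.approx(1.0)


class TestTreeSearch:
    def test_nj_recovers_additive_quartet(self):
        #  ((a:1,b:2):1,(c:3,d:4):1)  ->  additive distances
        d = np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, list("abcd"))
        cherries = [
            sorted(leaf.label for leaf in Tree(child).leaves())
            for child in tree.root.children
            if not child.is_leaf
        ]
        assert ["a", "b"] in cherries or ["c", "d"] in cherries
        assert tree.tree_length() == pytest.approx(12.0, abs=1e-9)

    def test_nj_matches_skbio_on_additive_metric(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        # star of three cherries: additive, so NJ reconstructs it exactly
        leaf = rng.random(6) * 2 + 0.1  # terminal lengths
        inner = rng.random(3) * 1 + 0.1  # cherry-to-root lengths
        labels = [f"t{i}" for i in range(6)]
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                ci, cj = i // 2, j // 2
                if ci == cj:
                    d[i, j] = leaf[i] + leaf[j]
                else:
                    d[i, j] = leaf[i] + inner[ci] + inner[cj] + leaf[j]
                d[j, i] = d[i, j]
        expected_length = leaf.sum() + inner.sum()
        ours = nj_tree(d, labels)
        theirs = skbio_nj(DistanceMatrix(d, labels))
        assert ours.tree_length() == pytest.approx(expected_length, abs=1e-9)
        total = sum(
            (n.length or 0.0) for n in theirs.traverse() if not n.is_root()
        )
        assert ours.tree_length() == pytest.approx(total, abs=1e-9)

    def test_quartet_topology_recovery(self):
        tree = Tree.quartet(list("abcd"), 0.2, 0.3)
        sim = simulate_on_tree(tree, get_model("LG"), 2000, seed=3)
        fit = ml_tree(sim.true_alignment, get_model("LG"))
        # the fitted quartet must contain the (a,b) or (c,d) cherry
        cherries = [
            sorted(l.label for l in Tree(c).leaves())
            for c in fit.tree.root.children
            if not c.is_leaf
        ]
        assert ["a", "b"] in cherries or ["c", "d"] in cherries

    def test_nni_improves_on_nj_start(self):
        from ucatest.phylo.optimize import _EncodedAlignment, fit_on_tree
        from ucatest.phylo.search import nni_search
        from ucatest.simulate import simulate_two_groups

        sim = simulate_two_groups("uca", 400, seed=2)
        enc = _EncodedAlignment(sim.true_alignment)
        # deliberately bad start: a wrong caterpillar topology
        ids = enc.ids
        root = Node()
        prev = root
        for lab in ids[:-2]:
            prev.add(Node(lab, 0.2))
            nxt = prev.add(Node(length=0.2))
            prev = nxt
        prev.add(Node(ids[-2], 0.2))
        prev.add(Node(ids[-1], 0.2))
        start = fit_on_tree(enc, Tree(root), get_model("LG"))
        improved = nni_search(enc, start)
        assert improved.loglik >= start.loglik

    def test_ml_tree_n8_at_least_nj(self):
        from ucatest.phylo.optimize import _EncodedAlignment, fit_on_tree
        from ucatest.phylo.search import ml_distance_matrix
        from ucatest.simulate import simulate_two_groups

        sim = simulate_two_groups("uca", 300, seed=4)
        enc = _EncodedAlignment(sim.true_alignment)
        model = get_model("LG")
        d = ml_distance_matrix(enc, model)
        nj_fit = fit_on_tree(enc, nj_tree(d, enc.ids), model)
        full = ml_tree(sim.true_alignment, model)
        assert full.loglik >= nj_fit.loglik - 1e-6


class TestTreeLength:
    def test_star(self):
        assert tree_length(Tree.star("abcd", 2500.0)) == pytest.approx(10000.0)

    def test_zero(self):
        assert tree_length(Tree.star("abc", 0.0)) == 0.0

    def test_root_invariant(self):
        t1 = Tree.quartet(list("abcd"), 0.3, 0.2)
        root = Node()
        cherry = root.add(Node(length=0.2))
        cherry.add(Node("a", 0.3))
        cherry.add(Node("b", 0.3))
        root.add(Node("c", 0.3))
        root.add(Node("d", 0.3))
        assert tree_length(t1) == pytest.approx(tree_length(Tree(root)))
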