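"""Simulator checks: stationary behaviour, seed determinism, indel
bookkeeping and the scenario constructors."""

import numpy as np
import pytest
from scipy import stats as sps

from ucatest.models import get_model
from ucatest.phylo.tree import Node, Tree
from ucatest.simulate import (
    IndelModel,
    TwoGroupConfig,
    sample_frequencies,
    simulate_on_tree,
    simulate_profile,
    simulate_star_io,
    simulate_two_groups,
)


class TestSampleFrequencies:
    def test_valid_and_deterministic(self):
        pi = sample_frequencies(3)
        assert pi.shape == (20,)
        assert np.all(pi > 0)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(pi, sample_frequencies(3))

    def test_symmetric_marginals(self):
        draws = np.array([sample_frequencies(s) for s in range(10000)])
        means = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(means - 0.05) < 3 * se + 1e-4)


class TestSimulateOnTree:
    def test_zero_lengths_identical(self):
        tree = Tree.star("abcd", 0.0)
        sim = simulate_on_tree(tree, get_model("Poisson"), 50, seed=1)
        assert len(set(sim.unaligned.sequences)) == 1

    def test_saturated_star_pairwise_identity(self):
        """At branch length 2500 every pair behaves as independent draws
        from pi: identity matches sum(pi^2) within binomial error."""
        sim = simulate_star_io(2, 10000, 2500.0, seed=2)
        pi = sim.models[0].frequencies
        a, b = (np.frombuffer(s.encode(), dtype="S1") for s in sim.unaligned.sequences)
        obs = float((a == b).mean())
        expect = float((pi**2).sum())
        se = np.sqrt(expect * (1 - expect) / 10000)
        assert abs(obs - expect) < 3 * se

    def test_short_branch_pair_identity(self):
        """Two sequences at small total length T: identity is close to
        exp(-T) + (1-exp(-T))*sum(pi^2) (the two-branch composition of the
        closed-form transition probability)."""
        root = Node()
        root.add(Node("a", 0.01))
        root.add(Node("b", 0.01))
        model = get_model("Poisson+F").with_frequencies(sample_frequencies(5))
        sim = simulate_on_tree(Tree(root), model, 20000, seed=6)
        pi = model.frequencies
        t_total = 0.02
        expect = np.exp(-t_total) + (1 - np.exp(-t_total)) * float((pi**2).sum())
        a, b = sim.unaligned.sequences
        obs = np.mean([x == y for x, y in zip(a, b)])
        se = np.sqrt(expect * (1 - expect) / 20000)
        assert abs(obs - expect) < 4 * se

    def test_stationary_residue_frequencies(self):
        model = get_model("Poisson+F").with_frequencies(sample_frequencies(11))
        root = Node()
        root.add(Node("a", 2500.0))
        root.add(Node("b", 2500.0))
        sim = simulate_on_tree(Tree(root), model, 50000, seed=12)
        from ucatest.models import AMINO_ACIDS

        for seq in sim.unaligned.sequences:
            counts = np.array([seq.count(aa) for aa in AMINO_ACIDS])
            freqs = counts / counts.sum()
            pi = model.frequencies
            se = np.sqrt(pi * (1 - pi) / 50000)
            assert np.all(np.abs(freqs - pi) < 4 * se + 1e-4)

    def test_seed_determinism(self):
        cfg = TwoGroupConfig(indels=IndelModel())
        a = simulate_two_groups("io", 300, seed=9, config=cfg)
        b = simulate_two_groups("io", 300, seed=9, config=cfg)
        assert a.true_alignment.records == b.true_alignment.records

    def test_gap_strip_consistency_with_indels(self):
        cfg = TwoGroupConfig(indels=IndelModel(0.08, 0.08))
        sim = simulate_two_groups("uca", 300, seed=10, config=cfg)
        stripped = [
            (i, s.replace("-", "")) for i, s in sim.true_alignment
        ]
        assert stripped == sim.unaligned.records

    def test_no_indels_exact_length(self):
        sim = simulate_two_groups("io", 250, seed=4)
        assert all(len(s) == 250 for s in sim.unaligned.sequences)
        assert sim.true_alignment.n_columns == 250


class TestStarIo:
    def test_shapes_and_partition(self):
        sim = simulate_star_io(8, 120, 2500.0, seed=5)
        assert len(sim.unaligned) == 8
        assert all(len(s) == 120 for s in sim.unaligned.sequences)
        assert sim.partition == {
            "g1": ["s1", "s2", "s3", "s4"],
            "g2": ["s5", "s6", "s7", "s8"],
        }
        # two collapsed quartets: all internal branches are zero
        internal = [
            n.length
            for n in sim.tree.postorder()
            if not n.is_leaf and n.parent is not None
        ]
        assert internal == [0.0] * len(internal)

    def test_zero_branch_length_all_identical(self):
        sim = simulate_star_io(8, 100, 0.0, seed=5)
        assert len(set(sim.unaligned.sequences)) == 1


class TestProfile:
    def test_no_gaps_and_determinism(self):
        sim = simulate_profile(8, 150, seed=3, frequency_source="per-site")
        assert all("-" not in s for s in sim.unaligned.sequences)
        again = simulate_profile(8, 150, seed=3, frequency_source="per-site")
        assert sim.unaligned.records == again.unaligned.records

    def test_shared_mode_matches_star_column_patterns(self):
        """Shared-frequency profile sampling and the saturated star tree are
        the same i.i.d.-from-pi process: a contingency test on two-sequence
        column patterns does not tell them apart."""
        n_sites = 10000
        prof = simulate_profile(2, n_sites, seed=14, frequency_source="shared")
        star = simulate_star_io(2, n_sites, 2500.0, seed=14)

        def pattern_counts(sim):
            a, b = sim.unaligned.sequences
            idx = {}
            from ucatest.models import AMINO_ACIDS

            code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
            arr = np.array([code[x] * 20 + code[y] for x, y in zip(a, b)])
            return np.bincount(arr, minlength=400)

        c1, c2 = pattern_counts(prof), pattern_counts(star)
        keep = (c1 + c2) >= 5
        chi2, p, _, _ = sps.chi2_contingency(np.vstack([c1[keep], c2[keep]]))
        assert p > 0.01

    def test_invalid_source_rejected(self):
        with pytest.raises(ValueError):
            simulate_profile(4, 10, 0, frequency_source="weird")


class TestTwoGroups:
    def test_io_has_groups_and_default_length(self):
        sim = simulate_two_groups("io", seed=1)
        assert sim.partition == {"B": ["b1", "b2", "b3", "b4"],
                                 "E": ["e1", "e2", "e3", "e4"]}
        assert sim.true_alignment.n_columns >= 6591

    def test_uca_join_zero_is_single_tree(self):
        cfg = TwoGroupConfig(joining_branch=0.0)
        sim = simulate_two_groups("uca", 200, seed=2, config=cfg)
        assert len(sim.trees) == 1
        assert sim.trees[0].n_leaves == 8

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            simulate_two_groups("maybe", 100, 0)


class TestIndelModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            IndelModel(insertion_rate=-0.1)
        with pytest.raises(ValueError):
            IndelModel(length_q=1.5)

    def test_length_cap(self):
        m = IndelModel(length_q=0.99, max_length=20)
        rng = np.random.default_rng(0)
        assert max(m.sample_length(rng) for _ in range(500)) <= 20
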