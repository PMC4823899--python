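"""Aligner and identity-statistic checks: brute-force and Biopython oracles
for the pairwise DP, round-trip and stability properties for the
progressive aligner."""

import numpy as np
import pytest

from ucatest.io_formats import SequenceSet
from ucatest.models import AMINO_ACIDS
from ucatest.msa import (
    BLOSUM62,
    GAP_EXTEND,
    GAP_OPEN,
    average_identity,
    column_identity_scores,
    identity_summary,
    pairwise_align,
    pairwise_identity,
    progressive_align,
    strip_gaps,
)
from ucatest.phylo.tree import Tree
from ucatest.simulate import simulate_on_tree, simulate_star_io


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("AAAA", "AAAA", 1.0),
            ("AAAA", "AATT", 0.5),
            ("A-AA", "AAAA", 1.0),  # gap column excluded from the denominator
            ("A---", "-AAA", 0.0),  # no comparable columns
        ],
    )
    def test_examples(self, s1, s2, expected):
        assert pairwise_identity(s1, s2) == pytest.approx(expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("AA", "AAA")


class TestAverageIdentity:
    def test_identical_sequences(self):
        aln = SequenceSet([(f"s{i}", "ARNDAR") for i in range(4)])
        part = {"g1": ["s0", "s1"], "g2": ["s2", "s3"]}
        for mode in ("all", "within", "between"):
            assert average_identity(aln, mode, part) == pytest.approx(1.0)

    def test_within_minus_between_saturated(self):
        """Two groups of within-identical sequences whose between-group
        residues are independent draws from pi: the identity contrast
        approaches 1 - sum(pi^2)."""
        sim = simulate_star_io(2, 10000, 2500.0, seed=4)
        x, y = sim.unaligned.sequences
        aln = SequenceSet([("a1", x), ("a2", x), ("b1", y), ("b2", y)])
        part = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        summ = identity_summary(aln, part)
        pi = sim.models[0].frequencies
        expect = 1.0 - float((pi**2).sum())
        se = 3.0 * np.sqrt(expect * (1 - expect) / 10000)
        assert summ.within_minus_between == pytest.approx(expect, abs=se)

    def test_degenerate_grouping_rejected(self):
        aln = SequenceSet([("a", "AR"), ("b", "ND")])
        with pytest.raises(ValueError):
            average_identity(aln, "within", {"g1": ["a"], "g2": ["b"]})

    def test_column_scores_match_segment_average(self):
        rng = np.random.default_rng(0)
        rows = [
            ("s%d" % i, "".join(rng.choice(list(AMINO_ACIDS), size=50)))
            for i in range(4)
        ]
        aln = SequenceSet(rows)
        scores = column_identity_scores(aln)
        assert scores.shape == (50,)
        assert average_identity(aln, "all") == pytest.approx(scores.mean())


def brute_force_best_score(s1, s2, gap_open, gap_extend):
    """Enumerate every global alignment with affine gap states."""
    from ucatest.msa import _encode

    a, b = _encode(s1), _encode(s2)
    best = [-np.inf]

    def rec(i, j, state, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, 0, score + BLOSUM62[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, 1, score - (gap_extend if state == 1 else gap_open))
        if j < len(b):
            rec(i, j + 1, 2, score - (gap_extend if state == 2 else gap_open))

    rec(0, 0, 0, 0.0)
    return best[0]


class TestPairwiseAlign:
    def test_identical_gapless_diagonal_score(self):
        res = pairwise_align("ARNDC", "ARNDC")
        assert res.aligned1 == res.aligned2 == "ARNDC"
        expect = sum(BLOSUM62[i, i] for i in range(5))
        assert res.score == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("A", "")

    def test_matches_brute_force_enumeration(self, rng):
        letters = list("ARND")
        for _ in range(25):
            s1 = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            s2 = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            got = pairwise_align(s1, s2)
            assert got.score == pytest.approx(
                brute_force_best_score(s1, s2, GAP_OPEN, GAP_EXTEND)
            )
            # the reported alignment must realise the reported score
            assert got.aligned1.replace("-", "") == s1
            assert got.aligned2.replace("-", "") == s2

    def test_matches_biopython_score(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -GAP_OPEN
        aligner.extend_gap_score = -GAP_EXTEND
        aligner.mode = "global"
        for _ in range(10):
            s1 = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 40)))
            s2 = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 40)))
            assert pairwise_align(s1, s2).score == pytest.approx(
                aligner.score(s1, s2)
            )

    def test_deterministic(self):
        a = pairwise_align("ARNDCQEG", "ARDCQEG")
        b = pairwise_align("ARNDCQEG", "ARDCQEG")
        assert (a.aligned1, a.aligned2) == (b.aligned1, b.aligned2)


class TestProgressiveAlign:
    def test_identical_sequences_no_gaps(self):
        seqs = SequenceSet([(f"s{i}", "ARNDCQEGHI" * 3) for i in range(5)])
        aln = progressive_align(seqs)
        assert aln.n_columns == 30
        assert all("-" not in s for s in aln.sequences)

    def test_round_trip(self):
        from ucatest.simulate import IndelModel, TwoGroupConfig, simulate_two_groups

        sim = simulate_two_groups(
            "uca", 300, seed=8, config=TwoGroupConfig(indels=IndelModel())
        )
        aln = progressive_align(sim.unaligned)
        assert strip_gaps(aln).records == sim.unaligned.records
        assert aln.n_columns >= max(len(s) for s in sim.unaligned.sequences)

    def test_easy_instance_identity_stable(self):
        """Realigning homologous, moderately diverged sequences should not
        change the average identity much."""
        tree = Tree.star([f"s{i}" for i in range(6)], 0.1)
        from ucatest.models import get_model

        sim = simulate_on_tree(tree, get_model("LG"), 400, seed=11)
        true_id = average_identity(sim.true_alignment, "all")
        realigned = progressive_align(sim.unaligned)
        assert abs(average_identity(realigned, "all") - true_id) < 0.05

    def test_input_order_stability(self):
        from ucatest.simulate import simulate_two_groups

        sim = simulate_two_groups("uca", 250, seed=9)
        aln1 = progressive_align(sim.unaligned)
        reordered = SequenceSet(list(reversed(sim.unaligned.records)))
        aln2 = progressive_align(reordered)
        assert abs(aln1.n_columns - aln2.n_columns) <= 0.05 * aln1.n_columns

    def test_saturated_groups_joint_longer(self):
        from ucatest.simulate import IndelModel, TwoGroupConfig, simulate_two_groups

        sim = simulate_two_groups(
            "io", 400, seed=13, config=TwoGroupConfig(indels=IndelModel())
        )
        seps = []
        for name, ids in sim.partition.items():
            seps.append(progressive_align(sim.unaligned.subset(ids)).n_columns)
        joint = progressive_align(sim.unaligned).n_columns
        assert joint > max(seps) * 0.999
        assert joint >= np.mean(seps)

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_align(SequenceSet([("a", "A-R"), ("b", "AR")]))


class TestStripGaps:
    def test_examples(self):
        assert strip_gaps(SequenceSet([("a", "A-R")])).records == [("a", "AR")]
        seqs = SequenceSet([("a", "ARND")])
        assert strip_gaps(seqs).records == seqs.records
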