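"""Sequence simulation under every scenario the toolkit studies.

Three families of data sets:

* ``simulate_star_io`` — the simplified Koonin–Wolf counterexample: eight
  sequences on two quartets whose internal branches are collapsed to zero
  and whose terminal branches are enormous (2500 substitutions), i.e. eight
  independently originated sequences drawn from one shared, randomly
  sampled amino-acid frequency pool.
* ``simulate_profile`` — the profile model itself: every column filled
  i.i.d. from a frequency vector, either one shared vector (equivalent to
  the saturated star tree) or a fresh vector per column.
* ``simulate_two_groups`` — two quartets ("B" and "E") under LG with
  invariant sites, gamma rates and sampled frequencies, either genuinely
  independent (IO) or joined by a finite branch (UCA), optionally with an
  indel process.

All draws go through one ``numpy`` Generator seeded from the caller, so
identical calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io_formats import SequenceSet
from .models import (
    AMINO_ACIDS,
    GAP,
    SubstitutionModel,
    get_model,
    rate_categories,
)
from .phylo.likelihood import ModelPrep
from .phylo.tree import Node, Tree

DEFAULT_TWO_GROUP_LENGTH = 6591  # root sequence length of the B/E scenario


@dataclass(frozen=True)
class IndelModel:
    """Insertion/deletion process riding on the substitution process.

    Rates are events per site per unit branch length (i.e. per expected
    substitution); fragment lengths are geometric with parameter q
    (mean 1/(1-q)), truncated at ``max_length``.
    """

    insertion_rate: float = 0.03
    deletion_rate: float = 0.03
    length_q: float = 0.5
    max_length: int = 20

    def __post_init__(self):
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ValueError("indel rates must be non-negative")
        if not (0.0 < self.length_q < 1.0):
            raise ValueError("geometric parameter q must lie in (0,1)")

    def sample_length(self, rng: np.random.Generator) -> int:
        # geometric over {1,2,...} with P(k) ~ (1-q) q^(k-1)
        k = int(rng.geometric(1.0 - self.length_q))
        return min(k, self.max_length)


@dataclass
class SimResult:
    """A simulated data set with its homology-true alignment."""

    true_alignment: SequenceSet
    unaligned: SequenceSet
    trees: List[Tree]
    models: List[SubstitutionModel]
    partition: Dict[str, List[str]]
    seed: int

    @property
    def tree(self) -> Tree:
        return self.trees[0]

    @property
    def model(self) -> SubstitutionModel:
        return self.models[0]


def sample_frequencies(seed) -> np.ndarray:
    """Twenty independent Uniform(0,1) draws normalised to sum one."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(20)
    return u / u.sum()


def _strip_gaps_string(s: str) -> str:
    return s.replace(GAP, "")


class _Evolver:
    """Evolves sequences down a tree, with optional indels and true-homology
    bookkeeping via a growing master column list."""

    def __init__(self, model: SubstitutionModel, rng: np.random.Generator,
                 indels: Optional[IndelModel]):
        self.prep = ModelPrep(model)
        cats = rate_categories(model)
        self.rates, self.weights = cats.rates, cats.weights
        self.rng = rng
        self.indels = indels
        self.master: List[int] = []
        self.next_col = 0

    def _new_columns(self, n: int, master_pos: int) -> List[int]:
        ids = list(range(self.next_col, self.next_col + n))
        self.next_col += n
        self.master[master_pos:master_pos] = ids
        return ids

    def root_sequence(self, length: int):
        states = self.rng.choice(20, size=length, p=self.prep.pi)
        cats = self.rng.choice(len(self.rates), size=length, p=self.weights)
        cols = self._new_columns(length, len(self.master))
        return list(cols), states.astype(np.int8), cats.astype(np.int8)

    def _substitute(self, states, cats, t: float):
        if t == 0 or len(states) == 0:
            return states.copy()
        pmats = self.prep.transition_matrices(t)  # (K,20,20)
        cum = np.cumsum(pmats, axis=2)
        rows = cum[cats.astype(int), states.astype(int)]  # (L,20)
        u = self.rng.random(len(states))
        new = (rows < u[:, None]).sum(axis=1)
        return np.minimum(new, 19).astype(np.int8)

    def _apply_indels(self, cols, states, cats, t: float):
        ind = self.indels
        states = list(states)
        cats = list(cats)
        elapsed = 0.0
        while True:
            L = len(states)
            total = ind.insertion_rate * (L + 1) + ind.deletion_rate * L
            if total <= 0:
                break
            elapsed += self.rng.exponential(1.0 / total)
            if elapsed >= t:
                break
            if self.rng.random() < ind.insertion_rate * (L + 1) / total:
                k = ind.sample_length(self.rng)
                pos = int(self.rng.integers(0, L + 1))
                if pos == 0:
                    mpos = self.master.index(cols[0]) if cols else len(self.master)
                else:
                    mpos = self.master.index(cols[pos - 1]) + 1
                new_cols = self._new_columns(k, mpos)
                new_states = self.rng.choice(20, size=k, p=self.prep.pi)
                new_cats = self.rng.choice(len(self.rates), size=k, p=self.weights)
                cols[pos:pos] = new_cols
                states[pos:pos] = list(new_states.astype(np.int8))
                cats[pos:pos] = list(new_cats.astype(np.int8))
            else:
                if L == 0:
                    continue
                k = ind.sample_length(self.rng)
                pos = int(self.rng.integers(0, L))
                del cols[pos : pos + k]
                del states[pos : pos + k]
                del cats[pos : pos + k]
        return cols, np.asarray(states, dtype=np.int8), np.asarray(cats, dtype=np.int8)

    def evolve(self, tree: Tree, length: int):
        """Returns dict leaf-label -> (cols, states)."""
        root_cols, root_states, root_cats = self.root_sequence(length)
        out = {}

        def rec(node: Node, cols, states, cats):
            for child in node.children:
                c_states = self._substitute(states, cats, child.length)
                c_cols, c_cats = list(cols), cats
                if self.indels is not None and child.length > 0:
                    c_cols, c_states, c_cats = self._apply_indels(
                        c_cols, c_states, c_cats, child.length
                    )
                if child.is_leaf:
                    out[child.label] = (c_cols, c_states)
                else:
                    rec(child, c_cols, c_states, c_cats)

        rec(tree.root, root_cols, root_states, root_cats)
        return out


def _build_alignment(master: List[int], leaf_data, order: Sequence[str]) -> SequenceSet:
    pos = {c: i for i, c in enumerate(master)}
    n_cols = len(master)
    rows = []
    for label in order:
        cols, states = leaf_data[label]
        row = np.full(n_cols, -1, dtype=np.int16)
        idx = np.fromiter((pos[c] for c in cols), dtype=np.int64, count=len(cols))
        row[idx] = states
        rows.append(
            (label, "".join(GAP if v < 0 else AMINO_ACIDS[v] for v in row))
        )
    return SequenceSet(rows)


def _drop_empty_columns(aln: SequenceSet) -> SequenceSet:
    mat = aln.to_matrix()
    keep = (mat >= 0).any(axis=0)
    return SequenceSet.from_matrix(aln.ids, mat[:, keep])


def simulate_on_tree(
    tree: Tree,
    model: SubstitutionModel,
    length: int,
    indels: Optional[IndelModel] = None,
    seed: int | np.random.Generator = 0,
) -> SimResult:
    """Simulate one alignment down one tree.

    The root sequence is drawn i.i.d. from the model's stationary
    frequencies; each site carries one rate category for the whole tree;
    indel events (if enabled) occur in continuous time along each branch
    with geometric fragment lengths.  Inserted residues are drawn from the
    stationary frequencies.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if tree.n_leaves < 2:
        raise ValueError("tree needs at least two leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = -1 if isinstance(seed, np.random.Generator) else int(seed)
    ev = _Evolver(model, rng, indels)
    leaf_data = ev.evolve(tree, length)
    order = tree.leaf_labels()
    true_aln = _drop_empty_columns(_build_alignment(ev.master, leaf_data, order))
    unaligned = SequenceSet(
        [(i, _strip_gaps_string(s)) for i, s in true_aln]
    )
    labels = list(true_aln.ids)
    return SimResult(
        true_aln, unaligned, [tree], [model], {"all": labels}, seed_val
    )


def _poisson_model_with(pi: np.ndarray) -> SubstitutionModel:
    return get_model("Poisson+F").with_frequencies(pi)


def simulate_star_io(
    n_sequences: int = 8,
    length: int = 1000,
    branch_length: float = 2500.0,
    seed: int = 0,
) -> SimResult:
    """Independent-origins star simulation (the simplified profile model).

    For eight sequences the tree is two quartets with collapsed internal
    branches; otherwise a plain star.  Terminal branches default to 2500 —
    computationally stationary, so the sequences are draws from a common
    pool of amino-acid frequencies sampled uniformly per run.
    """
    if n_sequences < 2:
        raise ValueError("need at least two sequences")
    rng = np.random.default_rng(seed)
    pi = sample_frequencies(rng)
    model = _poisson_model_with(pi)
    labels = [f"s{i+1}" for i in range(n_sequences)]
    if n_sequences == 8:
        tree = Tree.two_collapsed_quartets(labels, branch_length)
    else:
        tree = Tree.star(labels, branch_length)
    res = simulate_on_tree(tree, model, length, indels=None, seed=rng)
    half = n_sequences // 2
    res.partition = {"g1": labels[:half], "g2": labels[half:]}
    res.seed = int(seed)
    return res


def simulate_profile(
    n_sequences: int,
    length: int,
    seed: int = 0,
    frequency_source: str = "per-site",
) -> SimResult:
    """Koonin–Wolf profile sampling: column i filled i.i.d. from pi^[i].

    ``frequency_source="shared"`` uses one vector for every column, which
    gives the same column-pattern distribution as the saturated star tree;
    ``"per-site"`` draws a fresh vector per column.
    """
    if n_sequences < 2 or length < 1:
        raise ValueError("need n >= 2 sequences and length >= 1")
    if frequency_source not in ("shared", "per-site"):
        raise ValueError("frequency_source must be 'shared' or 'per-site'")
    rng = np.random.default_rng(seed)
    labels = [f"s{i+1}" for i in range(n_sequences)]
    if frequency_source == "shared":
        pi = sample_frequencies(rng)
        freqs = np.tile(pi, (length, 1))
    else:
        u = rng.random((length, 20))
        freqs = u / u.sum(axis=1, keepdims=True)
    cum = np.cumsum(freqs, axis=1)
    draws = rng.random((n_sequences, length))
    states = (cum[None, :, :] < draws[:, :, None]).sum(axis=2)
    states = np.minimum(states, 19)
    rows = [
        (lab, "".join(AMINO_ACIDS[v] for v in states[i]))
        for i, lab in enumerate(labels)
    ]
    seqs = SequenceSet(rows)
    model = _poisson_model_with(freqs.mean(axis=0) / freqs.mean(axis=0).sum())
    tree = Tree.star(labels, 2500.0)
    half = n_sequences // 2
    return SimResult(
        seqs, seqs, [tree], [model],
        {"g1": labels[:half], "g2": labels[half:]}, int(seed),
    )


@dataclass(frozen=True)
class TwoGroupConfig:
    """The two-quartet ("B" and "E") scenario.

    The default branch lengths stand in for empirically derived bacterial
    and eukaryotic quartets: B has shorter branches than E.  Both groups
    share one frequency vector sampled per run (the common amino-acid pool)
    and an LG+I+G substitution process.  Under UCA the quartets are joined
    by a finite branch; under IO they are simulated from independent roots.
    """

    b_terminal: float = 0.3
    b_internal: float = 0.15
    e_terminal: float = 0.5
    e_internal: float = 0.25
    joining_branch: float = 0.1
    alpha: float = 1.0
    p_inv: float = 0.1
    indels: Optional[IndelModel] = None


def _two_group_model(pi: np.ndarray, cfg: TwoGroupConfig) -> SubstitutionModel:
    return (
        get_model("LG+I+G+F")
        .with_frequencies(pi)
        .with_parameters(alpha=cfg.alpha, p_inv=cfg.p_inv)
    )


def simulate_two_groups(
    scenario: str,
    length: int = DEFAULT_TWO_GROUP_LENGTH,
    seed: int = 0,
    config: Optional[TwoGroupConfig] = None,
) -> SimResult:
    """Simulate the B/E two-quartet scenario under ``"io"`` or ``"uca"``.

    Under IO the two quartets are simulated independently and their true
    alignments juxtaposed column-by-column (no homology across groups; the
    shorter block is padded with all-gap columns when indels change the
    lengths).  Under UCA a single eight-leaf tree joins the quartets by a
    finite branch.
    """
    if scenario not in ("io", "uca"):
        raise ValueError(f"unknown scenario {scenario!r}; use 'io' or 'uca'")
    cfg = config or TwoGroupConfig()
    rng = np.random.default_rng(seed)
    pi = sample_frequencies(rng)
    model = _two_group_model(pi, cfg)
    b_labels = [f"b{i+1}" for i in range(4)]
    e_labels = [f"e{i+1}" for i in range(4)]
    tree_b = Tree.quartet(b_labels, cfg.b_terminal, cfg.b_internal)
    tree_e = Tree.quartet(e_labels, cfg.e_terminal, cfg.e_internal)
    partition = {"B": b_labels, "E": e_labels}
    if scenario == "io":
        res_b = simulate_on_tree(tree_b, model, length, cfg.indels, rng)
        res_e = simulate_on_tree(tree_e, model, length, cfg.indels, rng)
        mat_b = res_b.true_alignment.to_matrix()
        mat_e = res_e.true_alignment.to_matrix()
        width = max(mat_b.shape[1], mat_e.shape[1])
        juxt = np.full((8, width), -1, dtype=np.int8)
        juxt[:4, : mat_b.shape[1]] = mat_b
        juxt[4:, : mat_e.shape[1]] = mat_e
        true_aln = SequenceSet.from_matrix(b_labels + e_labels, juxt)
        unaligned = SequenceSet(
            [(i, _strip_gaps_string(s)) for i, s in true_aln]
        )
        return SimResult(
            true_aln, unaligned, [tree_b, tree_e], [model, model],
            partition, int(seed),
        )
    # UCA: join the two quartets by a finite internal branch
    root = Node()
    for t, half_len in ((tree_b, cfg.joining_branch / 2.0),
                        (tree_e, cfg.joining_branch / 2.0)):
        sub = t.copy().root
        sub.length = half_len
        root.add(sub)
    joint = Tree(root)
    res = simulate_on_tree(joint, model, length, cfg.indels, rng)
    res.partition = partition
    res.seed = int(seed)
    return res
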