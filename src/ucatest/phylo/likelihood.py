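"""Felsenstein pruning likelihood for amino-acid alignments.

The engine computes log-likelihoods over compressed site patterns, treats
gaps as missing data (a partial-likelihood vector of ones), handles
discrete rate categories (gamma + invariant sites) and guards against
underflow with per-node rescaling.  Outside ("pre-order") partial vectors
give each branch a cheap one-dimensional likelihood profile, which is what
the coordinate-wise branch-length optimiser uses.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

from ..models import (
    MAX_SCALED_LENGTH,
    SATURATION_LENGTH,
    SubstitutionModel,
    build_rate_matrix,
    rate_categories,
)
from .tree import Node, Tree

#: branch-length box constraints; a fit at the upper bound means the branch
#: is saturated (the data cannot distinguish it from an infinite branch)
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 50.0

_LOG_MIN_BL = math.log(MIN_BRANCH_LENGTH)
_LOG_MAX_BL = math.log(MAX_BRANCH_LENGTH)
_TINY = 1e-300


def compress_patterns(matrix: np.ndarray):
    """Unique alignment columns and their multiplicities."""
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    return np.ascontiguousarray(patterns), counts.astype(float)


class ModelPrep:
    """Eigendecomposition of a model's rate matrix plus its rate categories.

    ``P(t) = left @ diag(exp(lambda * t)) @ right`` where the decomposition
    comes from symmetrising Q with sqrt(pi); numerically exact for
    time-reversible models.
    """

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.pi = model.frequencies
        q = build_rate_matrix(model)
        sq = np.sqrt(self.pi)
        b = q * sq[:, None] / sq[None, :]
        b = (b + b.T) / 2.0
        lam, u = np.linalg.eigh(b)
        self.lam = lam
        self.left = u / sq[:, None]
        self.right = u.T * sq[None, :]
        cats = rate_categories(model)
        self.rates = cats.rates
        self.weights = cats.weights

    def replace_rate_parameters(self, model: SubstitutionModel) -> "ModelPrep":
        """Same frequencies/exchangeabilities, new alpha / p_inv."""
        new = object.__new__(ModelPrep)
        new.model = model
        new.pi = self.pi
        new.lam, new.left, new.right = self.lam, self.left, self.right
        cats = rate_categories(model)
        new.rates = cats.rates
        new.weights = cats.weights
        return new

    def transition_matrices(self, t: float) -> np.ndarray:
        """(K, 20, 20) stochastic matrices, one per rate category."""
        s = np.minimum(t * self.rates, MAX_SCALED_LENGTH)
        e = np.exp(self.lam[None, :] * s[:, None])
        p = np.matmul(self.left[None, :, :] * e[:, None, :], self.right)
        np.maximum(p, 0.0, out=p)
        sat = s >= SATURATION_LENGTH
        if np.any(sat):
            p[sat] = self.pi[None, :]
        return p

    def transition_matrices_batch(self, ts: np.ndarray) -> np.ndarray:
        """(G, K, 20, 20) matrices for a vector of branch lengths."""
        s = np.minimum(ts[:, None] * self.rates[None, :], MAX_SCALED_LENGTH)
        e = np.exp(self.lam[None, None, :] * s[:, :, None])  # (G,K,20)
        p = np.matmul(self.left[None, None] * e[:, :, None, :], self.right)
        np.maximum(p, 0.0, out=p)
        sat = s >= SATURATION_LENGTH
        if np.any(sat):
            p[sat] = self.pi[None, :]
        return p


class TreeLikelihood:
    """Pruning likelihood and branch optimisation on one (tree, model, data).

    Parameters
    ----------
    patterns : (n_seq, n_patterns) int8
        Compressed alignment columns; -1 is missing (gap).
    counts : (n_patterns,) float
        Pattern multiplicities.
    row_index : dict label -> row
        Where each tree leaf finds its sequence.
    tree : Tree
        Branch lengths are read at construction and written back by
        ``write_lengths``.
    prep : ModelPrep
    """

    def __init__(self, patterns, counts, row_index: Dict[str, int], tree: Tree,
                 prep: ModelPrep, leaf_cache: Optional[Dict[int, tuple]] = None):
        self.patterns = patterns
        self.counts = counts
        self.prep = prep
        self.tree = tree
        self.nodes: List[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.root_id = self.index[id(tree.root)]
        self.children = [[self.index[id(c)] for c in n.children] for n in self.nodes]
        self.parent = [
            (self.index[id(n.parent)] if n.parent is not None else -1)
            for n in self.nodes
        ]
        self.lengths = np.array([max(n.length, 0.0) for n in self.nodes])
        self.leaf_states = [None] * self.n
        self._leaf_idx = [None] * self.n
        self._leaf_miss = [None] * self.n
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                if node.label not in row_index:
                    raise ValueError(f"leaf {node.label!r} missing from alignment")
                row = row_index[node.label]
                states = patterns[row]
                self.leaf_states[i] = states
                if leaf_cache is not None and row in leaf_cache:
                    self._leaf_idx[i], self._leaf_miss[i] = leaf_cache[row]
                    continue
                miss = states < 0
                idx = np.where(miss, 0, states).astype(np.intp)
                miss = miss if miss.any() else None
                self._leaf_idx[i], self._leaf_miss[i] = idx, miss
                if leaf_cache is not None:
                    leaf_cache[row] = (idx, miss)
        self.npat = patterns.shape[1]
        self._ones_ka = np.ones(len(prep.weights) * 20)
        # caches filled by _forward / _outward
        self._msg = [None] * self.n
        self._msg_scale = [None] * self.n
        self._partial = [None] * self.n
        self._part_scale = [None] * self.n
        self._out = [None] * self.n
        self._out_scale = [None] * self.n

    # -- core recursions ----------------------------------------------

    def _message(self, i: int, t: float):
        """Partial likelihood just above node i, i.e. P(t) applied to the
        node's partial; returns (array (K,20,npat), scale (npat,))."""
        p = self.prep.transition_matrices(t)
        if self.leaf_states[i] is not None:
            m = p[:, :, self._leaf_idx[i]]
            miss = self._leaf_miss[i]
            if miss is not None:
                m[:, :, miss] = 1.0
            return m, None
        return np.matmul(p, self._partial[i]), self._part_scale[i]

    def _forward(self) -> float:
        """Post-order pass; fills message/partial caches, returns LnL."""
        for i in range(self.n):
            if self.leaf_states[i] is not None:
                continue
            kids = self.children[i]
            scale = np.zeros(self.npat)
            msgs = []
            for c in kids:
                m, s = self._message(c, self.lengths[c])
                self._msg[c] = m
                self._msg_scale[c] = s
                msgs.append(m)
                if s is not None:
                    scale += s
            acc = msgs[0] * msgs[1] if len(msgs) > 1 else msgs[0].copy()
            for m in msgs[2:]:
                acc *= m
            top = acc.max(axis=(0, 1))
            np.maximum(top, _TINY, out=top)
            acc /= top[None, None, :]
            scale += np.log(top)
            self._partial[i] = acc
            self._part_scale[i] = scale
        return self._root_loglik()

    def _root_loglik(self) -> float:
        r = self.root_id
        per_cat = np.matmul(self.prep.pi[None, None, :], self._partial[r])[:, 0, :]
        site = self.prep.weights @ per_cat
        np.maximum(site, _TINY, out=site)
        return float(self.counts @ (np.log(site) + self._part_scale[r]))

    def _subtree_closure(self, targets) -> set:
        """Targets plus all their ancestors (nodes whose outside vectors are
        needed to reach the targets)."""
        need = set()
        for i in targets:
            j = i
            while j != -1 and j not in need:
                need.add(j)
                j = self.parent[j]
        return need

    def _outward(self, optimize=None, needed=None):
        """Pre-order pass computing the outside vector of every branch.

        When ``optimize`` is given (a callable taking an edge id), each
        branch is optimised the moment its outside vector is available, and
        its message is refreshed before the sibling vectors are built — a
        proper monotone coordinate-descent sweep: every one-dimensional
        profile is exact for the current parameter vector.  ``needed``
        restricts the pass to the branches of interest and their ancestors.
        """
        r = self.root_id
        K = len(self.prep.weights)
        # the raw (weight-free) outside vector of the root
        self._out[r] = np.broadcast_to(self.prep.pi[None, :, None], (K, 20, 1))
        self._out_scale[r] = np.zeros(self.npat)
        wfold = self.prep.weights[:, None, None]
        for i in range(self.n - 1, -1, -1):  # pre-order = reversed post-order
            if self.leaf_states[i] is not None:
                continue
            if needed is not None and i != r and i not in needed:
                continue
            if i == r:
                through, th_scale = self._out[r], self._out_scale[r]
            else:
                p = self.prep.transition_matrices(self.lengths[i])
                # self._out[i] is weight-folded; unfold for the pass-through
                raw = self._out[i] / wfold
                through = np.matmul(p.transpose(0, 2, 1), raw)
                th_scale = self._out_scale[i]
            kids = self.children[i]
            for c in kids:
                if needed is not None and c not in needed:
                    continue
                o = np.array(through, copy=True)
                if o.shape[2] == 1:
                    o = np.broadcast_to(o, (o.shape[0], 20, self.npat)).copy()
                sc = th_scale.copy()
                for s in kids:
                    if s == c:
                        continue
                    o *= self._msg[s]
                    if self._msg_scale[s] is not None:
                        sc += self._msg_scale[s]
                top = o.max(axis=(0, 1))
                np.maximum(top, _TINY, out=top)
                o /= top[None, None, :]
                sc = sc + np.log(top)
                # fold the category weights in once; _edge_loglik then only
                # needs an elementwise product and a BLAS reduction
                self._out[c] = o * wfold
                self._out_scale[c] = sc
                if optimize is not None and optimize(c):
                    # length changed: refresh the message the siblings and
                    # the subtree below will see
                    m, s = self._message(c, self.lengths[c])
                    self._msg[c] = m
                    self._msg_scale[c] = s

    def _edge_loglik(self, i: int, t: float) -> float:
        m, ms = self._message(i, t)
        m *= self._out[i]
        site = self._ones_ka @ m.reshape(-1, self.npat)
        np.maximum(site, _TINY, out=site)
        ll = np.log(site) + self._out_scale[i]
        if ms is not None:
            ll += ms
        return float(self.counts @ ll)

    def _edge_loglik_batch(self, i: int, ts: np.ndarray) -> np.ndarray:
        """Edge log-likelihood profile over a vector of branch lengths,
        evaluated in one vectorised pass (chunked to bound memory)."""
        out = np.empty(len(ts))
        k20 = len(self.prep.weights) * 20
        # keep the (chunk, K, 20, npat) intermediate under ~80 MB
        chunk = max(1, int(8e6 / (k20 * max(self.npat, 1))))
        for lo in range(0, len(ts), chunk):
            sub = ts[lo : lo + chunk]
            p = self.prep.transition_matrices_batch(sub)  # (g,K,20,20)
            states = self.leaf_states[i]
            if states is not None:
                m = p[:, :, :, self._leaf_idx[i]]
                miss = self._leaf_miss[i]
                if miss is not None:
                    m[:, :, :, miss] = 1.0
                ms = None
            else:
                m = np.matmul(p, self._partial[i][None])
                ms = self._part_scale[i]
            m *= self._out[i][None]
            site = np.matmul(
                self._ones_ka[None, None, :], m.reshape(len(sub), k20, self.npat)
            )[:, 0, :]
            np.maximum(site, _TINY, out=site)
            ll = np.log(site) + self._out_scale[i][None, :]
            if ms is not None:
                ll += ms[None, :]
            out[lo : lo + chunk] = ll @ self.counts
        return out

    # -- public api ----------------------------------------------------

    def loglik(self) -> float:
        return self._forward()

    def optimize_branches(
        self,
        max_sweeps: int = 50,
        tol: float = 1e-3,
        grid_points: int = 7,
        edge_subset: Optional[List[int]] = None,
    ) -> float:
        """Coordinate-wise branch-length optimisation.

        Each sweep runs a pre-order traversal with exact outside vectors;
        every branch is optimised on a log-spaced length grid (one
        vectorised likelihood pass) followed by a parabolic refinement.
        The best visited configuration is kept, so the returned LnL never
        decreases below the starting one.
        """
        edges = (
            set(i for i in range(self.n) if i != self.root_id)
            if edge_subset is None
            else set(i for i in edge_subset if i != self.root_id)
        )
        kids = self.children[self.root_id]
        if len(kids) == 2:
            # a degree-2 root splits one unrooted edge in two; only the sum
            # is identifiable (pulley principle), so fold it into one edge
            # to avoid a flat ridge in the coordinate descent
            a, b = kids
            self.lengths[a] = min(
                self.lengths[a] + self.lengths[b], MAX_BRANCH_LENGTH
            )
            self.lengths[b] = 0.0
            edges.discard(b)
        best_ll = self._forward()
        best_lengths = self.lengths.copy()
        gains = {i: np.inf for i in edges}  # last observed per-edge LnL gain
        state = {"sweep": 0}

        def optimize_edge(i: int) -> bool:
            if i not in edges:
                return False
            if state["sweep"] > 0 and gains[i] < 0.005:
                return False  # converged edge; others will reawaken it
            cur = self._edge_loglik(i, self.lengths[i])
            if self.lengths[i] >= MAX_BRANCH_LENGTH - 1e-9:
                # saturated branch: stay at the bound unless backing off
                # half-way already improves the likelihood
                if self._edge_loglik(i, MAX_BRANCH_LENGTH / 2.0) <= cur:
                    gains[i] = 0.0
                    return False

            # one vectorised pass over a log-spaced grid around the current
            # value, then a parabolic refinement step; an optimum outside
            # the window reawakens the edge next sweep and it re-centres
            centre = math.log(max(self.lengths[i], 1e-6))
            lo = max(_LOG_MIN_BL, centre - 2.5)
            hi = min(_LOG_MAX_BL, centre + 2.5)
            def grid_stage(centre_x, half_width, n_points):
                g_lo = max(_LOG_MIN_BL, centre_x - half_width)
                g_hi = min(_LOG_MAX_BL, centre_x + half_width)
                grid = np.linspace(g_lo, g_hi, n_points)
                lls = self._edge_loglik_batch(i, np.exp(grid))
                g = int(np.argmax(lls))
                bx, bll = float(grid[g]), float(lls[g])
                if 0 < g < n_points - 1:
                    y0, y1, y2 = lls[g - 1], lls[g], lls[g + 1]
                    denom = y0 + y2 - 2.0 * y1
                    if denom < -1e-12:
                        h = grid[1] - grid[0]
                        # vertex of the parabola through the three points
                        x_ref = float(
                            np.clip(grid[g] + 0.5 * h * (y0 - y2) / denom, g_lo, g_hi)
                        )
                        ll_ref = self._edge_loglik(i, math.exp(x_ref))
                        if ll_ref > bll:
                            bx, bll = x_ref, float(ll_ref)
                return bx, bll, grid[1] - grid[0]

            # coarse stage over the window, then a fine stage around its
            # best whenever the edge actually moved (converged edges skip it)
            best_x, best_ll_edge, spacing = grid_stage(
                centre, 2.5, grid_points
            )
            if best_ll_edge - cur > 0.02:
                fine_x, fine_ll, _ = grid_stage(best_x, spacing, 5)
                if fine_ll > best_ll_edge:
                    best_x, best_ll_edge = fine_x, fine_ll
            if best_ll_edge >= cur:
                new = math.exp(best_x)
                if new > 5.0 and new < MAX_BRANCH_LENGTH:
                    # flat saturated plateau: tie-break toward the bound so
                    # the fit is flagged as saturated rather than stopping
                    # at an arbitrary point of the plateau
                    if self._edge_loglik(i, MAX_BRANCH_LENGTH) >= best_ll_edge - 1e-6:
                        new = MAX_BRANCH_LENGTH
                changed = abs(new - self.lengths[i]) > 1e-12
                self.lengths[i] = new
                gains[i] = float(best_ll_edge - cur)
                if gains[i] >= 0.005:
                    # a real move shifts the optima of the adjacent edges
                    for j in self.children[i]:
                        if j in gains:
                            gains[j] = np.inf
                    p = self.parent[i]
                    if p != -1:
                        for j in self.children[p]:
                            if j != i and j in gains:
                                gains[j] = np.inf
                        if p in gains:
                            gains[p] = np.inf
                return changed
            gains[i] = 0.0
            return False

        for sweep in range(max_sweeps):
            state["sweep"] = sweep
            if sweep == 0:
                active = edges
            else:
                active = {i for i in edges if gains[i] >= 0.005}
                if not active:
                    break
            self._outward(
                optimize=optimize_edge, needed=self._subtree_closure(active)
            )
            ll = self._forward()
            if ll > best_ll:
                gain = ll - best_ll
                best_ll = ll
                best_lengths = self.lengths.copy()
                if gain < tol:
                    break
            else:
                break
        self.lengths = best_lengths
        return best_ll

    def write_lengths(self) -> None:
        """Copy the optimised branch lengths back onto the Tree nodes."""
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                node.length = float(self.lengths[i])

    @property
    def saturated_branches(self) -> List[str]:
        out = []
        for i, node in enumerate(self.nodes):
            if node.parent is None:
                continue
            if self.lengths[i] >= MAX_BRANCH_LENGTH - 1e-6:
                out.append(node.label or f"internal_{i}")
        return out


def _check_labels(alignment, tree: Tree):
    labs = tree.leaf_labels()
    if set(labs) != set(alignment.ids):
        raise ValueError("tree leaves and alignment identifiers do not match")


def log_likelihood(alignment, tree: Tree, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an aligned SequenceSet on a tree.

    Columns are compressed to unique patterns first; gaps are marginalised
    as missing data.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    _check_labels(alignment, tree)
    mat = alignment.to_matrix()
    patterns, counts = compress_patterns(mat)
    row_index = {ident: r for r, ident in enumerate(alignment.ids)}
    engine = TreeLikelihood(patterns, counts, row_index, tree, ModelPrep(model))
    return engine.loglik()
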