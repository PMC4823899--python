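"""Tree search: ML pairwise distances, neighbour joining, and ML topology
search (exhaustive for up to five taxa, NJ start plus NNI hill climbing
beyond that)."""

from __future__ import annotations


from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ..models import SubstitutionModel, get_model
from .likelihood import ModelPrep, TreeLikelihood
from .optimize import FitResult, _EncodedAlignment, fit_on_tree
from .tree import Node, Tree, enumerate_topologies

MAX_PAIR_DISTANCE = 10.0
NNI_MAX_ROUNDS = 20
NNI_MIN_GAIN = 1e-2
#: candidates whose raw likelihood falls this far below the incumbent are
#: rejected without local re-optimisation (local sweeps recover far less)
NNI_REJECT_MARGIN = 30.0


def ml_pairwise_distance(
    states_a: np.ndarray,
    states_b: np.ndarray,
    counts: np.ndarray,
    prep: ModelPrep,
) -> float:
    """Maximum-likelihood distance between two encoded sequences, capped."""
    ok = (states_a >= 0) & (states_b >= 0)
    if not ok.any():
        return MAX_PAIR_DISTANCE
    pair = np.bincount(
        (states_a[ok].astype(int) * 20 + states_b[ok].astype(int)),
        weights=counts[ok],
        minlength=400,
    ).reshape(20, 20)

    log_pi = np.log(prep.pi)

    def neg(t: float) -> float:
        p = prep.transition_matrices(t)  # (K,20,20)
        joint = np.einsum("k,kab->ab", prep.weights, p)
        with np.errstate(divide="ignore"):
            lo = np.log(np.maximum(joint, 1e-300)) + log_pi[:, None]
        return -float((pair * lo).sum())

    res = minimize_scalar(
        neg,
        bounds=(1e-8, MAX_PAIR_DISTANCE),
        method="bounded",
        options={"xatol": 1e-3, "maxiter": 16},
    )
    return float(res.x)


_DIST_GRID = np.concatenate([[1e-8], np.geomspace(1e-3, MAX_PAIR_DISTANCE, 26)])


def ml_distance_matrix(encoded: _EncodedAlignment, model: SubstitutionModel):
    """All-pairs ML distances, evaluated jointly on a shared log-spaced
    grid of branch lengths with quadratic refinement around the grid
    optimum (ample accuracy for a neighbour-joining starting tree)."""
    if model.frequencies_estimated:
        from .optimize import empirical_frequencies

        model = model.with_frequencies(
            empirical_frequencies(encoded.patterns, encoded.counts)
        )
    prep = ModelPrep(model)
    n = len(encoded.ids)
    rows = [encoded.patterns[encoded.row_index[i]] for i in encoded.ids]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    c = np.zeros((len(pairs), 400))
    for k, (i, j) in enumerate(pairs):
        ok = (rows[i] >= 0) & (rows[j] >= 0)
        if ok.any():
            c[k] = np.bincount(
                rows[i][ok].astype(int) * 20 + rows[j][ok].astype(int),
                weights=encoded.counts[ok],
                minlength=400,
            )
    log_pi = np.log(prep.pi)
    ll_grid = np.empty((len(pairs), len(_DIST_GRID)))
    for g, t in enumerate(_DIST_GRID):
        p = prep.transition_matrices(t)
        joint = np.einsum("k,kab->ab", prep.weights, p)
        lo = np.log(np.maximum(joint, 1e-300)) + log_pi[:, None]
        ll_grid[:, g] = c @ lo.ravel()
    logt = np.log(_DIST_GRID)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if not c[k].any():
            d[i, j] = d[j, i] = MAX_PAIR_DISTANCE
            continue
        g = int(np.argmax(ll_grid[k]))
        if 0 < g < len(_DIST_GRID) - 1:
            x0, x1, x2 = logt[g - 1 : g + 2]
            y0, y1, y2 = ll_grid[k, g - 1 : g + 2]
            denom = (y0 - y1) * (x2 - x1) + (y2 - y1) * (x1 - x0)
            if denom < 0:
                shift = 0.5 * (
                    (y0 - y1) * (x2 - x1) ** 2 - (y2 - y1) * (x1 - x0) ** 2
                ) / denom
                t_hat = float(np.exp(np.clip(x1 + shift, logt[0], logt[-1])))
            else:
                t_hat = float(_DIST_GRID[g])
        else:
            t_hat = float(_DIST_GRID[g])
        d[i, j] = d[j, i] = min(t_hat, MAX_PAIR_DISTANCE)
    return d


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> Tree:
    """Neighbour joining with deterministic tie-breaking (lowest row, column
    index wins) and non-negative branch lengths; the final three clusters
    are joined at a trifurcating root."""
    d = np.array(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels do not match")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes: List[Node] = [Node(lab) for lab in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        idx = int(np.argmin(q))  # first minimum in row-major order
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[ai].length, nodes[aj].length = li, lj
        parent.add(nodes[ai])
        parent.add(nodes[aj])
        # distances from the new node
        new_d = 0.5 * (d[ai, :] + d[aj, :] - d[ai, aj])
        d = np.vstack([d, new_d])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]
    root = Node()
    sub = d[np.ix_(active, active)]
    # three-cluster closing lengths
    for pos, a in enumerate(active):
        others = [p for p in range(3) if p != pos]
        nodes[a].length = max(
            0.5 * (sub[pos, others[0]] + sub[pos, others[1]] - sub[others[0], others[1]]),
            0.0,
        )
        root.add(nodes[a])
    return Tree(root)


def _local_edge_ids(engine: TreeLikelihood, tree: Tree, swapped: Node) -> List[int]:
    """Branches adjacent to an NNI swap, by engine node id."""
    ids = set()
    v = swapped
    for node in [v] + v.children + ([v.parent] if v.parent else []):
        if node is None:
            continue
        i = engine.index.get(id(node))
        if i is not None and i != engine.root_id:
            ids.add(i)
        for c in node.children:
            j = engine.index.get(id(c))
            if j is not None:
                ids.add(j)
    return sorted(ids)


def _nni_candidates(tree: Tree):
    """Yield (candidate_tree, swapped_node_in_candidate) for all NNI moves."""
    nodes = list(tree.postorder())
    for idx, v in enumerate(nodes):
        if v.parent is None or v.is_leaf:
            continue
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        if not siblings:
            continue
        for ci in range(min(2, len(v.children))):
            cand = tree.copy()
            cnodes = list(cand.postorder())
            v2 = cnodes[idx]
            u2 = v2.parent
            s2 = [c for c in u2.children if c is not v2][0]
            c2 = v2.children[ci]
            u2.children[u2.children.index(s2)] = c2
            v2.children[ci] = s2
            c2.parent, s2.parent = u2, v2
            yield cand, v2


def nni_search(
    encoded: _EncodedAlignment,
    start: FitResult,
    max_rounds: int = NNI_MAX_ROUNDS,
) -> FitResult:
    """First-improvement NNI hill climbing.

    Candidates are scored by re-optimising only the branches around the
    swapped edge (model parameters frozen at the incumbent fit); an accepted
    swap is followed by full branch sweeps.
    """
    current_tree = start.tree.copy()
    current_ll = start.loglik
    prep = ModelPrep(start.model)
    changed = False
    leaf_cache: dict = {}
    for _ in range(max_rounds):
        improved = False
        for cand, swapped in _nni_candidates(current_tree):
            engine = TreeLikelihood(
                encoded.patterns, encoded.counts, encoded.row_index, cand, prep,
                leaf_cache=leaf_cache,
            )
            # cheap screens: raw likelihood first; clearly hopeless moves
            # are dropped, near-ties get a one-dimensional re-optimisation
            # of the swapped edge plus the re-arranged cherry's branches
            ll = engine.loglik()
            if ll < current_ll - NNI_REJECT_MARGIN:
                continue
            if ll <= current_ll + NNI_MIN_GAIN:
                centre = engine.index[id(swapped)]
                local = [centre] + [
                    engine.index[id(c)] for c in swapped.children
                ]
                ll = engine.optimize_branches(
                    max_sweeps=1, edge_subset=local, grid_points=7
                )
            if ll > current_ll + NNI_MIN_GAIN:
                local = _local_edge_ids(engine, cand, swapped)
                engine.optimize_branches(
                    max_sweeps=1, edge_subset=local, grid_points=7
                )
                ll = engine.optimize_branches(max_sweeps=10)
                engine.write_lengths()
                current_tree, current_ll = cand, ll
                improved = changed = True
                break
        if not improved:
            break
    if not changed:
        return start
    return FitResult(
        current_tree,
        start.model,
        current_ll,
        start.n_sites,
        saturated=[],
        converged=start.converged,
    )


def ml_tree(
    alignment,
    model: SubstitutionModel,
    encoded: Optional[_EncodedAlignment] = None,
) -> FitResult:
    """Maximum-likelihood tree for an aligned SequenceSet under one model.

    Exhaustive topology enumeration up to five taxa (three topologies for a
    quartet); neighbour joining on ML distances followed by NNI hill
    climbing for larger sets.  Two taxa reduce to a single-branch fit.
    """
    if isinstance(model, str):
        model = get_model(model)
    if encoded is None:
        encoded = _EncodedAlignment(alignment)
    n = len(encoded.ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    if n == 2:
        root = Node()
        root.add(Node(encoded.ids[0], 0.05))
        root.add(Node(encoded.ids[1], 0.05))
        return fit_on_tree(encoded, Tree(root), model)
    if n <= 5:
        # start every candidate topology at half the mean pairwise distance:
        # saturated data would otherwise have to climb from a poor short-
        # branch start on every topology
        d = ml_distance_matrix(encoded, model)
        start_len = max(
            float(d[np.triu_indices(n, 1)].mean()) / 2.0, 0.05
        )
        best = None
        for topo in enumerate_topologies(encoded.ids):
            topo.set_lengths(start_len)
            fit = fit_on_tree(encoded, topo, model)
            if best is None or fit.loglik > best.loglik:
                best = fit
        return best
    d = ml_distance_matrix(encoded, model)
    start_tree = nj_tree(d, encoded.ids)
    fit = fit_on_tree(encoded, start_tree, model)
    fit2 = nni_search(encoded, fit)
    if fit2 is not fit:
        # re-optimise free model parameters on the accepted topology
        fit2 = fit_on_tree(encoded, fit2.tree, fit2.model)
        if fit2.loglik < fit.loglik:
            fit2 = fit
    return fit2


def tree_length(tree: Tree) -> float:
    """Sum of branch lengths; the tree-length permutation statistic."""
    return tree.tree_length()
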