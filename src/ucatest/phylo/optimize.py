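"""Branch-length and model-parameter optimisation.

The fitting loop follows the ProtTest/phyml conventions the field's model
selection runs rely on: +F frequencies are set once by counting (floored at
1e-6 and renormalised), gamma shape and the invariant proportion are
optimised by bounded one-dimensional searches interleaved with coordinate
branch-length sweeps, and the free-parameter count k of a fit is the
model's parameter count plus one per branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from ..models import SubstitutionModel, parameter_count
from .likelihood import ModelPrep, TreeLikelihood, compress_patterns
from .tree import Tree

FREQ_FLOOR = 1e-6
# wide upper bound: at alpha ~ 1e4 the discrete-gamma rates are within 1% of
# one, so the boundary effectively recovers the rate-homogeneous model
ALPHA_BOUNDS = (0.02, 1.0e4)
P_INV_BOUNDS = (1e-6, 0.9)


@dataclass
class FitResult:
    """A maximum-likelihood fit of one model on one tree."""

    tree: Tree
    model: SubstitutionModel
    loglik: float
    n_sites: int
    saturated: List[str] = field(default_factory=list)
    converged: bool = True

    @property
    def k(self) -> int:
        """Free parameters: substitution-model parameters + branch lengths.
        Topology is not counted (ProtTest/phyml convention)."""
        return parameter_count(self.model) + self.tree.n_branches

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n_sites) - 2.0 * self.loglik

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FitResult({self.model.name}, LnL={self.loglik:.3f}, k={self.k}, "
            f"N={self.n_sites}, AIC={self.aic:.3f})"
        )


def empirical_frequencies(patterns: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Observed residue frequencies (gaps excluded), floored and renormalised."""
    w = np.broadcast_to(counts, patterns.shape)
    mask = patterns >= 0
    freq = np.bincount(patterns[mask].astype(int), weights=w[mask], minlength=20)
    if freq.sum() == 0:
        freq = np.ones(20)
    freq = freq / freq.sum()
    freq = np.maximum(freq, FREQ_FLOOR)
    return freq / freq.sum()


class _EncodedAlignment:
    """Compressed column patterns shared across fits of the same data."""

    def __init__(self, alignment):
        if len(alignment) == 0:
            raise ValueError("empty alignment")
        mat = alignment.to_matrix()
        self.patterns, self.counts = compress_patterns(mat)
        self.row_index: Dict[str, int] = {
            ident: r for r, ident in enumerate(alignment.ids)
        }
        self.n_sites = mat.shape[1]
        self.ids = list(alignment.ids)


def fit_on_tree(
    encoded: _EncodedAlignment,
    tree: Tree,
    model: SubstitutionModel,
    max_rounds: int = 2,
    sweep_kwargs: Optional[dict] = None,
    tol: float = 1e-3,
) -> FitResult:
    """Optimise branch lengths and free model parameters on a fixed topology."""
    tree = tree.copy()
    sweep_kwargs = dict(sweep_kwargs or {})
    if model.frequencies_estimated:
        model = model.with_frequencies(
            empirical_frequencies(encoded.patterns, encoded.counts)
        )
    prep = ModelPrep(model)
    engine = TreeLikelihood(
        encoded.patterns, encoded.counts, encoded.row_index, tree, prep
    )
    input_lengths = engine.lengths.copy()
    ll = engine.optimize_branches(**sweep_kwargs)
    converged = True
    if model.alpha is not None or model.p_inv is not None:
        for round_ in range(max_rounds):
            previous = ll
            if model.alpha is not None:
                model, ll = _optimize_rate_parameter(engine, model, "alpha")
            if model.p_inv is not None:
                model, ll = _optimize_rate_parameter(engine, model, "p_inv")
            ll = engine.optimize_branches(**sweep_kwargs)
            if ll - previous < tol:
                break
        else:
            converged = False
        if model.alpha is not None:
            # guard against an interior local optimum of the joint
            # (alpha, branch-lengths) surface: screen the near-homogeneous
            # boundary (which nests the rate-constant model) at the input
            # branch lengths — in a model-selection chain these are the
            # previous, simpler model's optimum — and polish only if it wins
            interior_model = model
            interior_lengths = engine.lengths.copy()
            boundary = model.with_parameters(alpha=ALPHA_BOUNDS[1])
            if model.p_inv is not None:
                boundary = boundary.with_parameters(p_inv=P_INV_BOUNDS[0])
            engine.prep = engine.prep.replace_rate_parameters(boundary)
            engine.lengths = input_lengths.copy()
            if engine.loglik() > ll - 2.0:
                ll_boundary = engine.optimize_branches(**sweep_kwargs)
            else:
                ll_boundary = -np.inf
            if ll_boundary > ll:
                model, ll = boundary, ll_boundary
                if boundary.p_inv is not None:
                    model, ll = _optimize_rate_parameter(engine, model, "p_inv")
            else:
                engine.lengths = interior_lengths
                engine.prep = engine.prep.replace_rate_parameters(interior_model)
                model = interior_model
    engine.write_lengths()
    return FitResult(
        tree,
        model,
        float(ll),
        encoded.n_sites,
        saturated=engine.saturated_branches,
        converged=converged,
    )


def _optimize_rate_parameter(engine: TreeLikelihood, model, which: str):
    base_prep = engine.prep

    def set_value(x: float):
        if which == "alpha":
            m = model.with_parameters(alpha=math.exp(x))
        else:
            m = model.with_parameters(p_inv=x)
        engine.prep = base_prep.replace_rate_parameters(m)
        return m

    def neg(x: float) -> float:
        set_value(x)
        return -engine.loglik()

    if which == "alpha":
        bounds = (math.log(ALPHA_BOUNDS[0]), math.log(ALPHA_BOUNDS[1]))
    else:
        bounds = P_INV_BOUNDS
    res = minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": 5e-3, "maxiter": 8}
    )
    # bounded Brent never probes the boundaries; for alpha especially the ML
    # optimum often sits at the no-heterogeneity end
    best_x, best_val = float(res.x), float(res.fun)
    for x in bounds:
        v = neg(x)
        if v < best_val:
            best_x, best_val = float(x), float(v)
    model = set_value(best_x)
    return model, float(-best_val)


def optimize_branch_lengths(alignment, tree: Tree, model: SubstitutionModel) -> Tree:
    """Coordinate-wise branch-length optimisation; model parameters fixed."""
    encoded = _EncodedAlignment(alignment)
    tree = tree.copy()
    engine = TreeLikelihood(
        encoded.patterns, encoded.counts, encoded.row_index, tree, ModelPrep(model)
    )
    engine.optimize_branches()
    engine.write_lengths()
    return tree


def optimize_model(alignment, tree: Tree, model: SubstitutionModel) -> FitResult:
    """Fit branch lengths plus the model's free parameters (+F by counting,
    alpha and p_inv by bounded search) on a fixed topology."""
    return fit_on_tree(_EncodedAlignment(alignment), tree, model)
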