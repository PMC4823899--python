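"""Amino-acid substitution models and transition probabilities.

The model zoo is the one a protein model-selection run needs: the Poisson
model (equal exchangeabilities; its transition probability has the closed
form ``exp(-t)*delta(a=b) + (1-exp(-t))*pi_b``), optionally with estimated
frequencies (+F), and the empirical LG matrix with invariant sites (+I),
discrete-gamma rate heterogeneity (+G) and estimated frequencies (+F).

All rate matrices are normalised to one expected substitution per site per
unit branch length, so branch lengths are in expected substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import linalg
from scipy.special import gammainc, gammaincinv

from ._lg_data import LG_EXCHANGEABILITIES_LOWER, LG_FREQUENCIES

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
GAP = "-"

#: beyond this scaled length the transition matrix is numerically stationary
SATURATION_LENGTH = 50.0
#: scaled branch lengths are capped here before exponentiation
MAX_SCALED_LENGTH = 1.0e4

MODEL_NAMES = ("Poisson", "Poisson+F", "LG", "LG+G", "LG+I+G", "LG+I+G+F")


def _lg_exchangeability_matrix() -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    # column-major lower triangle: (2,1),(3,1),...,(20,1),(3,2),...
    for j in range(N_STATES - 1):
        for i in range(j + 1, N_STATES):
            s[i, j] = s[j, i] = LG_EXCHANGEABILITIES_LOWER[k]
            k += 1
    return s


@dataclass(frozen=True)
class RateCategories:
    """Discrete site-rate categories with weights summing to one."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1:
            raise ValueError("rates and weights must be 1-D and equally long")
        if np.any(r < 0) or np.any(w < 0):
            raise ValueError("rates and weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    @property
    def mean_rate(self) -> float:
        return float(self.rates @ self.weights)


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible amino-acid model in GTR form.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"LG+I+G+F"``.
    exchangeabilities : (20, 20) ndarray
        Symmetric, non-negative, zero diagonal.
    frequencies : (20,) ndarray
        Equilibrium frequencies, positive, summing to one.
    alpha : float or None
        Gamma shape for across-site rate heterogeneity (+G); None disables.
    p_inv : float or None
        Proportion of invariant sites (+I); None disables.
    frequencies_estimated : bool
        Whether frequencies count as free parameters (+F) and are set from
        the data when fitting.
    n_rate_categories : int
        Number of discrete gamma categories (when alpha is present).
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: Optional[float] = None
    p_inv: Optional[float] = None
    frequencies_estimated: bool = False
    n_rate_categories: int = 4

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(s < 0) or np.any(np.diag(s) != 0):
            raise ValueError("exchangeabilities must be non-negative with zero diagonal")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive numbers")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.p_inv is not None and not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "frequencies", pi)

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        return replace(self, frequencies=np.asarray(pi, dtype=float))

    def with_parameters(self, alpha=None, p_inv=None) -> "SubstitutionModel":
        kw = {}
        if alpha is not None:
            kw["alpha"] = float(alpha)
        if p_inv is not None:
            kw["p_inv"] = float(p_inv)
        return replace(self, **kw)


def get_model(name: str) -> SubstitutionModel:
    """Return a named model with default parameter values.

    Optimisable parameters start at alpha=1.0 and p_inv=0.1.
    """
    uniform = np.full(N_STATES, 1.0 / N_STATES)
    poisson_s = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    lg_s = _lg_exchangeability_matrix()
    lg_pi = np.asarray(LG_FREQUENCIES, dtype=float)
    lg_pi = lg_pi / lg_pi.sum()
    if name == "Poisson":
        return SubstitutionModel(name, poisson_s, uniform)
    if name == "Poisson+F":
        return SubstitutionModel(name, poisson_s, uniform, frequencies_estimated=True)
    if name == "LG":
        return SubstitutionModel(name, lg_s, lg_pi)
    if name == "LG+G":
        return SubstitutionModel(name, lg_s, lg_pi, alpha=1.0)
    if name == "LG+I+G":
        return SubstitutionModel(name, lg_s, lg_pi, alpha=1.0, p_inv=0.1)
    if name == "LG+I+G+F":
        return SubstitutionModel(
            name, lg_s, lg_pi, alpha=1.0, p_inv=0.1, frequencies_estimated=True
        )
    raise ValueError(f"unknown model name: {name!r}")


def poisson_transition(a: int, b: int, t: float, pi: np.ndarray) -> float:
    """Closed-form Poisson transition probability P(b | a, t).

    ``exp(-t)`` is the probability that no substitution event replaced the
    site; otherwise the new state is an independent draw from pi.  At
    ``t = inf`` the initial state is forgotten entirely and the probability
    is just ``pi_b`` — the independent-origins regime.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    pi = np.asarray(pi, dtype=float)
    decay = 0.0 if np.isinf(t) else float(np.exp(-t))
    return decay * (1.0 if a == b else 0.0) + (1.0 - decay) * float(pi[b])


def pair_joint_probability(a: int, b: int, t: float, pi: np.ndarray) -> float:
    """Joint probability of observing states (a, b) in two sequences
    separated by total path length t under the Poisson model at
    stationarity.

    Same state: ``exp(-t)*pi_a + pi_a^2*(1-exp(-t))``; different states:
    ``pi_a*pi_b*(1-exp(-t))``.  At ``t = inf`` these reduce to ``pi_a^2``
    and ``pi_a*pi_b`` — two independent draws from pi.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    pi = np.asarray(pi, dtype=float)
    decay = 0.0 if np.isinf(t) else float(np.exp(-t))
    if a == b:
        return decay * float(pi[a]) + float(pi[a]) ** 2 * (1.0 - decay)
    return float(pi[a]) * float(pi[b]) * (1.0 - decay)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """GTR-form rate matrix Q with unit mean rate.

    ``Q_ab = s_ab * pi_b`` off-diagonal, diagonal set by zero row sums.

    Empirical-matrix models are rescaled to unit mean substitution rate
    (``-sum_a pi_a Q_aa = 1``).  The Poisson family (all exchangeabilities
    equal) instead keeps the closed-form convention ``Q_ab = pi_b - delta``:
    one replacement *event* per unit time, where an event may redraw the
    same residue, so that ``expm(Q t)`` equals
    ``exp(-t)*delta + (1-exp(-t))*pi_b`` exactly.
    """
    pi = model.frequencies
    s = model.exchangeabilities
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    off = s[~np.eye(N_STATES, dtype=bool)]
    if np.allclose(off, off[0]):
        # Poisson family: Q = s0 * (pi_b - delta); scale events to rate 1
        q = q / off[0]
        np.fill_diagonal(q, -(1.0 - pi))
        return q
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -float(pi @ np.diag(q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return q / scale


def stationary_frequencies(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (left null vector)."""
    w, v = np.linalg.eig(q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix(q: np.ndarray, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t * rate) = expm(Q * t * rate), with a stationary shortcut.

    Scaled lengths at or beyond ``SATURATION_LENGTH`` return the stationary
    matrix (every row equals pi); the exponent is capped at
    ``MAX_SCALED_LENGTH`` regardless.
    """
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    s = min(t * rate, MAX_SCALED_LENGTH)
    if s >= SATURATION_LENGTH:
        pi = stationary_frequencies(q)
        return np.tile(pi, (N_STATES, 1))
    return linalg.expm(q * s)


def discrete_gamma(alpha: float, n_categories: int = 4) -> RateCategories:
    """Mean-rate discretisation of a Gamma(alpha, 1/alpha) distribution.

    K equal-weight categories; each category's rate is the conditional mean
    of its quantile bin, so the weighted mean rate is exactly one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    k = int(n_categories)
    if k == 1:
        return RateCategories(np.array([1.0]), np.array([1.0]))
    # bin boundaries at quantiles i/K of Gamma(shape=alpha, scale=1/alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X | bin] * (1/K) = P(alpha+1, alpha*b_hi) - P(alpha+1, alpha*b_lo)
    cum_hi = np.where(np.isinf(upper), 1.0, gammainc(alpha + 1, alpha * upper))
    cum_lo = gammainc(alpha + 1, alpha * lower)
    rates = k * (cum_hi - cum_lo)
    rates = rates / (rates.mean())  # exact unit mean
    return RateCategories(rates, np.full(k, 1.0 / k))


def rate_categories(model: SubstitutionModel) -> RateCategories:
    """The model's site-rate categories with p_inv folded in.

    Invariant sites become an extra zero-rate category of weight p_inv; the
    gamma categories are reweighted by (1 - p_inv) and rescaled so the
    overall mean rate stays one.
    """
    if model.alpha is not None:
        base = discrete_gamma(model.alpha, model.n_rate_categories)
    else:
        base = RateCategories(np.array([1.0]), np.array([1.0]))
    if model.p_inv is None:
        return base
    p = model.p_inv
    rates = np.concatenate([[0.0], base.rates / (1.0 - p)])
    weights = np.concatenate([[p], base.weights * (1.0 - p)])
    return RateCategories(rates, weights)


def parameter_count(model: SubstitutionModel) -> int:
    """Free-parameter contribution of the substitution model to k.

    Estimated frequencies contribute 19 (a point on the 20-simplex), alpha
    and p_inv one each; fixed empirical exchangeabilities (LG) and the
    equal-rates Poisson matrix contribute nothing.
    """
    k = 0
    if model.frequencies_estimated:
        k += N_STATES - 1
    if model.alpha is not None:
        k += 1
    if model.p_inv is not None:
        k += 1
    return k
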