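"""Substitution-model invariants: the closed-form Poisson transition
probability, GTR construction, discrete-gamma rates and parameter counts."""

import numpy as np
import pytest
from scipy.linalg import expm

from ucatest.models import (
    RateCategories,
    build_rate_matrix,
    discrete_gamma,
    get_model,
    pair_joint_probability,
    parameter_count,
    poisson_transition,
    rate_categories,
    transition_matrix,
)


@pytest.fixture(scope="module")
def random_pi():
    rng = np.random.default_rng(7)
    pi = rng.random(20)
    return pi / pi.sum()


class TestPoissonClosedForm:
    def test_identity_at_zero(self, random_pi):
        assert poisson_transition(3, 3, 0.0, random_pi) == pytest.approx(1.0)
        assert poisson_transition(3, 5, 0.0, random_pi) == pytest.approx(0.0)

    def test_infinite_branch_forgets_start(self, random_pi):
        for b in (0, 7, 19):
            assert poisson_transition(2, b, np.inf, random_pi) == pytest.approx(
                random_pi[b]
            )

    def test_uniform_numeric_value(self):
        pi = np.full(20, 0.05)
        expect = np.exp(-1) + (1 - np.exp(-1)) / 20
        assert poisson_transition(4, 4, 1.0, pi) == pytest.approx(expect, abs=1e-12)

    def test_rows_sum_to_one(self, random_pi):
        for t in (0.0, 0.3, 2.0, np.inf):
            total = sum(poisson_transition(6, b, t, random_pi) for b in range(20))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_branch_rejected(self, random_pi):
        with pytest.raises(ValueError):
            poisson_transition(0, 0, -1.0, random_pi)

    def test_matches_matrix_exponential(self, random_pi):
        """Closed form equals expm of the Poisson rate matrix to 1e-10."""
        model = get_model("Poisson+F").with_frequencies(random_pi)
        q = build_rate_matrix(model)
        for t in (0.01, 0.1, 0.5, 1.0, 3.0, 10.0, 30.0):
            p = expm(q * t)
            closed = np.array(
                [
                    [poisson_transition(a, b, t, random_pi) for b in range(20)]
                    for a in range(20)
                ]
            )
            assert np.abs(p - closed).max() < 1e-10


class TestPairJoint:
    def test_zero_branch_is_one_draw(self, random_pi):
        assert pair_joint_probability(4, 4, 0.0, random_pi) == pytest.approx(
            random_pi[4]
        )
        assert pair_joint_probability(4, 5, 0.0, random_pi) == pytest.approx(0.0)

    def test_infinite_branch_independent_draws(self, random_pi):
        assert pair_joint_probability(4, 4, np.inf, random_pi) == pytest.approx(
            random_pi[4] ** 2
        )
        assert pair_joint_probability(4, 9, np.inf, random_pi) == pytest.approx(
            random_pi[4] * random_pi[9]
        )

    @pytest.mark.parametrize("t", [0.0, 0.2, 1.7, np.inf])
    def test_normalisation(self, t, random_pi):
        total = sum(
            pair_joint_probability(a, b, t, random_pi)
            for a in range(20)
            for b in range(20)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestRateMatrix:
    @pytest.mark.parametrize("name", ["Poisson", "LG", "LG+I+G+F"])
    def test_generator_properties(self, name):
        model = get_model(name)
        q = build_rate_matrix(model)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        assert np.abs(model.frequencies @ q).max() < 1e-12  # stationarity

    def test_lg_unit_mean_rate(self):
        model = get_model("LG")
        q = build_rate_matrix(model)
        assert -(model.frequencies @ np.diag(q)) == pytest.approx(1.0)

    @pytest.mark.parametrize("name", ["Poisson", "LG"])
    def test_transition_matrix_properties(self, name):
        model = get_model(name)
        q = build_rate_matrix(model)
        pi = model.frequencies
        assert np.abs(transition_matrix(q, 0.0) - np.eye(20)).max() < 1e-12
        for t in (0.1, 1.0, 10.0):
            p = transition_matrix(q, t)
            assert np.abs(p.sum(axis=1) - 1).max() < 1e-10
            assert np.abs(pi @ p - pi).max() < 1e-10
            # detailed balance of the time-reversible construction
            flux = pi[:, None] * p
            assert np.abs(flux - flux.T).max() < 1e-10

    def test_chapman_kolmogorov(self):
        q = build_rate_matrix(get_model("LG"))
        rng = np.random.default_rng(3)
        for _ in range(3):
            t1, t2 = rng.random(2) * 2
            lhs = transition_matrix(q, t1) @ transition_matrix(q, t2)
            assert np.abs(lhs - transition_matrix(q, t1 + t2)).max() < 1e-9

    def test_huge_length_is_stationary(self):
        """A branch of 2500 is computationally at the equilibrium: every row
        of P equals the stationary frequencies."""
        model = get_model("LG")
        p = transition_matrix(build_rate_matrix(model), 2500.0)
        assert np.abs(p - model.frequencies[None, :]).max() < 1e-10

    def test_negative_arguments_rejected(self):
        q = build_rate_matrix(get_model("LG"))
        with pytest.raises(ValueError):
            transition_matrix(q, -0.5)
        with pytest.raises(ValueError):
            transition_matrix(q, 0.5, rate=-1.0)


class TestRateCategories:
    def test_single_category(self):
        cats = discrete_gamma(0.7, 1)
        assert cats.rates.tolist() == [1.0]

    def test_huge_alpha_vanishing_heterogeneity(self):
        cats = discrete_gamma(1e6, 4)
        assert np.abs(cats.rates - 1).max() < 1e-2

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 5.0])
    def test_unit_mean(self, alpha):
        cats = discrete_gamma(alpha, 4)
        assert cats.mean_rate == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(cats.rates) > 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            discrete_gamma(-1.0, 4)
        with pytest.raises(ValueError):
            discrete_gamma(1.0, 0)

    def test_p_inv_folding(self):
        model = get_model("LG+I+G").with_parameters(alpha=0.8, p_inv=0.25)
        cats = rate_categories(model)
        assert cats.rates[0] == 0.0
        assert cats.weights[0] == pytest.approx(0.25)
        assert cats.mean_rate == pytest.approx(1.0, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RateCategories(np.array([1.0, 1.0]), np.array([0.6, 0.6]))


class TestParameterCount:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Poisson", 0),
            ("Poisson+F", 19),
            ("LG", 0),
            ("LG+G", 1),
            ("LG+I+G", 2),
            ("LG+I+G+F", 21),
        ],
    )
    def test_counts(self, name, expected):
        assert parameter_count(get_model(name)) == expected
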