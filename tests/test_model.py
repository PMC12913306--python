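"""Core SEM quantities: total effects, acyclicity, objective, constraints,
and agreement of every analytic gradient with central finite differences."""

import numpy as np
import pytest

from lincdic.model import (
    InterventionalConstraint,
    acyclicity,
    acyclicity_gradient,
    constraint_jacobian,
    constraint_value,
    objective,
    objective_gradient,
    total_effects,
    total_effects_power,
    validate_constraints,
)

from conftest import central_difference, random_dag_weights


def chain3(w12, w23):
    W = np.zeros((3, 3))
    W[0, 1] = w12
    W[1, 2] = w23
    return W


class TestTotalEffects:
    def test_empty_graph_has_no_effects(self):
        assert np.array_equal(total_effects(np.zeros((3, 3))), np.zeros((3, 3)))

    def test_three_variable_chain_composes_path_products(self):
        # direct effects on (0,1) and (1,2); indirect product on (0,2)
        T = total_effects(chain3(0.7, -0.3))
        expected = np.zeros((3, 3))
        expected[0, 1] = 0.7
        expected[1, 2] = -0.3
        expected[0, 2] = 0.7 * -0.3
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_chain_indirect_effect_value(self):
        # Neumann oracle W + W^2 on the chain gives 0.5 * 0.4 = 0.2
        W = chain3(0.5, 0.4)
        np.testing.assert_allclose(total_effects(W)[0, 2], 0.2, atol=1e-12)
        np.testing.assert_allclose(total_effects(W), W + W @ W, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("d", [3, 5, 10])
    def test_matches_neumann_power_sum_on_random_dags(self, d, seed):
        W = random_dag_weights(d, np.random.default_rng(seed))
        np.testing.assert_allclose(
            total_effects(W), total_effects_power(W), atol=1e-8
        )

    def test_singular_matrix_falls_back_to_power_sum(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])  # I - W singular
        np.testing.assert_allclose(total_effects(W), total_effects_power(W))
        with pytest.raises(np.linalg.LinAlgError):
            total_effects(W, fallback=False)


class TestAcyclicity:
    def test_zero_matrix(self):
        assert acyclicity(np.zeros((4, 4))) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_vanishes_on_random_dags(self, seed):
        W = random_dag_weights(6, np.random.default_rng(seed), density=0.6)
        assert abs(acyclicity(W)) < 1e-10

    def test_two_cycle_closed_form(self):
        # exp of [[0,1],[1,0]] has trace 2*cosh(1)
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert acyclicity(W) == pytest.approx(2 * np.cosh(1) - 2, rel=1e-10)

    @pytest.mark.parametrize("edges", [
        [(0, 1), (1, 0)],
        [(0, 1), (1, 2), (2, 0)],
        [(1, 2), (2, 1)],
    ])
    def test_positive_on_cycles(self, edges):
        W = np.zeros((3, 3))
        for i, j in edges:
            W[i, j] = 0.8
        assert acyclicity(W) > 1e-4

    def test_nonnegative_everywhere(self, rng):
        for _ in range(20):
            W = rng.normal(size=(4, 4))
            np.fill_diagonal(W, 0)
            assert acyclicity(W) >= -1e-12


class TestGradients:
    """Every analytic gradient matches central finite differences."""

    @pytest.mark.parametrize("seed", range(25))
    def test_acyclicity_gradient(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(scale=0.6, size=(4, 4))
        np.fill_diagonal(W, 0)
        g = acyclicity_gradient(W)
        g_fd = central_difference(acyclicity, W)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-7)

    def test_acyclicity_gradient_two_cycle_closed_form(self):
        # d/dw of (2 cosh(w^2) - 2) at w=1 is 4 sinh(1); the matrix gradient
        # splits it over the two symmetric entries
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = acyclicity_gradient(W)
        assert g[0, 1] == pytest.approx(2 * np.sinh(1), rel=1e-10)
        assert g[1, 0] == pytest.approx(2 * np.sinh(1), rel=1e-10)

    def test_triangular_gradient_matches_finite_differences(self):
        # on a DAG h is at a (flat) minimum: cycle creation is second order,
        # so the gradient vanishes and finite differences must agree
        W = np.triu(np.full((3, 3), 0.5), k=1)
        g = acyclicity_gradient(W)
        g_fd = central_difference(acyclicity, W)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("seed", range(25))
    def test_objective_gradient_away_from_zeros(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(7, 4))
        W = rng.uniform(0.2, 1.0, (4, 4)) * rng.choice([-1, 1], (4, 4))
        np.fill_diagonal(W, 0)
        g = objective_gradient(W, X, 0.1)
        g_fd = central_difference(lambda w: objective(w, X, 0.1), W)
        off = ~np.eye(4, dtype=bool)  # diagonal entries sit at the |.| kink
        np.testing.assert_allclose(g[off], g_fd[off], rtol=1e-4, atol=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_constraint_jacobian(self, seed):
        rng = np.random.default_rng(seed)
        W = random_dag_weights(5, rng, density=0.5)
        c = InterventionalConstraint(0, 4, 0.1 if seed % 2 else -0.1)
        J = constraint_jacobian(c, W)
        J_fd = central_difference(
            lambda w: constraint_value(c, total_effects(w)), W
        )
        np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-7)

    def test_constraint_jacobian_at_zero_is_indicator(self):
        c = InterventionalConstraint(1, 2, 1.0)
        J = constraint_jacobian(c, np.zeros((4, 4)))
        expected = np.zeros((4, 4))
        expected[1, 2] = 1.0
        np.testing.assert_allclose(J, expected, atol=1e-12)

    def test_chain_constraint_sensitivity_values(self):
        # sensitivities of T[0,2] on the 0->1->2 chain: existing-path entries
        # carry the complementary path products
        W = chain3(0.5, 0.4)
        c = InterventionalConstraint(0, 2, 1.0)  # delta=1 exposes dT directly
        J = constraint_jacobian(c, W)
        assert J[0, 1] == pytest.approx(0.4)   # completes with w23
        assert J[1, 2] == pytest.approx(0.5)   # completes with w12
        assert J[0, 2] == pytest.approx(1.0)   # the direct entry
        J_fd = central_difference(
            lambda w: constraint_value(c, total_effects(w)), W
        )
        np.testing.assert_allclose(J, J_fd, rtol=1e-5, atol=1e-7)


class TestObjective:
    def test_zero_weight_matrix(self, rng):
        X = rng.normal(size=(6, 3))
        expected = np.sum(X * X) / (2 * 6)
        assert objective(np.zeros((3, 3)), X, 0.0) == pytest.approx(expected)

    def test_zero_data_reduces_to_penalty(self, rng):
        W = rng.normal(size=(3, 3))
        np.fill_diagonal(W, 0)
        X = np.zeros((5, 3))
        assert objective(W, X, 0.5) == pytest.approx(0.5 * np.abs(W).sum())
        np.testing.assert_allclose(
            objective_gradient(W, X, 0.5), 0.5 * np.sign(W)
        )

    def test_perfect_copy_column(self):
        # X has identical columns; w12=1 reconstructs column 2 exactly,
        # column 1 keeps its full norm: F = (2*1^2)/(2*2) + lambda*1
        X = np.ones((2, 2))
        W = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert objective(W, X, 1.0) == pytest.approx(0.5 + 1.0)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            objective(np.zeros((3, 3)), rng.normal(size=(5, 4)), 0.1)


class TestConstraintSemantics:
    @pytest.mark.parametrize(
        "delta,tij,expected_sign",
        [
            (0.1, 0.5, 1),    # positive effect above threshold: satisfied
            (-0.1, -0.2, 1),  # negative effect below threshold: satisfied
            (0.1, 0.0, -1),   # required positive but absent: violated
            (0.1, -0.5, -1),  # wrong sign: violated
            (-0.1, 0.05, -1),
        ],
    )
    def test_value_sign(self, delta, tij, expected_sign):
        T = np.zeros((3, 3))
        T[0, 1] = tij
        v = constraint_value(InterventionalConstraint(0, 1, delta), T)
        assert np.sign(v) == expected_sign

    def test_satisfaction_implies_sign_and_magnitude(self, rng):
        # delta*(T-delta) > 0  =>  sign(T) == sign(delta) and |T| > |delta|
        for _ in range(200):
            delta = rng.uniform(-1, 1)
            t = rng.uniform(-2, 2)
            if delta == 0:
                continue
            if delta * (t - delta) > 0:
                assert np.sign(t) == np.sign(delta)
                assert abs(t) > abs(delta)

    def test_worked_values(self):
        T = np.zeros((2, 2))
        T[0, 1] = 0.5
        assert constraint_value(
            InterventionalConstraint(0, 1, 0.1), T
        ) == pytest.approx(0.04)
        T[0, 1] = -0.2
        assert constraint_value(
            InterventionalConstraint(0, 1, -0.1), T
        ) == pytest.approx(0.01)
        T[0, 1] = 0.0
        assert constraint_value(
            InterventionalConstraint(0, 1, 0.1), T
        ) == pytest.approx(-0.01)

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            InterventionalConstraint(1, 1, 0.1)
        with pytest.raises(ValueError):
            InterventionalConstraint(0, 1, 0.0)
        with pytest.raises(ValueError):
            validate_constraints(
                [
                    InterventionalConstraint(0, 1, 0.1),
                    InterventionalConstraint(0, 1, -0.1),
                ],
                d=3,
            )
        with pytest.raises(ValueError):
            validate_constraints([InterventionalConstraint(0, 5, 0.1)], d=3)
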