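"""Core model: distances, probabilities, likelihoods, analytic gradients."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from lsirm import (
    InterceptSet,
    LatentConfiguration,
    RegularizationSpec,
    ResponseMatrix,
    euclidean_distance,
    joint_log_likelihood,
    penalized_log_likelihood,
    response_probability,
)
from lsirm.data import DataValidationError
from lsirm.model import gradients, probability_matrix

from conftest import random_parameters


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "w, z, expected",
        [
            ((1.0, 2.0), (1.0, 2.0), 0.0),
            ((3.0, 4.0), (0.0, 0.0), 5.0),
            ((1.0,), (4.0,), 3.0),
        ],
    )
    def test_known_values(self, w, z, expected):
        assert euclidean_distance(np.array(w), np.array(z)) == pytest.approx(
            expected
        )

    def test_rotation_invariance(self, rng):
        for _ in range(10):
            D = int(rng.integers(2, 5))
            w, z = rng.normal(size=D), rng.normal(size=D)
            Q = ortho_group.rvs(D, random_state=np.random.RandomState(1))
            assert euclidean_distance(w @ Q, z @ Q) == pytest.approx(
                euclidean_distance(w, z), abs=1e-12
            )

    def test_dimension_mismatch_names_lengths(self):
        with pytest.raises(ValueError, match="2.*3|3.*2"):
            euclidean_distance(np.zeros(2), np.zeros(3))


class TestResponseProbability:
    def test_zero_linear_predictor_is_half(self):
        w = np.array([0.3, -0.2])
        assert response_probability(0.0, 0.0, w, w) == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        # theta + beta - gamma*d = 0.5 + 1.0 - 0.3 = 1.2
        z = np.array([0.0, 0.0])
        w = np.array([0.3, 0.0])
        p = response_probability(0.5, 1.0, w, z, gamma=1.0)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-1.2)), abs=1e-9)
        assert p == pytest.approx(0.768525, abs=1e-6)

    def test_gamma_zero_ignores_coordinates(self, rng):
        w, z = rng.normal(size=3), rng.normal(size=3)
        p = response_probability(0.4, -0.7, w, z, gamma=0.0)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(0.3)))

    def test_strictly_decreasing_in_distance(self):
        z = np.zeros(2)
        ps = [
            response_probability(0.0, 0.0, np.array([d, 0.0]), z)
            for d in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0.0 < p < 1.0 for p in ps)


class TestJointLogLikelihood:
    def test_all_zero_parameters(self):
        Y = ResponseMatrix(np.array([[1, 0], [0, 1], [1, 1]]))
        ic = InterceptSet(np.zeros(3), np.zeros(2))
        cfg = LatentConfiguration(np.zeros((3, 2)), np.zeros((2, 2)))
        assert joint_log_likelihood(Y, ic, cfg) == pytest.approx(
            -6 * np.log(2)
        )

    def test_single_observed_cell(self):
        mask = np.array([[True, False], [False, True]])
        Y = ResponseMatrix(np.array([[1, 0], [0, 0]]), mask)
        ic = InterceptSet(np.zeros(2), np.zeros(2))
        cfg = LatentConfiguration(np.zeros((2, 1)), np.zeros((2, 1)))
        assert joint_log_likelihood(Y, ic, cfg) == pytest.approx(
            2 * np.log(0.5)
        )

    def test_matches_per_cell_enumeration(self, rng):
        """Vectorized likelihood equals an independent per-cell summation."""
        N, J, D = 5, 4, 2
        theta, beta, Z, W = random_parameters(rng, N, J, D)
        values = rng.integers(0, 2, (N, J))
        mask = rng.random((N, J)) < 0.8
        mask[:, 0] = True
        mask[0, :] = True
        Y = ResponseMatrix(values, mask)
        total = 0.0
        for p in range(N):
            for i in range(J):
                if not mask[p, i]:
                    continue
                prob = response_probability(theta[p], beta[i], W[i], Z[p])
                total += (
                    np.log(prob) if values[p, i] == 1 else np.log(1 - prob)
                )
        got = joint_log_likelihood(
            Y, InterceptSet(theta, beta), LatentConfiguration(Z, W)
        )
        assert got == pytest.approx(total, abs=1e-10)

    def test_invariances(self, rng):
        """Rotation/translation of the space and theta/beta transfer."""
        N, J, D = 7, 5, 3
        theta, beta, Z, W = random_parameters(rng, N, J, D)
        Y = ResponseMatrix(rng.integers(0, 2, (N, J)))
        base = joint_log_likelihood(
            Y, InterceptSet(theta, beta), LatentConfiguration(Z, W)
        )
        Q = ortho_group.rvs(D, random_state=np.random.RandomState(7))
        t = rng.normal(size=D)
        c = 0.37
        variants = [
            (theta, beta, Z @ Q, W @ Q),
            (theta, beta, Z + t, W + t),
            (theta + c, beta - c, Z, W),
        ]
        for th, be, Zv, Wv in variants:
            alt = joint_log_likelihood(
                Y, InterceptSet(th, be), LatentConfiguration(Zv, Wv)
            )
            assert alt == pytest.approx(base, abs=1e-10)


class TestPenalizedLogLikelihood:
    def test_lambda_zero_equals_joint(self, rng):
        theta, beta, Z, W = random_parameters(rng, 4, 3, 2)
        Y = ResponseMatrix(rng.integers(0, 2, (4, 3)))
        ic, cfg = InterceptSet(theta, beta), LatentConfiguration(Z, W)
        assert penalized_log_likelihood(Y, ic, cfg, 0.0) == joint_log_likelihood(
            Y, ic, cfg
        )

    def test_zero_parameters_no_penalty(self):
        Y = ResponseMatrix(np.ones((2, 2), dtype=int))
        ic = InterceptSet(np.zeros(2), np.zeros(2))
        cfg = LatentConfiguration(np.zeros((2, 2)), np.zeros((2, 2)))
        assert penalized_log_likelihood(Y, ic, cfg, 5.0) == pytest.approx(
            -4 * np.log(2)
        )

    def test_penalty_arithmetic(self, rng):
        theta, beta, Z, W = random_parameters(rng, 4, 3, 2)
        Y = ResponseMatrix(rng.integers(0, 2, (4, 3)))
        ic, cfg = InterceptSet(theta, beta), LatentConfiguration(Z, W)
        lam = 1.3
        expected = joint_log_likelihood(Y, ic, cfg) - 0.5 * lam * (
            np.sum(theta**2) + np.sum(beta**2) + np.sum(Z**2) + np.sum(W**2)
        )
        assert penalized_log_likelihood(Y, ic, cfg, lam) == pytest.approx(
            expected, abs=1e-12
        )


class TestGradients:
    @pytest.mark.parametrize("lam", [0.0, 0.7])
    def test_matches_finite_differences(self, rng, lam):
        """Analytic gradients agree with central differences on 20 instances."""
        spec = RegularizationSpec(mode="penalized", lambda_=lam)
        eps = 1e-6
        for rep in range(20):
            N, J, D = 5, 4, int(rng.integers(1, 4))
            theta, beta, Z, W = random_parameters(rng, N, J, D)
            values = rng.integers(0, 2, (N, J))
            mask = rng.random((N, J)) < 0.85
            mask[:, 0] = True
            mask[0, :] = True
            Y = ResponseMatrix(values, mask)
            g = gradients(
                Y, InterceptSet(theta, beta), LatentConfiguration(Z, W), spec
            )

            def obj(theta, beta, Z, W):
                return penalized_log_likelihood(
                    Y, InterceptSet(theta, beta), LatentConfiguration(Z, W), lam
                )

            params = {"theta": theta, "beta": beta, "Z": Z, "W": W}
            for key, arr in params.items():
                flat = arr.ravel()
                for idx in range(flat.size):
                    up = {k: v.copy() for k, v in params.items()}
                    dn = {k: v.copy() for k, v in params.items()}
                    up[key].ravel()[idx] += eps
                    dn[key].ravel()[idx] -= eps
                    fd = (obj(**up) - obj(**dn)) / (2 * eps)
                    assert g[key].ravel()[idx] == pytest.approx(
                        fd, rel=1e-5, abs=1e-7
                    )

    def test_penalty_shifts_gradient_exactly(self, rng):
        theta, beta, Z, W = random_parameters(rng, 5, 4, 2)
        Y = ResponseMatrix(rng.integers(0, 2, (5, 4)))
        ic, cfg = InterceptSet(theta, beta), LatentConfiguration(Z, W)
        g0 = gradients(Y, ic, cfg, RegularizationSpec(lambda_=0.0))
        g1 = gradients(Y, ic, cfg, RegularizationSpec(lambda_=2.5))
        np.testing.assert_allclose(g1["theta"], g0["theta"] - 2.5 * theta)
        np.testing.assert_allclose(g1["W"], g0["W"] - 2.5 * W)

    def test_zero_distance_subgradient_is_finite(self):
        """Coincident person and item coordinates must not produce NaNs."""
        Y = ResponseMatrix(np.array([[1, 0], [0, 1]]))
        ic = InterceptSet(np.zeros(2), np.zeros(2))
        cfg = LatentConfiguration(np.zeros((2, 2)), np.zeros((2, 2)))
        g = gradients(Y, ic, cfg, RegularizationSpec())
        for arr in g.values():
            assert np.all(np.isfinite(arr))
        np.testing.assert_allclose(g["Z"], 0.0)


class TestResponseMatrixValidation:
    def test_rejects_nonbinary(self):
        with pytest.raises(DataValidationError, match="0/1"):
            ResponseMatrix(np.array([[0, 2], [1, 0]]))

    def test_rejects_empty_row(self):
        mask = np.array([[False, False], [True, True]])
        with pytest.raises(DataValidationError, match="rows"):
            ResponseMatrix(np.zeros((2, 2), dtype=int), mask)

    def test_rejects_empty_column(self):
        mask = np.array([[True, False], [True, False]])
        with pytest.raises(DataValidationError, match="columns"):
            ResponseMatrix(np.ones((2, 2), dtype=int), mask)

    def test_probability_matrix_in_open_interval(self, rng):
        theta, beta, Z, W = random_parameters(rng, 6, 5, 2, scale=3.0)
        P = probability_matrix(
            InterceptSet(theta, beta), LatentConfiguration(Z, W)
        )
        assert np.all(P > 0.0) and np.all(P < 1.0)
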