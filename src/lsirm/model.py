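"""Core LSIRM probability model, log-likelihoods, and analytic gradients.

The latent space item response model embeds N persons and J items in a shared
D-dimensional Euclidean space.  The probability of a correct/positive response
of person p on item i is

    P(Y_pi = 1) = logistic(theta_p + beta_i - gamma * d(w_i, z_p)),

where theta_p and beta_i are person and item intercepts, z_p and w_i are the
latent coordinates, d is the Euclidean distance, and gamma > 0 weights the
distance term.  Under joint maximum likelihood gamma is not separately
identified — it is absorbed into the scale of the coordinate estimates — so
all fitting code fixes gamma = 1; the argument exists for simulation and
evaluation only.

Everything here is pure computation on arrays; estimation lives in
:mod:`lsirm.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .data import ResponseMatrix

# Probability clamp keeping the Bernoulli log-likelihood finite.
PROB_EPS = 1e-12


@dataclass(frozen=True)
class LatentConfiguration:
    """Person coordinates Z (N x D) and item coordinates W (J x D)."""

    Z: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        Z = np.atleast_2d(np.asarray(self.Z, dtype=np.float64))
        W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        if Z.shape[1] != W.shape[1]:
            raise ValueError(
                f"Z has {Z.shape[1]} dimensions but W has {W.shape[1]}"
            )
        if Z.shape[1] < 1:
            raise ValueError("latent dimension must be >= 1")
        if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(W))):
            raise ValueError("latent coordinates must be finite")
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "W", W)

    @property
    def n_dim(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class InterceptSet:
    """Person intercepts theta (length N) and item intercepts beta (length J)."""

    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, dtype=np.float64))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(beta))):
            raise ValueError("intercepts must be finite")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class RegularizationSpec:
    """Regularization settings: an L2 penalty (pJML) or norm-ball constraints (cJML).

    ``lambda_`` is the ridge penalty strength for the penalized estimator
    (default 1, matching the shrinkage of standard-normal priors).  For the
    constrained estimator, ``C_person`` bounds the Euclidean norm of each
    (theta_p, z_p) vector and ``C_item`` that of each (beta_i, w_i) vector.
    """

    mode: Literal["penalized", "constrained"] = "penalized"
    lambda_: float = 1.0
    C_person: float | None = None
    C_item: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("penalized", "constrained"):
            raise ValueError(f"unknown regularization mode {self.mode!r}")
        if self.lambda_ < 0:
            raise ValueError("lambda must be nonnegative")
        for name in ("C_person", "C_item"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of a synthetic dataset, for recovery evaluation."""

    theta: np.ndarray
    beta: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be strictly positive")


def euclidean_distance(w: np.ndarray, z: np.ndarray) -> float:
    """Euclidean distance between an item and a person coordinate vector."""
    w = np.asarray(w, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if w.shape != z.shape:
        raise ValueError(
            f"dimension mismatch: w has length {w.size}, z has length {z.size}"
        )
    return float(np.sqrt(np.sum((w - z) ** 2)))


def distance_matrix(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """All person-item Euclidean distances as an N x J matrix."""
    # (N, 1, D) - (1, J, D); small D keeps this cheap.
    diff = Z[:, None, :] - W[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def response_probability(
    theta_p: float,
    beta_i: float,
    w_i: np.ndarray,
    z_p: np.ndarray,
    gamma: float = 1.0,
) -> float:
    """Probability of a positive response under the LSIRM."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    d = euclidean_distance(np.atleast_1d(w_i), np.atleast_1d(z_p))
    return float(expit(theta_p + beta_i - gamma * d))


def probability_matrix(
    intercepts: InterceptSet, config: LatentConfiguration, gamma: float = 1.0
) -> np.ndarray:
    """Model probabilities for every person-item cell (N x J)."""
    eta = (
        intercepts.theta[:, None]
        + intercepts.beta[None, :]
        - gamma * distance_matrix(config.Z, config.W)
    )
    return expit(eta)


def joint_log_likelihood(
    Y: ResponseMatrix, intercepts: InterceptSet, config: LatentConfiguration
) -> float:
    """Bernoulli joint log-likelihood over observed cells (gamma fixed at 1).

    Missing cells contribute nothing (missing-at-random).  Probabilities are
    clamped to [PROB_EPS, 1 - PROB_EPS] so the result stays finite.
    """
    P = probability_matrix(intercepts, config)
    P = np.clip(P, PROB_EPS, 1.0 - PROB_EPS)
    mask = Y.observed_mask
    ll = Y.values * np.log(P) + (1.0 - Y.values) * np.log1p(-P)
    return float(np.sum(ll[mask]))


def penalty_term(intercepts: InterceptSet, config: LatentConfiguration) -> float:
    """Sum of squares of all parameters (the L2 penalty without lambda/2)."""
    return float(
        np.sum(intercepts.theta**2)
        + np.sum(intercepts.beta**2)
        + np.sum(config.Z**2)
        + np.sum(config.W**2)
    )


def penalized_log_likelihood(
    Y: ResponseMatrix,
    intercepts: InterceptSet,
    config: LatentConfiguration,
    lambda_: float = 1.0,
) -> float:
    """Joint log-likelihood minus (lambda/2) * sum of squared parameters."""
    if lambda_ < 0:
        raise ValueError("lambda must be nonnegative")
    ll = joint_log_likelihood(Y, intercepts, config)
    if lambda_ == 0:
        return ll
    return ll - 0.5 * lambda_ * penalty_term(intercepts, config)


def gradients(
    Y: ResponseMatrix,
    intercepts: InterceptSet,
    config: LatentConfiguration,
    spec: RegularizationSpec | None = None,
) -> dict[str, np.ndarray]:
    """Analytic gradients of the (optionally penalized) log-likelihood.

    Returns a dict with keys ``theta``, ``beta``, ``Z``, ``W`` holding arrays
    shaped like the corresponding parameters.  The derivative of the distance
    with respect to a coordinate uses the unit direction vector; at zero
    distance the (valid) subgradient 0 is used.
    """
    theta, beta = intercepts.theta, intercepts.beta
    Z, W = config.Z, config.W
    D = distance_matrix(Z, W)
    P = expit(theta[:, None] + beta[None, :] - D)
    R = np.where(Y.observed_mask, Y.values - P, 0.0)

    g_theta = R.sum(axis=1)
    g_beta = R.sum(axis=0)

    # S_pi = R_pi / d_pi, with the zero-distance subgradient set to 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(D > 0, R / np.where(D > 0, D, 1.0), 0.0)
    s_row = S.sum(axis=1)
    s_col = S.sum(axis=0)
    g_Z = -(Z * s_row[:, None] - S @ W)
    g_W = -(W * s_col[:, None] - S.T @ Z)

    if spec is not None and spec.mode == "penalized" and spec.lambda_ > 0:
        lam = spec.lambda_
        g_theta = g_theta - lam * theta
        g_beta = g_beta - lam * beta
        g_Z = g_Z - lam * Z
        g_W = g_W - lam * W

    return {"theta": g_theta, "beta": g_beta, "Z": g_Z, "W": g_W}
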