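"""Synthetic LSIRM data generation and parameter-recovery metrics.

The generator emulates a deductive-reasoning-style item design: item
intercepts form an equally spaced grid on [-2, 2] randomly assigned to
items, the first item-coordinate dimension decreases over its range in
equally sized steps, the remaining item coordinates and all person
parameters are normal draws (person coordinates correlated bivariate
normal), and the distance term enters with a configurable weight gamma.
With a 24-item base design, larger item counts tile the item-parameter
block (e.g. four repeats for 96 items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import ResponseMatrix
from .model import SimulationTruth, distance_matrix
from .rotation import align_to_reference

_BASE_ITEMS = 24


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults give the standard two-dimensional design: N persons, J = 24
    items, item intercepts on a [-2, 2] grid, first item coordinate stepping
    from 2 down to -2, unit-variance person intercepts and coordinates with
    a 0.3 correlation between the two coordinate dimensions, and gamma = 1
    (gamma = 1.7 emulates a stronger latent-space effect).
    """

    N: int = 500
    J: int = 24
    D: int = 2
    gamma: float = 1.0
    beta_range: tuple[float, float] = (-2.0, 2.0)
    w1_range: tuple[float, float] = (2.0, -2.0)
    w_var: float = 1.0
    theta_mean: float = 0.0
    theta_var: float = 1.0
    z_var: tuple[float, float] = (1.0, 1.0)
    z_corr: float = 0.3
    repeat_items: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be strictly positive")
        if not abs(self.z_corr) < 1:
            raise ValueError("|z_corr| must be < 1")
        if self.N < 1 or self.J < 1 or self.D < 1:
            raise ValueError("N, J and D must be positive")


def _item_parameters(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Item intercepts and coordinates, tiling a 24-item base block if asked."""
    J, D = config.J, config.D
    if config.repeat_items and J > _BASE_ITEMS and J % _BASE_ITEMS == 0:
        base = _BASE_ITEMS
        reps = J // _BASE_ITEMS
    else:
        base = J
        reps = 1
    beta_base = rng.permutation(
        np.linspace(config.beta_range[0], config.beta_range[1], base)
    )
    W_base = np.empty((base, D))
    W_base[:, 0] = np.linspace(config.w1_range[0], config.w1_range[1], base)
    if D > 1:
        W_base[:, 1:] = rng.normal(0.0, np.sqrt(config.w_var), (base, D - 1))
    beta = np.tile(beta_base, reps)
    W = np.tile(W_base, (reps, 1))
    return beta, W


def _person_parameters(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    N, D = config.N, config.D
    theta = rng.normal(config.theta_mean, np.sqrt(config.theta_var), N)
    var = np.ones(D)
    for d in range(min(D, len(config.z_var))):
        var[d] = config.z_var[d]
    cov = np.diag(var)
    if D >= 2:
        c = config.z_corr * np.sqrt(var[0] * var[1])
        cov[0, 1] = cov[1, 0] = c
    Z = rng.multivariate_normal(np.zeros(D), cov, N, method="cholesky")
    return theta, Z


def generate(config: GeneratorConfig) -> tuple[ResponseMatrix, SimulationTruth]:
    """Draw one dataset: Y_pi ~ Bernoulli(logistic(theta_p + beta_i - gamma*d))."""
    rng = np.random.default_rng(config.seed)
    beta, W = _item_parameters(config, rng)
    theta, Z = _person_parameters(config, rng)
    P = expit(
        theta[:, None] + beta[None, :] - config.gamma * distance_matrix(Z, W)
    )
    Y = (rng.random(P.shape) < P).astype(np.int64)
    truth = SimulationTruth(theta=theta, beta=beta, Z=Z, W=W, gamma=config.gamma)
    return ResponseMatrix(Y), truth


def model_probabilities(truth: SimulationTruth) -> np.ndarray:
    """True cell probabilities implied by a SimulationTruth."""
    return expit(
        truth.theta[:, None]
        + truth.beta[None, :]
        - truth.gamma * distance_matrix(truth.Z, truth.W)
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery metrics per parameter family across replications.

    All of ``mab`` (mean absolute bias), ``var`` and ``mse`` are computed
    after rescaling each replicate's estimates to the standard deviation of
    the true values (separating shrinkage from noise); ``sd_bias`` is the
    mean bias of the raw estimate SD against its theoretical expectation
    (gamma * SD(truth) for coordinates, SD(truth) otherwise).
    ``correlation`` is the mean Pearson correlation with the truth.
    """

    mab: dict[str, float]
    var: dict[str, float]
    mse: dict[str, float]
    sd_bias: dict[str, float]
    correlation: dict[str, float]


def _family_arrays(truth: SimulationTruth) -> dict[str, np.ndarray]:
    return {
        "theta": np.asarray(truth.theta, dtype=float),
        "beta": np.asarray(truth.beta, dtype=float),
        "Z": np.asarray(truth.Z, dtype=float),
        "W": np.asarray(truth.W, dtype=float),
    }


def recovery_metrics(truth: SimulationTruth, fits) -> RecoveryReport:
    """Recovery of the generating parameters across replicate fits.

    Each fit is aligned to the truth's orientation (orthogonal Procrustes on
    the item coordinates, applied to persons too) and its coordinates divided
    by gamma before comparison, since JML absorbs gamma into the coordinate
    scale.
    """
    true_fam = _family_arrays(truth)
    est: dict[str, list[np.ndarray]] = {k: [] for k in true_fam}
    raw_sd: dict[str, list[float]] = {k: [] for k in true_fam}
    corr: dict[str, list[float]] = {k: [] for k in true_fam}

    for fit in fits:
        W_al, Z_al = align_to_reference(fit.W, fit.Z, truth.W)
        fam = {
            "theta": fit.theta,
            "beta": fit.beta,
            "Z": Z_al / truth.gamma,
            "W": W_al / truth.gamma,
        }
        for k, arr in fam.items():
            t = true_fam[k]
            if arr.shape != t.shape:
                raise ValueError(
                    f"{k}: estimate shape {arr.shape} != truth shape {t.shape}"
                )
            raw = arr * (1.0 if k in ("theta", "beta") else truth.gamma)
            raw_sd[k].append(float(np.std(raw)))
            sd_t = float(np.std(t))
            sd_e = float(np.std(arr))
            scaled = arr * (sd_t / sd_e) if sd_e > 0 else arr.copy()
            est[k].append(scaled)
            corr[k].append(
                float(np.corrcoef(arr.ravel(), t.ravel())[0, 1])
                if arr.size > 1
                else 1.0
            )

    mab: dict[str, float] = {}
    var: dict[str, float] = {}
    mse: dict[str, float] = {}
    sd_bias: dict[str, float] = {}
    correlation: dict[str, float] = {}
    for k, t in true_fam.items():
        stack = np.stack(est[k])  # (reps, ...)
        bias = stack.mean(axis=0) - t
        v = stack.var(axis=0)
        mab[k] = float(np.mean(np.abs(bias)))
        var[k] = float(np.mean(v))
        mse[k] = float(np.mean((stack - t[None]) ** 2))
        expected_sd = float(np.std(t)) * (
            truth.gamma if k in ("Z", "W") else 1.0
        )
        sd_bias[k] = float(np.mean(raw_sd[k]) - expected_sd)
        correlation[k] = float(np.mean(corr[k]))
    return RecoveryReport(
        mab=mab, var=var, mse=mse, sd_bias=sd_bias, correlation=correlation
    )
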