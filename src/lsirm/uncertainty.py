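"""Nonparametric bootstrap standard errors and confidence ellipses.

Persons (rows) are resampled with replacement and the model is refit on each
replicate with identical options.  Because the latent space is identified
only up to rotation/reflection, every replicate is echelon-rotated (done by
the fitter) and then Procrustes-aligned to the point estimate's item
configuration before aggregating, so orientation artifacts cannot inflate
the spread.  Item-side uncertainty is summarized as per-parameter standard
deviations across aligned replicates plus, for two-dimensional spaces, a
confidence ellipse per item from the empirical 2x2 coordinate covariance
scaled by the chi-square(2) quantile.

Person-level standard errors are not reported: row resampling breaks the
correspondence between replicate persons and original persons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data import ResponseMatrix
from .estimators import FitOptions, LSIRMFit, fit_cjml, fit_pjml
from .model import RegularizationSpec
from .rotation import align_to_reference, echelon_zero_pattern


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse for an item position in a 2-D latent space."""

    center: np.ndarray
    semi_axes: np.ndarray  # major, minor
    angle: float  # radians, orientation of the major axis
    constrained: bool  # echelon-fixed coordinate -> degenerate (a line)


@dataclass(frozen=True)
class BootstrapResult:
    """Aggregated bootstrap replicates for the item parameters."""

    B: int
    n_failed: int
    beta_se: np.ndarray
    W_se: np.ndarray  # (J, D); 0 with constrained flag for fixed coords
    W_cov: np.ndarray  # (J, D, D) empirical covariance
    ellipses: tuple[Ellipse, ...] | None
    level: float
    replicate_W: np.ndarray  # (B_ok, J, D) aligned item coordinates
    replicate_beta: np.ndarray
    seed: int


def bootstrap(
    Y: ResponseMatrix,
    options: FitOptions,
    spec: RegularizationSpec | None = None,
    B: int = 1000,
    level: float = 0.99,
    seed: int = 0,
    fit: LSIRMFit | None = None,
) -> BootstrapResult:
    """Bootstrap the item parameters of an LSIRM fit.

    Parameters
    ----------
    B
        Number of resamples (>= 1).
    level
        Confidence level of the ellipses, in (0, 1).
    fit
        Optional precomputed point estimate on the full data; fitted here
        when omitted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if spec is None:
        spec = (
            RegularizationSpec(mode="constrained")
            if options.estimator == "cjml"
            else RegularizationSpec(mode="penalized", lambda_=1.0)
        )

    def _fit_once(data: ResponseMatrix, fit_seed: int) -> LSIRMFit:
        opts = FitOptions(
            D=options.D,
            estimator=options.estimator,
            max_iter=options.max_iter,
            rel_tol=options.rel_tol,
            step_init=options.step_init,
            seed=fit_seed,
            init=options.init,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if options.estimator == "cjml":
                return fit_cjml(data, opts, spec)
            return fit_pjml(data, opts, spec.lambda_)

    if fit is None:
        fit = _fit_once(Y, options.seed)

    rng = np.random.default_rng(seed)
    Ws: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    n_failed = 0
    N = Y.n_persons
    for b in range(B):
        idx = rng.integers(0, N, N)
        try:
            Yb = ResponseMatrix(Y.values[idx], Y.observed_mask[idx])
            rep = _fit_once(Yb, options.seed + b + 1)
        except Exception:
            n_failed += 1
            continue
        W_al, _ = align_to_reference(rep.W, rep.Z, fit.W)
        Ws.append(W_al)
        betas.append(rep.beta)
    if B > 4 and n_failed > 0.2 * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed; results unreliable"
        )
    if not Ws:
        raise RuntimeError("all bootstrap replicates failed")

    W_stack = np.stack(Ws)  # (B_ok, J, D)
    beta_stack = np.stack(betas)
    J, D = fit.W.shape
    W_se = W_stack.std(axis=0)
    beta_se = beta_stack.std(axis=0)

    fixed = np.zeros((J, D), dtype=bool)
    for j, d in echelon_zero_pattern(D):
        fixed[j, d] = True
    W_se = np.where(fixed, 0.0, W_se)

    centered = W_stack - W_stack.mean(axis=0)
    W_cov = np.einsum("bjd,bje->jde", centered, centered) / W_stack.shape[0]

    ellipses = None
    if D == 2:
        q = chi2.ppf(level, df=2)
        ells = []
        for j in range(J):
            cov = W_cov[j].copy()
            cov[fixed[j]] = 0.0
            cov[:, fixed[j]] = 0.0
            vals, vecs = np.linalg.eigh(cov)
            vals = np.clip(vals, 0.0, None)[::-1]
            vecs = vecs[:, ::-1]
            ells.append(
                Ellipse(
                    center=fit.W[j].copy(),
                    semi_axes=np.sqrt(q * vals),
                    angle=float(np.arctan2(vecs[1, 0], vecs[0, 0])),
                    constrained=bool(fixed[j].any()),
                )
            )
        ellipses = tuple(ells)

    return BootstrapResult(
        B=B,
        n_failed=n_failed,
        beta_se=beta_se,
        W_se=W_se,
        W_cov=W_cov,
        ellipses=ellipses,
        level=level,
        replicate_W=W_stack,
        replicate_beta=beta_stack,
        seed=seed,
    )
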