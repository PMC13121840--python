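"""Sequential (continuation-ratio) ordinal LSIRM via cumulative dummy coding.

An ordinal item with C observed categories is expanded into C - 1 binary
"dummy items", one per category boundary c = 1..C-1:

* dummy c = 1 when the response reached at least category c,
* dummy c = 0 when the response stopped exactly at category c - 1,
* dummy c is missing when the sequential process stopped before boundary c
  (response below c - 1), because that conditional step never occurred.

Fitting the binary LSIRM to the expanded matrix — with all dummies of one
original item sharing a single latent coordinate vector w — is exactly
equivalent to maximizing the sequential-model likelihood, where the dummy
intercepts play the role of per-boundary threshold parameters.  The lowest
observed category is the reference (no parameter); categories never observed
for an item are collapsed out before expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DataValidationError, OrdinalResponseMatrix, ResponseMatrix
from .estimators import FitOptions, LSIRMFit, _fit
from .model import RegularizationSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DummyExpansion:
    """Binary expansion of an ordinal matrix with its column bookkeeping."""

    binary: ResponseMatrix
    item_map: tuple[tuple[int, int], ...]  # dummy column -> (orig item, boundary)
    item_group: np.ndarray  # dummy column -> original item index
    dropped: tuple[tuple[int, int], ...]  # (item, unobserved category code)
    n_thresholds: np.ndarray  # per original item

    @property
    def n_dummy_items(self) -> int:
        return len(self.item_map)


@dataclass(frozen=True)
class OrdinalItemParameters:
    """Per-item threshold (category-boundary) parameters.

    ``thresholds[j]`` holds the C'_j - 1 boundary effects of item j in
    boundary order; the lowest observed category is the reference with
    effect 0.  ``ordered`` flags whether the estimated thresholds are
    monotone decreasing, a post-fit diagnostic only (the sequential model
    identifies each boundary separately, so no order is enforced).
    """

    thresholds: tuple[np.ndarray, ...]
    ordered: tuple[bool, ...]


def sequential_expand(Yord: OrdinalResponseMatrix) -> DummyExpansion:
    """Recode an ordinal matrix into cumulative binary dummy items."""
    values, mask = Yord.values, Yord.observed_mask
    N, J = values.shape

    cols: list[np.ndarray] = []
    col_mask: list[np.ndarray] = []
    item_map: list[tuple[int, int]] = []
    groups: list[int] = []
    dropped: list[tuple[int, int]] = []
    n_thresholds = np.zeros(J, dtype=np.int64)

    for j in range(J):
        obs = values[mask[:, j], j]
        observed_cats = np.unique(obs)
        if observed_cats.size < 2:
            raise DataValidationError(
                f"item {j} has a single observed category; no information"
            )
        declared = np.arange(Yord.categories[j])
        unused = np.setdiff1d(declared, observed_cats)
        for cat in unused:
            dropped.append((j, int(cat)))
        if unused.size:
            logger.info(
                "item %d: collapsing %d unobserved categor%s %s",
                j,
                unused.size,
                "y" if unused.size == 1 else "ies",
                unused.tolist(),
            )
        # relabel observed categories to consecutive codes 0..C'-1
        relabel = np.searchsorted(observed_cats, values[:, j])
        C_prime = observed_cats.size
        n_thresholds[j] = C_prime - 1
        for c in range(1, C_prime):
            dummy = (relabel >= c).astype(np.float64)
            dmask = mask[:, j] & (relabel >= c - 1)
            cols.append(np.where(dmask, dummy, 0.0))
            col_mask.append(dmask)
            item_map.append((j, c))
            groups.append(j)

    binary = ResponseMatrix(
        np.column_stack(cols), np.column_stack(col_mask)
    )
    return DummyExpansion(
        binary=binary,
        item_map=tuple(item_map),
        item_group=np.asarray(groups, dtype=np.int64),
        dropped=tuple(dropped),
        n_thresholds=n_thresholds,
    )


def sequential_log_likelihood(
    Yord: OrdinalResponseMatrix,
    theta: np.ndarray,
    thresholds: tuple[np.ndarray, ...] | list[np.ndarray],
    Z: np.ndarray,
    W: np.ndarray,
) -> float:
    """Direct log-likelihood of the sequential ordinal model.

    For person p and item j with relabeled response y (0..C'-1) and
    continuation probabilities p_c = logistic(theta_p + b_jc - d(w_j, z_p)),
    the probability of the response is
    prod_{c=1}^{y} p_c * (1 - p_{y+1}) with the last factor omitted at the
    top category.  Used as an independent cross-check of the dummy-item
    equivalence; fitting goes through the expansion.
    """
    from scipy.special import expit

    values, mask = Yord.values, Yord.observed_mask
    N, J = values.shape
    total = 0.0
    for j in range(J):
        obs_idx = np.flatnonzero(mask[:, j])
        obs = values[obs_idx, j]
        observed_cats = np.unique(obs)
        relabel = np.searchsorted(observed_cats, obs)
        C_prime = observed_cats.size
        b = np.asarray(thresholds[j], dtype=np.float64)
        if b.size != C_prime - 1:
            raise ValueError(
                f"item {j}: expected {C_prime - 1} thresholds, got {b.size}"
            )
        d = np.sqrt(np.sum((Z[obs_idx] - W[j][None, :]) ** 2, axis=1))
        for c in range(1, C_prime):
            p_c = expit(theta[obs_idx] + b[c - 1] - d)
            reached = relabel >= c - 1
            passed = relabel >= c
            total += float(np.sum(np.log(p_c[reached & passed])))
            total += float(np.sum(np.log1p(-p_c[reached & ~passed])))
    return total


def fit_ordinal(
    Yord: OrdinalResponseMatrix,
    options: FitOptions,
    spec: RegularizationSpec | None = None,
) -> tuple[LSIRMFit, OrdinalItemParameters, DummyExpansion]:
    """Fit the sequential ordinal LSIRM via its binary dummy expansion.

    All dummies of one original item share a single coordinate vector w (the
    gradient contributions of its dummy columns are summed), while each dummy
    keeps its own intercept — the boundary threshold.  Person parameters are
    unchanged from the binary model.
    """
    if spec is None:
        spec = RegularizationSpec(mode="penalized", lambda_=1.0)
    expansion = sequential_expand(Yord)
    fit = _fit(
        expansion.binary,
        options,
        spec,
        item_group=expansion.item_group,
    )
    thresholds: list[np.ndarray] = []
    ordered: list[bool] = []
    for j in range(Yord.n_items):
        cols = [k for k, (jj, _) in enumerate(expansion.item_map) if jj == j]
        b = fit.beta[cols]
        thresholds.append(b)
        ordered.append(bool(np.all(np.diff(b) <= 0)) if b.size > 1 else True)
    params = OrdinalItemParameters(
        thresholds=tuple(thresholds), ordered=tuple(ordered)
    )
    return fit, params, expansion
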