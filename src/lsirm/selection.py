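"""Cell-wise K-fold cross-validation for latent-space dimension selection.

Folds partition the *observed (person, item) cells* of the response matrix —
not its rows — so each fold's fit treats its held-out cells as missing
completely at random and predicts them afterwards.  Three held-out metrics
are computed, all "unnormalized" so that smaller is better and values add
over folds:

* UCE — count of misclassified cells at a 0.5 probability threshold;
* URE — fold size times (1 - AUC), the rank-based ROC error;
* RSS — residual sum of squares of responses against predicted
  probabilities.

The candidate dimension minimizing a metric's total over folds is selected;
ties break toward the smaller (more parsimonious) dimension.  The same fold
partition is reused for every candidate so metric differences reflect the
model, not the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import ResponseMatrix
from .estimators import FitOptions, LSIRMFit, fit_cjml, fit_pjml
from .model import RegularizationSpec

METRICS = ("uce", "ure", "rss")


@dataclass(frozen=True)
class FoldPartition:
    """Assignment of every observed cell to exactly one of K folds."""

    rows: np.ndarray  # observed-cell row indices, in fold order
    cols: np.ndarray
    fold_id: np.ndarray  # parallel fold index 0..K-1
    K: int
    seed: int

    def cells(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        sel = self.fold_id == k
        return self.rows[sel], self.cols[sel]

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_id, minlength=self.K)


def make_folds(Y: ResponseMatrix, K: int, seed: int) -> FoldPartition:
    """Uniformly random partition of the observed cells into K folds.

    When the number of observed cells is not a multiple of K, the remainder
    cells go to the first folds, so fold sizes differ by at most one.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rows, cols = np.nonzero(Y.observed_mask)
    n = rows.size
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} observed cells")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    rows, cols = rows[perm], cols[perm]
    base, rem = divmod(n, K)
    sizes = np.full(K, base)
    sizes[:rem] += 1
    fold_id = np.repeat(np.arange(K), sizes)
    return FoldPartition(rows=rows, cols=cols, fold_id=fold_id, K=K, seed=seed)


def predict_fold(
    fit: LSIRMFit, cells: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Model probabilities for held-out cells (invariant to rotation)."""
    rows, cols = cells
    P = fit.probabilities()
    return P[rows, cols]


def uce(y: np.ndarray, p: np.ndarray) -> float:
    """Count of misclassified cells; probabilities >= 0.5 classify as 1."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    yhat = (p >= 0.5).astype(float)
    return float(np.sum(np.abs(y - yhat)))


def ure(y: np.ndarray, p: np.ndarray) -> float:
    """Fold size times (1 - AUC); AUC uses midranks (Mann-Whitney) for ties.

    If only one class is present among the held-out responses the AUC is
    undefined and is taken as 0.5 with a warning.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if np.unique(y).size < 2:
        warnings.warn(
            "single-class fold: AUC undefined, using 0.5", RuntimeWarning
        )
        auc = 0.5
    else:
        auc = float(roc_auc_score(y, p))
    return float(y.size) * (1.0 - auc)


def rss(y: np.ndarray, p: np.ndarray) -> float:
    """Residual sum of squares of responses against predicted probabilities."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    return float(np.sum((y - p) ** 2))


_METRIC_FUNCS = {"uce": uce, "ure": ure, "rss": rss}


@dataclass(frozen=True)
class CVResult:
    """Per-(D, metric, fold) cross-validation scores and the selections."""

    D_candidates: tuple[int, ...]
    K: int
    per_fold: dict[tuple[int, str], np.ndarray]  # (D, metric) -> K values
    totals: dict[tuple[int, str], float]
    selected_D: dict[str, int]
    unconverged: tuple[tuple[int, int], ...]  # (D, fold) pairs
    seed: int

    def table(self):
        """Totals as a tidy DataFrame: rows = D, columns = metrics."""
        import pandas as pd

        return pd.DataFrame(
            {
                m.upper(): [self.totals[(D, m)] for D in self.D_candidates]
                for m in METRICS
            },
            index=pd.Index(self.D_candidates, name="D"),
        )


def cross_validate(
    Y: ResponseMatrix,
    D_candidates: Sequence[int],
    K: int = 10,
    options: FitOptions | None = None,
    spec: RegularizationSpec | None = None,
    seed: int = 0,
) -> CVResult:
    """Select the latent dimension by cell-wise K-fold cross-validation.

    One fold partition (drawn from ``seed``) is shared across all candidate
    dimensions.  For each D and fold, the model is refit with the fold's
    cells masked, the held-out cells are predicted, and all three metrics
    are scored; totals are sums over folds and each metric selects the
    argmin total.
    """
    D_candidates = tuple(sorted(int(d) for d in D_candidates))
    if not D_candidates:
        raise ValueError("D_candidates must be nonempty")
    if options is None:
        options = FitOptions()
    if spec is None:
        spec = RegularizationSpec(mode="penalized", lambda_=1.0)
    folds = make_folds(Y, K, seed)

    per_fold: dict[tuple[int, str], np.ndarray] = {}
    unconverged: list[tuple[int, int]] = []
    for D in D_candidates:
        scores = {m: np.zeros(K) for m in METRICS}
        for k in range(K):
            rows, cols = folds.cells(k)
            Y_train = Y.with_cells_masked(rows, cols)
            opts_k = FitOptions(
                D=D,
                estimator=options.estimator,
                max_iter=options.max_iter,
                rel_tol=options.rel_tol,
                step_init=options.step_init,
                seed=options.seed + 1000 * D + k,
                init=options.init,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if options.estimator == "cjml":
                    fit = fit_cjml(Y_train, opts_k, spec)
                else:
                    fit = fit_pjml(Y_train, opts_k, spec.lambda_)
            if not fit.converged:
                unconverged.append((D, k))
            y = Y.values[rows, cols]
            p = predict_fold(fit, (rows, cols))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for m in METRICS:
                    scores[m][k] = _METRIC_FUNCS[m](y, p)
        for m in METRICS:
            per_fold[(D, m)] = scores[m]

    totals = {key: float(v.sum()) for key, v in per_fold.items()}
    selected = {}
    for m in METRICS:
        vals = np.array([totals[(D, m)] for D in D_candidates])
        selected[m] = D_candidates[int(np.argmin(vals))]  # first min: smaller D
    return CVResult(
        D_candidates=D_candidates,
        K=K,
        per_fold=per_fold,
        totals=totals,
        selected_D=selected,
        unconverged=tuple(unconverged),
        seed=seed,
    )
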