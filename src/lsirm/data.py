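"""Response-matrix containers and validation.

A latent space item response model (LSIRM) operates on a wide person-by-item
matrix of integer-coded responses.  Binary responses are coded {0, 1}; ordinal
responses are coded {0, ..., C_j - 1} with a per-item category count C_j.
Missingness is carried as an explicit boolean mask rather than sentinel
values, so every downstream computation can restrict itself to observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DataValidationError(ValueError):
    """Raised when a response matrix violates the model's input contract."""


def _check_coverage(mask: np.ndarray) -> None:
    rows = np.flatnonzero(~mask.any(axis=1))
    if rows.size:
        raise DataValidationError(
            f"persons with no observed responses: rows {rows.tolist()}"
        )
    cols = np.flatnonzero(~mask.any(axis=0))
    if cols.size:
        raise DataValidationError(
            f"items with no observed responses: columns {cols.tolist()}"
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary person-by-item response data with an observed-cell mask.

    Parameters
    ----------
    values
        N x J integer array.  Entries at unobserved cells are ignored (and
        stored as 0 internally).
    observed_mask
        N x J boolean array; True marks an observed cell.  ``None`` means
        fully observed.
    """

    values: np.ndarray
    observed_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataValidationError("response matrix must be 2-dimensional")
        mask = self.observed_mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise DataValidationError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if not np.all(np.isfinite(values[mask])):
            raise DataValidationError("observed responses must be finite")
        obs = values[mask]
        if obs.size and not np.all(np.isin(obs, (0, 1))):
            bad = np.unique(obs[~np.isin(obs, (0, 1))])
            raise DataValidationError(
                f"binary responses must be 0/1; found {bad.tolist()}"
            )
        _check_coverage(mask)
        clean = np.where(mask, values, 0).astype(np.float64)
        object.__setattr__(self, "values", clean)
        object.__setattr__(self, "observed_mask", mask)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def with_cells_masked(self, rows: np.ndarray, cols: np.ndarray) -> "ResponseMatrix":
        """Return a copy with the given cells marked missing (for CV folds)."""
        mask = self.observed_mask.copy()
        mask[rows, cols] = False
        return ResponseMatrix(self.values.copy(), mask)


@dataclass(frozen=True)
class OrdinalResponseMatrix:
    """Ordinal person-by-item responses, coded 0..C_j-1 per item.

    Category counts may differ across items; when not supplied they are
    inferred as ``max observed code + 1`` per item.
    """

    values: np.ndarray
    observed_mask: np.ndarray = None  # type: ignore[assignment]
    categories: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataValidationError("response matrix must be 2-dimensional")
        mask = self.observed_mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise DataValidationError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        obs = values[mask]
        if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs < 0)):
            raise DataValidationError("ordinal responses must be nonnegative integers")
        if obs.size and np.any(obs != np.round(obs)):
            raise DataValidationError("ordinal responses must be integer-coded")
        _check_coverage(mask)
        clean = np.where(mask, values, 0).astype(np.int64)
        cats = self.categories
        if cats is None:
            cats = np.array(
                [
                    clean[mask[:, j], j].max() + 1 if mask[:, j].any() else 2
                    for j in range(clean.shape[1])
                ],
                dtype=np.int64,
            )
        else:
            cats = np.asarray(cats, dtype=np.int64)
            if cats.shape != (clean.shape[1],):
                raise DataValidationError("categories must have one entry per item")
            for j in range(clean.shape[1]):
                col = clean[mask[:, j], j]
                if col.size and col.max() >= cats[j]:
                    raise DataValidationError(
                        f"item {j}: observed code {col.max()} >= declared "
                        f"category count {cats[j]}"
                    )
        if np.any(cats < 2):
            raise DataValidationError("every item needs at least 2 categories")
        object.__setattr__(self, "values", clean)
        object.__setattr__(self, "observed_mask", mask)
        object.__setattr__(self, "categories", cats)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]
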