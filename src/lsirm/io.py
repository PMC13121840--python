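"""Reading response matrices and serializing fit results.

Data files are delimited text (CSV by default, TSV by ``.tsv`` extension)
with an optional header row of item names and an optional leading ID column.
Missing responses use a configurable code (default ``"NA"``).  Fit output is
a person table, an item table, and a JSON metadata record carrying the seed,
options, convergence information and the echelon conventions, so a run can
be reproduced bit-for-bit from its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataValidationError, OrdinalResponseMatrix, ResponseMatrix
from .estimators import LSIRMFit
from .ordinal import OrdinalItemParameters
from .selection import CVResult


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_response_matrix(
    path: str | Path,
    missing_code: str = "NA",
    ordinal: bool = False,
    header: bool = True,
    id_column: bool = True,
):
    """Read a person-by-item matrix from a delimited text file.

    Returns a :class:`ResponseMatrix` (binary mode) or
    :class:`OrdinalResponseMatrix` (ordinal mode).  Non-integer cells raise
    an error naming the offending position.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        header=0 if header else None,
        na_values=[missing_code],
        keep_default_na=False,
        dtype=str,
    )
    if id_column:
        df = df.iloc[:, 1:]
    values = np.zeros(df.shape, dtype=np.int64)
    mask = np.zeros(df.shape, dtype=bool)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if pd.isna(cell) or cell == "":
                continue
            try:
                values[i, j] = int(cell)
            except ValueError:
                raise DataValidationError(
                    f"non-integer cell {cell!r} at row {i}, column "
                    f"{df.columns[j]!r}"
                ) from None
            mask[i, j] = True
    if ordinal:
        return OrdinalResponseMatrix(values, mask)
    bad = np.argwhere(mask & ~np.isin(values, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise DataValidationError(
            f"binary mode: value {values[i, j]} at row {i}, column "
            f"{df.columns[j]!r} is not 0/1"
        )
    return ResponseMatrix(values, mask)


def write_response_matrix(
    Y, path: str | Path, missing_code: str = "NA"
) -> None:
    """Write a response matrix as CSV with an ID column and item headers."""
    path = Path(path)
    values = np.asarray(Y.values)
    df = pd.DataFrame(
        np.where(Y.observed_mask, values.astype(np.int64).astype(object), missing_code),
        columns=[f"item{j + 1}" for j in range(values.shape[1])],
    )
    df.insert(0, "person", np.arange(1, values.shape[0] + 1))
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_fit(
    fit: LSIRMFit,
    outdir: str | Path,
    ordinal_params: OrdinalItemParameters | None = None,
    prefix: str = "fit",
) -> dict[str, Path]:
    """Write person/item parameter tables (CSV) and run metadata (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    D = fit.config.n_dim

    person = pd.DataFrame({"theta": fit.theta})
    for d in range(D):
        person[f"z{d + 1}"] = fit.Z[:, d]
    person.insert(0, "person", np.arange(1, len(fit.theta) + 1))
    person_path = outdir / f"{prefix}_persons.csv"
    person.to_csv(person_path, index=False)

    if ordinal_params is None:
        item = pd.DataFrame({"beta": fit.beta})
        for d in range(D):
            item[f"w{d + 1}"] = fit.W[:, d]
        item.insert(0, "item", np.arange(1, len(fit.beta) + 1))
    else:
        n_max = max(len(t) for t in ordinal_params.thresholds)
        rows = {}
        for c in range(n_max):
            rows[f"threshold{c + 1}"] = [
                t[c] if c < len(t) else np.nan
                for t in ordinal_params.thresholds
            ]
        item = pd.DataFrame(rows)
        for d in range(D):
            item[f"w{d + 1}"] = fit.W[:, d]
        item.insert(0, "item", np.arange(1, fit.W.shape[0] + 1))
    item_path = outdir / f"{prefix}_items.csv"
    item.to_csv(item_path, index=False)

    meta = {
        "estimator": fit.options.estimator,
        "D": fit.options.D,
        "seed": fit.options.seed,
        "max_iter": fit.options.max_iter,
        "rel_tol": fit.options.rel_tol,
        "step_init": fit.options.step_init,
        "regularization": {
            "mode": fit.spec.mode,
            "lambda": fit.spec.lambda_,
            "C_person": fit.spec.C_person,
            "C_item": fit.spec.C_item,
        },
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "objective": fit.objective,
        "loglik_trace_first": float(fit.loglik_trace[0]),
        "loglik_trace_last": float(fit.loglik_trace[-1]),
        "echelon": {
            "anchor_items": list(range(fit.config.n_dim)),
            "sign_convention": "diagonal of anchor rows nonnegative",
            "sign_flips": fit.rotation.sign_flips.tolist(),
        },
    }
    meta_path = outdir / f"{prefix}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return {"persons": person_path, "items": item_path, "meta": meta_path}


def write_cv_result(cv: CVResult, outdir: str | Path, prefix: str = "cv"):
    """Write the CV totals table (CSV) and full result (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / f"{prefix}_table.csv"
    cv.table().to_csv(table_path)
    payload = {
        "K": cv.K,
        "seed": cv.seed,
        "D_candidates": list(cv.D_candidates),
        "selected_D": cv.selected_D,
        "totals": {f"D={D},{m}": v for (D, m), v in cv.totals.items()},
        "per_fold": {
            f"D={D},{m}": v.tolist() for (D, m), v in cv.per_fold.items()
        },
        "unconverged": [list(x) for x in cv.unconverged],
    }
    json_path = outdir / f"{prefix}_result.json"
    json_path.write_text(json.dumps(payload, indent=2))
    return {"table": table_path, "json": json_path}
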