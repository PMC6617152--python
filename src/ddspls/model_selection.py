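"""Leave-one-out cross-validation and (R, L0) grid search.

MSEP is reported on the full-sample standardized response scale, so 1.0 is
the mean-prediction reference level: values below 1 mean the cross-validated
model beats predicting the training average; values above 1 mean it does
not.  Everything (standardization, threshold, weights, regression) is refit
inside each fold — nothing from the held-out row leaks into selection.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import _fit_arrays, _predict_arrays
from .datasets import BlockDataset
from .errors import ParameterError, SchemaError

__all__ = ["CvGridResult", "loo_msep", "grid_search", "select_best"]

_TIE_TOL = 1e-12


def loo_msep(
    data: BlockDataset,
    R: int,
    L0: int,
    return_predictions: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Per-response leave-one-out MSEP at one (R, L0) grid point.

    Each row is predicted by a model refit on the other n-1 rows; squared
    errors are computed after scaling by the full-sample response standard
    deviation, so an intercept-only model scores exactly ``n / (n - 1)``.
    Optionally also returns the (n, q) LOO predictions in original units.
    """
    n = data.n
    if n < 3:
        raise SchemaError("leave-one-out needs n >= 3")
    # canonical row order (by ID) so the result is exactly invariant to row
    # permutation of the input dataset
    order = np.argsort(np.asarray(data.row_ids))
    X_list = [np.ascontiguousarray(X[order]) for X in data.blocks.values()]
    Y = np.ascontiguousarray(data.response[order])
    sd_full = Y.std(axis=0, ddof=1)
    sd_full = np.where(sd_full == 0.0, 1.0, sd_full)

    preds = np.empty_like(Y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        X_train = [X[mask] for X in X_list]
        fit = _fit_arrays(X_train, Y[mask], R, L0)
        preds[i] = _predict_arrays(fit, [X[i : i + 1] for X in X_list])[0]
        mask[i] = True

    msep = np.mean(((Y - preds) / sd_full) ** 2, axis=0)
    if return_predictions:
        inverse = np.empty_like(preds)
        inverse[order] = preds
        return msep, inverse
    return msep


@dataclass
class CvGridResult:
    """LOO MSEP surface over the (R, L0) grid plus the selected point."""

    grid: list[tuple[int, int]]  # (R, L0) pairs
    msep_per_response: np.ndarray  # (len(grid), q)
    msep_mean: np.ndarray  # (len(grid),)
    response_names: list[str]
    best: tuple[int, int]
    best_loo_predictions: np.ndarray  # (n, q), original units
    row_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid point per response, plus the mean."""
        rows = []
        for (R, L0), per_resp, mean in zip(
            self.grid, self.msep_per_response, self.msep_mean
        ):
            for name, v in zip(self.response_names, per_resp):
                rows.append({"R": R, "L0": L0, "response": name, "msep": v})
            rows.append({"R": R, "L0": L0, "response": "__mean__", "msep": mean})
        return pd.DataFrame(rows)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "grid": [list(g) for g in self.grid],
            "msep_per_response": self.msep_per_response.tolist(),
            "msep_mean": self.msep_mean.tolist(),
            "response_names": self.response_names,
            "best": list(self.best),
            "best_loo_predictions": self.best_loo_predictions.tolist(),
            "row_ids": self.row_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _argmin_with_ties(
    grid: list[tuple[int, int]], msep_mean: np.ndarray
) -> tuple[int, int]:
    best_val = float(np.min(msep_mean))
    tied = [g for g, v in zip(grid, msep_mean) if v <= best_val + _TIE_TOL]
    return min(tied, key=lambda g: (g[1], g[0]))  # smaller L0, then smaller R


def grid_search(
    data: BlockDataset,
    R_values: list[int] | None = None,
    L0_values: list[int] | None = None,
) -> CvGridResult:
    """Evaluate :func:`loo_msep` at every (R, L0) point and pick the best.

    Defaults: R in 1..q and L0 in 1..min(30, total covariate count).
    """
    if R_values is None:
        R_values = list(range(1, data.q + 1))
    if L0_values is None:
        L0_values = list(range(1, min(30, data.n_covariates) + 1))
    if not R_values or not L0_values:
        raise ParameterError("R_values and L0_values must be non-empty")
    if max(R_values) > data.q:
        raise ParameterError(f"max R {max(R_values)} exceeds q={data.q}")

    grid = [(R, L0) for R in R_values for L0 in L0_values]
    per_resp = np.empty((len(grid), data.q))
    for k, (R, L0) in enumerate(grid):
        per_resp[k] = loo_msep(data, R, L0)
    mean = per_resp.mean(axis=1)
    best = _argmin_with_ties(grid, mean)
    _, best_preds = loo_msep(data, best[0], best[1], return_predictions=True)
    return CvGridResult(
        grid=grid,
        msep_per_response=per_resp,
        msep_mean=mean,
        response_names=list(data.response_names),
        best=best,
        best_loo_predictions=best_preds,
        row_ids=list(data.row_ids),
    )


def select_best(result: CvGridResult) -> tuple[int, int]:
    """Argmin of mean MSEP; ties broken by smaller L0 then smaller R."""
    if not result.grid:
        raise ParameterError("empty grid result")
    return _argmin_with_ties(result.grid, result.msep_mean)
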