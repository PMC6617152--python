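"""Multi-block sparse PLS built on soft-thresholded cross-covariance SVDs.

The estimator works in three stages on standardized data:

1. Per block t, soft-threshold the cross-covariance ``Y' X_t / (n - 1)`` at a
   data-driven threshold ``lambda`` chosen so that the total number of
   surviving covariate columns across blocks meets the user budget ``L0``,
   then take its top-``R`` right singular vectors as block weights ``U_t``.
2. Aggregate the per-block component scores through a second, unthresholded
   application of the same construction ("super-weights" ``beta_t``),
   yielding ``R`` shared super-components.
3. Regress the standardized response on the super-components through the
   Moore-Penrose pseudo-inverse (no matrix inversion; rank-deficient score
   matrices are handled), giving per-block coefficient matrices ``B_t`` with
   exactly zero rows for unselected covariates, so that
   ``Y ~ sum_t X_t B_t``.

No deflation is used: all ``R`` components come from one R-dimensional SVD
per block, which bounds the usable component count by the rank of the
thresholded cross-covariance (itself at most ``q``).

A classical one-component NIPALS PLS is provided as an independent
equivalence oracle for the single-block, unthresholded case.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .datasets import BlockDataset, StandardizationParams, destandardize_predictions
from .errors import NoSignalError, ParameterError, SchemaError

__all__ = [
    "CrossCovariance",
    "DdsplsModel",
    "soft_threshold",
    "cross_covariance",
    "select_lambda",
    "block_weights",
    "super_weights",
    "fit_ddspls",
    "predict",
    "nipals_first_component",
    "save_model",
    "load_model",
]

_RCOND = 1e-10  # singular values below _RCOND * max are treated as zero


def soft_threshold(values: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Elementwise ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ParameterError(f"lambda must be >= 0, got {lam}")
    x = np.asarray(values, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
    return out if out.ndim else float(out)


@dataclass
class CrossCovariance:
    """Per-block cross-covariance ``Y' X_t / (n - 1)`` on standardized data."""

    matrices: dict[str, np.ndarray]  # block name -> (q, p_t)
    column_max: dict[str, np.ndarray]  # block name -> (p_t,) max |entry| per column

    @property
    def block_names(self) -> list[str]:
        return list(self.matrices)

    def all_column_max(self) -> np.ndarray:
        return np.concatenate([self.column_max[k] for k in self.matrices])


def cross_covariance(data: BlockDataset) -> CrossCovariance:
    """Cross-covariance of each (standardized) block with the response.

    With unit-variance columns the entries are Pearson correlations.
    """
    if data.n < 2:
        raise SchemaError("cross-covariance needs n >= 2")
    Y = data.response
    denom = data.n - 1
    matrices = {name: (Y.T @ X) / denom for name, X in data.blocks.items()}
    column_max = {name: np.abs(M).max(axis=0) for name, M in matrices.items()}
    return CrossCovariance(matrices=matrices, column_max=column_max)


def select_lambda(cc: CrossCovariance, L0: int) -> float:
    """Smallest threshold keeping at most ``L0`` covariate columns overall.

    Candidate thresholds are the distinct per-column max absolute
    cross-covariances; a column survives iff its max absolute entry strictly
    exceeds lambda.  When a count of exactly ``L0`` is attainable it is
    attained; under ties the largest attainable count <= ``L0`` results.
    """
    if L0 < 1:
        raise ParameterError(f"L0 must be >= 1, got {L0}")
    colmax = cc.all_column_max()
    if not np.any(colmax > 0):
        raise NoSignalError("all cross-covariance entries are zero")
    return _select_lambda_from_colmax(colmax, L0)


def _select_lambda_from_colmax(colmax: np.ndarray, L0: int) -> float:
    if L0 >= colmax.size or int(np.sum(colmax > 0)) <= L0:
        return 0.0
    for lam in np.unique(colmax):
        if int(np.sum(colmax > lam)) <= L0:
            return float(lam)
    return float(colmax.max())  # unreachable: count at max is 0


def _svd_weights(M: np.ndarray, R: int, rcond: float = _RCOND) -> np.ndarray:
    """Top-``R`` right singular vectors of ``M`` as columns of a (p, R) matrix.

    Columns beyond the numerical rank are zero.  Sign convention: the
    largest-magnitude entry of each column is positive.
    """
    p = M.shape[1]
    U = np.zeros((p, R))
    if not np.any(M):
        return U
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > rcond * s[0]))
    r = min(R, rank)
    V = Vt[:r].T
    for j in range(r):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    U[:, :r] = V
    return U


def block_weights(
    cc_thresholded: Mapping[str, np.ndarray], R: int
) -> dict[str, np.ndarray]:
    """Per-block (p_t, R) weight matrices from the thresholded cross-covariances."""
    if R < 1:
        raise ParameterError(f"R must be >= 1, got {R}")
    return {name: _svd_weights(M, R) for name, M in cc_thresholded.items()}


def super_weights(
    block_scores: np.ndarray, Y_std: np.ndarray, R: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Second-level weights gathering block scores into shared components.

    ``block_scores`` is the (n, T*R) concatenation of the per-block scores
    ``X_t U_t``.  The same SVD construction is applied one level up, without
    thresholding: the top-``R`` right singular vectors of
    ``Y' scores / (n - 1)`` are partitioned into T consecutive (R, R) slices,
    slice t being ``beta_t``.  Returns ``(per-block slices, stacked matrix)``.
    """
    n, total = block_scores.shape
    if Y_std.shape[0] != n:
        raise SchemaError("scores and response row counts differ")
    if total % R != 0:
        raise SchemaError(f"score column count {total} is not a multiple of R={R}")
    M = (Y_std.T @ block_scores) / (n - 1)
    stacked = _svd_weights(M, R)  # (T*R, R)
    T = total // R
    slices = [stacked[t * R : (t + 1) * R] for t in range(T)]
    return slices, stacked


class _CoreFit(NamedTuple):
    """Raw fitted state on arrays; names are attached by :func:`fit_ddspls`."""

    lam: float
    U: list[np.ndarray]  # per block (p_t, R)
    beta: list[np.ndarray]  # per block (R, R)
    C: np.ndarray  # (R, q) super-component regression
    B: list[np.ndarray]  # per block (p_t, q)
    selected_cols: list[np.ndarray]  # per block boolean (p_t,)
    selected_resp: np.ndarray  # boolean (q,)
    x_center: list[np.ndarray]
    x_scale: list[np.ndarray]
    y_center: np.ndarray
    y_scale: np.ndarray


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = X.mean(axis=0)
    s = X.std(axis=0, ddof=1)
    s = np.where(np.ptp(X, axis=0) == 0.0, 1.0, s)  # constant columns keep scale 1
    Z = (X - c) / s
    Z[:, np.ptp(X, axis=0) == 0.0] = 0.0
    return Z, c, s


def _fit_arrays(
    X_list: Sequence[np.ndarray], Y: np.ndarray, R: int, L0: int
) -> _CoreFit:
    """Fit on raw arrays: the fast path shared by the public API and LOO."""
    n, q = Y.shape
    if R > q:
        raise ParameterError(f"R={R} exceeds the number of responses q={q}")
    if L0 < 1:
        raise ParameterError(f"L0 must be >= 1, got {L0}")

    Xs, x_center, x_scale = [], [], []
    for X in X_list:
        Xz, c, s = _standardize_columns(np.asarray(X, float))
        Xs.append(Xz)
        x_center.append(c)
        x_scale.append(s)
    Yz, y_center, y_scale = _standardize_columns(np.asarray(Y, float))

    denom = n - 1
    cc = [(Yz.T @ Xz) / denom for Xz in Xs]
    colmax = [np.abs(M).max(axis=0) for M in cc]
    allmax = np.concatenate(colmax)

    if not np.any(allmax > 0):  # degenerate: intercept-only model
        lam = 0.0
        survivors = [np.zeros(m.size, bool) for m in colmax]
    else:
        lam = _select_lambda_from_colmax(allmax, L0)
        survivors = [m > lam for m in colmax]

    U: list[np.ndarray] = []
    thresholded: list[np.ndarray] = []
    for M, keep in zip(cc, survivors):
        S = np.sign(M) * np.maximum(np.abs(M) - lam, 0.0)
        S[:, ~keep] = 0.0  # exact zeros for dropped columns
        thresholded.append(S)
        Ut = _svd_weights(S, R)
        Ut[~keep, :] = 0.0
        U.append(Ut)

    scores = np.hstack([Xz @ Ut for Xz, Ut in zip(Xs, U)])  # (n, T*R)
    selected_resp = np.zeros(q, bool)
    for S in thresholded:
        selected_resp |= np.abs(S).sum(axis=1) > 0

    if np.any(scores):
        M2 = (Yz.T @ scores) / denom
        stacked = _svd_weights(M2, R)
        super_comp = scores @ stacked  # (n, R)
        C = np.linalg.pinv(super_comp, rcond=_RCOND) @ Yz
        C[:, ~selected_resp] = 0.0  # unselected responses fall back to their mean
    else:
        stacked = np.zeros((scores.shape[1], R))
        C = np.zeros((R, q))

    T = len(X_list)
    beta = [stacked[t * R : (t + 1) * R] for t in range(T)]
    B = []
    selected_cols = []
    for Ut, bt, keep in zip(U, beta, survivors):
        Bt = Ut @ bt @ C
        Bt[~keep, :] = 0.0
        B.append(Bt)
        selected_cols.append(np.abs(Bt).sum(axis=1) > 0)
    return _CoreFit(
        lam=lam,
        U=U,
        beta=beta,
        C=C,
        B=B,
        selected_cols=selected_cols,
        selected_resp=selected_resp,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
    )


def _predict_arrays(fit: _CoreFit, X_list: Sequence[np.ndarray]) -> np.ndarray:
    """Predict responses (original units) for raw covariate arrays."""
    pred = np.zeros((np.asarray(X_list[0]).shape[0], fit.C.shape[1]))
    for X, c, s, Bt in zip(X_list, fit.x_center, fit.x_scale, fit.B):
        pred += ((np.asarray(X, float) - c) / s) @ Bt
    return pred * fit.y_scale + fit.y_center


@dataclass
class DdsplsModel:
    """Fitted multi-block sparse PLS model.

    ``regression[t]`` maps the standardized block t to the standardized
    response; rows for unselected covariates are exactly zero.
    """

    R: int
    L0: int
    lambda_: float
    block_names: list[str]
    block_column_names: dict[str, list[str]]
    response_names: list[str]
    block_weights: dict[str, np.ndarray]
    super_weights: dict[str, np.ndarray]
    regression: dict[str, np.ndarray]
    component_regression: np.ndarray  # (R, q)
    selected_covariates: set[tuple[str, str]]
    selected_responses: set[str]
    training_params: StandardizationParams

    @property
    def n_selected(self) -> int:
        return len(self.selected_covariates)

    def selected_by_block(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {name: [] for name in self.block_names}
        for block, col in self.selected_covariates:
            out[block].append(col)
        for cols, name in zip(out.values(), out):
            cols.sort(key=self.block_column_names[name].index)
        return out

    def predict(self, new_blocks: "BlockDataset | Mapping[str, np.ndarray]") -> np.ndarray:
        return predict(self, new_blocks)


def fit_ddspls(data: BlockDataset, R: int, L0: int) -> DdsplsModel:
    """Fit the full pipeline: standardize, threshold, SVD weights, regression.

    If no covariate column survives thresholding the model degenerates to
    intercept-only (predicting training means) — a valid model, not an error.
    """
    fit = _fit_arrays(list(data.blocks.values()), data.response, R, L0)
    names = data.block_names
    params = StandardizationParams(
        block_center={k: c for k, c in zip(names, fit.x_center)},
        block_scale={k: s for k, s in zip(names, fit.x_scale)},
        block_constant={
            k: data.blocks[k].std(axis=0, ddof=1) == 0.0 for k in names
        },
        response_center=fit.y_center,
        response_scale=fit.y_scale,
        response_constant=data.response.std(axis=0, ddof=1) == 0.0,
    )
    selected = {
        (name, data.block_column_names[name][j])
        for name, keep in zip(names, fit.selected_cols)
        for j in np.flatnonzero(keep)
    }
    return DdsplsModel(
        R=R,
        L0=L0,
        lambda_=fit.lam,
        block_names=names,
        block_column_names={k: list(v) for k, v in data.block_column_names.items()},
        response_names=list(data.response_names),
        block_weights={k: U for k, U in zip(names, fit.U)},
        super_weights={k: b for k, b in zip(names, fit.beta)},
        regression={k: B for k, B in zip(names, fit.B)},
        component_regression=fit.C,
        selected_covariates=selected,
        selected_responses={
            data.response_names[m] for m in np.flatnonzero(fit.selected_resp)
        },
        training_params=params,
    )


def predict(
    model: DdsplsModel, new_blocks: "BlockDataset | Mapping[str, np.ndarray]"
) -> np.ndarray:
    """Predict responses in original units for new rows.

    Responses with no contributing selected covariate are predicted by the
    constant training mean.
    """
    if isinstance(new_blocks, BlockDataset):
        for name in model.block_names:
            if name not in new_blocks.blocks:
                raise SchemaError(f"missing block {name!r}")
            if new_blocks.block_column_names[name] != model.block_column_names[name]:
                raise SchemaError(f"block {name!r} columns differ from training data")
        mats = {name: new_blocks.blocks[name] for name in model.block_names}
    else:
        mats = {}
        for name in model.block_names:
            if name not in new_blocks:
                raise SchemaError(f"missing block {name!r}")
            X = np.asarray(new_blocks[name], float)
            if X.shape[1] != len(model.block_column_names[name]):
                raise SchemaError(f"block {name!r} has wrong column count")
            mats[name] = X

    p = model.training_params
    pred = np.zeros((next(iter(mats.values())).shape[0], len(model.response_names)))
    for name in model.block_names:
        Xz = (mats[name] - p.block_center[name]) / p.block_scale[name]
        pred += Xz @ model.regression[name]
    return destandardize_predictions(pred, p)


def nipals_first_component(
    X: np.ndarray, Y: np.ndarray, tol: float = 1e-12, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """First PLS component by NIPALS: returns ``(u, v, t, s)``.

    Iterates to the leading pair of ``Y'X`` under unit-norm constraints on
    both weights; ``t = X u`` and ``s = Y v`` are the component scores.
    Used as an independent oracle for the unthresholded single-block case.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 2:
        raise SchemaError("X and Y must share n >= 2 rows")
    if Y.ndim == 1:
        Y = Y[:, None]
    if not np.any(Y.T @ X):
        raise NoSignalError("Y'X is identically zero")

    # start from the Y column with the largest variance
    s = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not np.any(s):
        s = Y[:, 0] + 1.0
    u = np.zeros(X.shape[1])
    for _ in range(max_iter):
        u_new = X.T @ s
        u_new /= np.linalg.norm(u_new)
        t = X @ u_new
        v = Y.T @ t
        v /= np.linalg.norm(v)
        s = Y @ v
        if np.linalg.norm(u_new - u) < tol:
            u = u_new
            break
        u = u_new
    t = X @ u
    v = Y.T @ t
    v /= np.linalg.norm(v)
    s = Y @ v
    return u, v, t, s


# -- serialization ------------------------------------------------------------


def save_model(model: DdsplsModel, path: str | os.PathLike) -> None:
    """Serialize a fitted model to JSON (loadable bit-for-bit)."""
    payload = {
        "R": model.R,
        "L0": model.L0,
        "lambda": model.lambda_,
        "block_names": model.block_names,
        "block_column_names": model.block_column_names,
        "response_names": model.response_names,
        "block_weights": {k: v.tolist() for k, v in model.block_weights.items()},
        "super_weights": {k: v.tolist() for k, v in model.super_weights.items()},
        "regression": {k: v.tolist() for k, v in model.regression.items()},
        "component_regression": model.component_regression.tolist(),
        "selected_covariates": sorted(map(list, model.selected_covariates)),
        "selected_responses": sorted(model.selected_responses),
        "training_params": model.training_params.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | os.PathLike) -> DdsplsModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return DdsplsModel(
        R=d["R"],
        L0=d["L0"],
        lambda_=d["lambda"],
        block_names=d["block_names"],
        block_column_names=d["block_column_names"],
        response_names=d["response_names"],
        block_weights={k: np.asarray(v, float) for k, v in d["block_weights"].items()},
        super_weights={k: np.asarray(v, float) for k, v in d["super_weights"].items()},
        regression={k: np.asarray(v, float) for k, v in d["regression"].items()},
        component_regression=np.asarray(d["component_regression"], float),
        selected_covariates={(b, c) for b, c in d["selected_covariates"]},
        selected_responses=set(d["selected_responses"]),
        training_params=StandardizationParams.from_dict(d["training_params"]),
    )
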