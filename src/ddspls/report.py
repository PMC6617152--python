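"""Selection reports, goodness of fit, and the standard plots.

The report lists, per response, the selected biomarkers with their block of
origin and coefficient sign (so block-of-origin vs predicted-response
patterns are visible), flags responses predicted as constants, and reports
training R-squared alongside a cross-validated R-squared derived from the
LOO MSEP — the two are labelled and never conflated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DdsplsModel, predict
from .datasets import BlockDataset
from .errors import DegenerateInputError, SchemaError
from .model_selection import CvGridResult

__all__ = ["SelectionReport", "r_squared", "build_selection_report", "plot_all"]


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """1 - SSE/SST on the original scale; negative for bad models."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise SchemaError("observed and predicted must have equal length")
    if observed.size < 2:
        raise SchemaError("need at least 2 points")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateInputError("observed response is constant")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


@dataclass
class SelectionReport:
    """Per-response selection table with signs, R-squared and model metadata."""

    selections: dict[str, list[dict]]
    # response -> [{block, covariate, coefficient, sign}], standardized scale
    r2_train: dict[str, float]
    r2_cv: dict[str, float]  # from LOO MSEP; empty if no CV result given
    constant_responses: list[str]  # predicted as a constant (no selected input)
    R: int
    L0: int
    lambda_: float
    block_response_table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for resp, entries in self.selections.items():
            for e in entries:
                rows.append({"response": resp, **e})
        return pd.DataFrame(
            rows, columns=["response", "block", "covariate", "coefficient", "sign"]
        )

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "R": self.R,
            "L0": self.L0,
            "lambda": self.lambda_,
            "selections": self.selections,
            "r2_train": self.r2_train,
            "r2_cv": self.r2_cv,
            "constant_responses": self.constant_responses,
            "block_response_counts": (
                {
                    resp: {b: int(v) for b, v in col.items()}
                    for resp, col in self.block_response_table.to_dict().items()
                }
                if self.block_response_table is not None
                else {}
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def build_selection_report(
    model: DdsplsModel,
    data: BlockDataset,
    cv: CvGridResult | None = None,
) -> SelectionReport:
    """Extract non-zero coefficient rows, signs and R-squared from a fit."""
    preds = predict(model, data)
    selections: dict[str, list[dict]] = {}
    r2_train: dict[str, float] = {}
    constant: list[str] = []
    counts = pd.DataFrame(
        0, index=model.block_names, columns=model.response_names, dtype=int
    )
    for m, resp in enumerate(model.response_names):
        entries = []
        for block in model.block_names:
            Bt = model.regression[block]
            for j in np.flatnonzero(Bt[:, m] != 0.0):
                coef = float(Bt[j, m])
                entries.append(
                    {
                        "block": block,
                        "covariate": model.block_column_names[block][j],
                        "coefficient": coef,
                        "sign": "+" if coef > 0 else "-",
                    }
                )
                counts.loc[block, resp] += 1
        selections[resp] = entries
        if not entries:
            constant.append(resp)
        if data.response[:, m].std() == 0:
            r2_train[resp] = float("nan")
        else:
            r2_train[resp] = r_squared(data.response[:, m], preds[:, m])

    r2_cv: dict[str, float] = {}
    if cv is not None:
        k = cv.grid.index((model.R, model.L0)) if (model.R, model.L0) in cv.grid else None
        if k is not None:
            n = data.n
            null_level = n / (n - 1)  # LOO MSEP of the mean-only model
            for m, resp in enumerate(model.response_names):
                r2_cv[resp] = 1.0 - cv.msep_per_response[k, m] / null_level
    return SelectionReport(
        selections=selections,
        r2_train=r2_train,
        r2_cv=r2_cv,
        constant_responses=constant,
        R=model.R,
        L0=model.L0,
        lambda_=model.lambda_,
        block_response_table=counts,
    )


# -- plots --------------------------------------------------------------------


def plot_all(
    cv: CvGridResult,
    model: DdsplsModel,
    data: BlockDataset,
    report: SelectionReport,
    directory: str | os.PathLike,
) -> list[str]:
    """MSEP-vs-L0 curves, predicted-vs-observed, and coefficient bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(directory, exist_ok=True)
    paths = []

    # MSEP curves: one panel per response plus the mean, one line per R
    q = len(cv.response_names)
    fig, axes = plt.subplots(1, q + 1, figsize=(3 * (q + 1), 3), sharey=True)
    R_values = sorted({R for R, _ in cv.grid})
    for ax, (m, title) in zip(
        np.atleast_1d(axes),
        list(enumerate(cv.response_names)) + [(None, "mean")],
    ):
        for R in R_values:
            pts = [
                (L0, cv.msep_mean[k] if m is None else cv.msep_per_response[k, m])
                for k, (r_, L0) in enumerate(cv.grid)
                if r_ == R
            ]
            pts.sort()
            ax.plot([p[0] for p in pts], [p[1] for p in pts], marker="o", ms=2, label=f"R={R}")
        ax.axhline(1.0, color="grey", lw=0.5, ls="--")
        ax.set_title(title)
        ax.set_xlabel("L0")
    np.atleast_1d(axes)[0].set_ylabel("LOO MSEP (standardized)")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    p = os.path.join(directory, "msep_curves.png")
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # predicted vs observed (LOO predictions of the best model)
    fig, axes = plt.subplots(1, q, figsize=(3 * q, 3))
    for m, ax in zip(range(q), np.atleast_1d(axes)):
        obs = data.response[:, m]
        pred = cv.best_loo_predictions[:, m]
        ax.scatter(obs, pred, s=12)
        lo, hi = min(obs.min(), pred.min()), max(obs.max(), pred.max())
        ax.plot([lo, hi], [lo, hi], color="grey", lw=0.5)
        ax.set_title(cv.response_names[m])
        ax.set_xlabel("observed")
    np.atleast_1d(axes)[0].set_ylabel("LOO predicted")
    p = os.path.join(directory, "predicted_vs_observed.png")
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    # coefficient bars per response with any selection
    active = [r for r, e in report.selections.items() if e]
    if active:
        fig, axes = plt.subplots(1, len(active), figsize=(4 * len(active), 3))
        for ax, resp in zip(np.atleast_1d(axes), active):
            entries = report.selections[resp]
            labels = [f"{e['block']}:{e['covariate']}" for e in entries]
            vals = [e["coefficient"] for e in entries]
            ax.barh(labels, vals)
            ax.axvline(0, color="k", lw=0.5)
            ax.set_title(resp)
            ax.tick_params(labelsize=7)
        p = os.path.join(directory, "coefficients.png")
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
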