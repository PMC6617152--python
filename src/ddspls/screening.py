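"""Univariate screening: Pearson correlation screens and one-way ANOVA.

The correlation screen computes every covariate x response Pearson r with a
two-sided p-value, and retains pairs with |r| >= threshold (inclusive;
default 0.55).  Pairs where the covariate's block shares its name with the
response (same-muscle pairs) are flagged separately from cross-block pairs.
The magnitude rule and the p-values are reported side by side, never merged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import BlockDataset
from .errors import DegenerateInputError, ParameterError, SchemaError

__all__ = ["CorrelationScreen", "pearson_screen", "anova_one_way"]


@dataclass
class CorrelationScreen:
    """All covariate x response correlations plus the retained pairs."""

    table: pd.DataFrame
    # columns: block, covariate, response, r, p, within_block, retained
    threshold: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def matrix(self, block: str) -> pd.DataFrame:
        """(p_t x q) correlation matrix for one block."""
        sub = self.table[self.table["block"] == block]
        return sub.pivot(index="covariate", columns="response", values="r")

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False)


def pearson_screen(data: BlockDataset, threshold: float = 0.55) -> CorrelationScreen:
    """Correlate every covariate with every response; retain |r| >= threshold.

    Zero-variance columns yield undefined (NaN) correlations which are never
    retained.
    """
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    if data.n < 3:
        raise SchemaError("Pearson screen needs n >= 3")
    n = data.n
    Y = data.response
    y_const = np.ptp(Y, axis=0) == 0.0
    y_sd = np.where(y_const, 1.0, Y.std(axis=0, ddof=1))
    Yz = (Y - Y.mean(axis=0)) / y_sd

    rows = []
    for block, X in data.blocks.items():
        x_const = np.ptp(X, axis=0) == 0.0
        x_sd = np.where(x_const, 1.0, X.std(axis=0, ddof=1))
        Xz = (X - X.mean(axis=0)) / x_sd
        r_mat = (Xz.T @ Yz) / (n - 1)  # (p_t, q)
        r_mat = np.clip(r_mat, -1.0, 1.0)
        undef = x_const[:, None] | y_const[None, :]
        r_mat = np.where(undef, np.nan, r_mat)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = r_mat * np.sqrt((n - 2) / np.maximum(1 - r_mat**2, 1e-300))
        p_mat = 2 * stats.t.sf(np.abs(t_stat), df=n - 2)
        for j, cov in enumerate(data.block_column_names[block]):
            for m, resp in enumerate(data.response_names):
                r = r_mat[j, m]
                rows.append(
                    {
                        "block": block,
                        "covariate": cov,
                        "response": resp,
                        "r": r,
                        "p": np.nan if np.isnan(r) else p_mat[j, m],
                        "within_block": block == resp,
                        "retained": bool(not np.isnan(r) and abs(r) >= threshold),
                    }
                )
    return CorrelationScreen(table=pd.DataFrame(rows), threshold=threshold)


def anova_one_way(values, groups) -> tuple[float, float, dict[str, float]]:
    """Classical one-way ANOVA: returns (F, p, per-group means)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise SchemaError("values and groups must have the same length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DegenerateInputError("one-way ANOVA needs at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise DegenerateInputError("every group needs at least 2 observations")
    if all(np.allclose(s, s[0]) for s in samples):
        raise DegenerateInputError("zero within-group variance everywhere")
    f_stat, p_value = stats.f_oneway(*samples)
    means = {str(g): float(s.mean()) for g, s in zip(labels, samples)}
    return float(f_stat), float(p_value), means
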