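"""Multi-block data model, CSV I/O and standardization.

A :class:`BlockDataset` holds several covariate matrices ("blocks") that
describe the same individuals, together with a multivariate response.  All
downstream stages (screening, model fitting, cross-validation) consume this
object.  Standardization (zero mean, unit variance with the n-1 denominator)
is performed through :func:`standardize`, which records enough information in
:class:`StandardizationParams` to map predictions back to original units.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, MissingDataError, SchemaError

__all__ = [
    "BlockDataset",
    "StandardizationParams",
    "read_block_dataset",
    "read_wide_dataset",
    "write_block_dataset",
    "standardize",
    "destandardize_predictions",
]


@dataclass
class BlockDataset:
    """Named covariate blocks sharing rows, plus a response matrix.

    Parameters
    ----------
    blocks
        Ordered mapping block name -> (n, p_t) float array.
    block_column_names
        Per block, the p_t column (biomarker) names.
    response
        (n, q) float array of response values in original units.
    response_names
        The q response names.
    row_ids
        The n individual identifiers, in row order.
    """

    blocks: dict[str, np.ndarray]
    block_column_names: dict[str, list[str]]
    response: np.ndarray
    response_names: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.blocks = {k: np.asarray(v, dtype=float) for k, v in self.blocks.items()}
        self.response = np.asarray(self.response, dtype=float)
        if self.response.ndim != 2:
            raise SchemaError("response must be a 2-D matrix")
        n = self.response.shape[0]
        if n < 3:
            raise SchemaError(f"need at least 3 rows, got {n}")
        self.row_ids = [str(r) for r in self.row_ids]
        if len(self.row_ids) != n:
            raise SchemaError("row_ids length does not match response rows")
        if len(set(self.row_ids)) != n:
            raise SchemaError("row_ids must be unique")
        if len(self.response_names) != self.response.shape[1]:
            raise SchemaError("response_names length does not match response columns")
        if len(set(self.response_names)) != len(self.response_names):
            raise SchemaError("duplicate response names")
        if not self.blocks:
            raise SchemaError("at least one covariate block is required")
        for name, X in self.blocks.items():
            if X.ndim != 2 or X.shape[1] < 1:
                raise SchemaError(f"block {name!r} must be a 2-D matrix with >= 1 column")
            if X.shape[0] != n:
                raise AlignmentError(
                    f"block {name!r} has {X.shape[0]} rows, expected {n}"
                )
            cols = self.block_column_names.get(name)
            if cols is None or len(cols) != X.shape[1]:
                raise SchemaError(f"column names for block {name!r} missing or wrong length")
            if len(set(cols)) != len(cols):
                dupes = sorted({c for c in cols if cols.count(c) > 1})
                raise SchemaError(f"duplicate column names in block {name!r}: {dupes}")
            if not np.isfinite(X).all():
                raise MissingDataError(f"block {name!r} contains missing/non-finite values")
        if not np.isfinite(self.response).all():
            raise MissingDataError("response contains missing/non-finite values")

    # -- convenience accessors ------------------------------------------------

    @property
    def n(self) -> int:
        return self.response.shape[0]

    @property
    def q(self) -> int:
        return self.response.shape[1]

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    @property
    def block_sizes(self) -> list[int]:
        return [X.shape[1] for X in self.blocks.values()]

    @property
    def n_covariates(self) -> int:
        return sum(self.block_sizes)

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "BlockDataset":
        """Return a new dataset restricted to (and reordered by) ``index``."""
        idx = np.asarray(index)
        return BlockDataset(
            blocks={k: X[idx] for k, X in self.blocks.items()},
            block_column_names={k: list(v) for k, v in self.block_column_names.items()},
            response=self.response[idx],
            response_names=list(self.response_names),
            row_ids=[self.row_ids[i] for i in idx],
        )

    def equals(self, other: "BlockDataset", atol: float = 0.0) -> bool:
        if (
            self.block_names != other.block_names
            or self.response_names != other.response_names
            or self.row_ids != other.row_ids
            or self.block_column_names != other.block_column_names
        ):
            return False
        if not np.allclose(self.response, other.response, atol=atol, rtol=0):
            return False
        return all(
            np.allclose(self.blocks[k], other.blocks[k], atol=atol, rtol=0)
            for k in self.blocks
        )


@dataclass
class StandardizationParams:
    """Per-column centers/scales of every block and of the response.

    ``scale`` is the sample standard deviation (n-1 denominator); constant
    columns keep scale 1 and are flagged so they can be recognised later.
    """

    block_center: dict[str, np.ndarray]
    block_scale: dict[str, np.ndarray]
    block_constant: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    response_center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    response_scale: np.ndarray = field(default_factory=lambda: np.ones(0))
    response_constant: np.ndarray = field(repr=False, default_factory=lambda: np.zeros(0, bool))

    def to_dict(self) -> dict:
        return {
            "block_center": {k: v.tolist() for k, v in self.block_center.items()},
            "block_scale": {k: v.tolist() for k, v in self.block_scale.items()},
            "block_constant": {k: v.astype(int).tolist() for k, v in self.block_constant.items()},
            "response_center": self.response_center.tolist(),
            "response_scale": self.response_scale.tolist(),
            "response_constant": self.response_constant.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StandardizationParams":
        return cls(
            block_center={k: np.asarray(v, float) for k, v in d["block_center"].items()},
            block_scale={k: np.asarray(v, float) for k, v in d["block_scale"].items()},
            block_constant={k: np.asarray(v, bool) for k, v in d["block_constant"].items()},
            response_center=np.asarray(d["response_center"], float),
            response_scale=np.asarray(d["response_scale"], float),
            response_constant=np.asarray(d["response_constant"], bool),
        )


def _center_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # ptp is an exact constancy test; sd == 0 is float-fragile
    constant = np.ptp(X, axis=0) == 0.0
    scale = np.where(constant, 1.0, sd)
    return center, scale, constant


def standardize(data: BlockDataset) -> tuple[BlockDataset, StandardizationParams]:
    """Center and scale every column of every block and of the response.

    Non-constant columns end up with mean 0 and unit sample standard
    deviation; constant columns are centered only and flagged.
    """
    b_center: dict[str, np.ndarray] = {}
    b_scale: dict[str, np.ndarray] = {}
    b_const: dict[str, np.ndarray] = {}
    new_blocks: dict[str, np.ndarray] = {}
    for name, X in data.blocks.items():
        c, s, flag = _center_scale(X)
        b_center[name], b_scale[name], b_const[name] = c, s, flag
        Z = (X - c) / s
        Z[:, flag] = 0.0  # exact zeros for constant columns
        new_blocks[name] = Z
    yc, ys, yflag = _center_scale(data.response)
    params = StandardizationParams(
        block_center=b_center,
        block_scale=b_scale,
        block_constant=b_const,
        response_center=yc,
        response_scale=ys,
        response_constant=yflag,
    )
    Yz = (data.response - yc) / ys
    Yz[:, yflag] = 0.0
    std = BlockDataset(
        blocks=new_blocks,
        block_column_names={k: list(v) for k, v in data.block_column_names.items()},
        response=Yz,
        response_names=list(data.response_names),
        row_ids=list(data.row_ids),
    )
    return std, params


def destandardize_predictions(
    pred: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Map standardized response predictions back to original units."""
    pred = np.asarray(pred, dtype=float)
    if pred.ndim != 2 or pred.shape[1] != params.response_center.shape[0]:
        raise SchemaError(
            f"prediction has {pred.shape[-1] if pred.ndim else 0} columns, "
            f"expected {params.response_center.shape[0]}"
        )
    return pred * params.response_scale + params.response_center


# -- CSV I/O ------------------------------------------------------------------


def _read_indexed_csv(path: str | os.PathLike) -> pd.DataFrame:
    # pandas silently renames duplicate headers; check the raw header line
    with open(path, encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise SchemaError(f"{path}: duplicate column names {dupes}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected an ID column plus data columns")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        raise AlignmentError(f"{path}: duplicate IDs {sorted(df[id_col][df[id_col].duplicated()])}")
    return df.set_index(id_col)


def _frame_to_matrix(df: pd.DataFrame, what: str) -> np.ndarray:
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise MissingDataError(f"{what}: empty cells in columns {bad}")
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{what}: non-numeric values ({exc})") from exc


def read_block_dataset(
    response_path: str | os.PathLike,
    block_paths: Mapping[str, str | os.PathLike],
) -> BlockDataset:
    """Read one CSV per block plus a response CSV into a :class:`BlockDataset`.

    Every file needs a header row whose first column is the individual ID.
    Row order is taken from the response file; block rows are matched by ID.
    """
    resp = _read_indexed_csv(response_path)
    row_ids = list(resp.index)
    blocks: dict[str, np.ndarray] = {}
    col_names: dict[str, list[str]] = {}
    for name, path in block_paths.items():
        df = _read_indexed_csv(path)
        missing = [i for i in row_ids if i not in df.index]
        extra = [i for i in df.index if i not in resp.index]
        if missing or extra:
            raise AlignmentError(
                f"block {name!r}: IDs missing from block file {missing}; "
                f"IDs absent from response {extra}"
            )
        df = df.loc[row_ids]
        if df.columns.duplicated().any():
            raise SchemaError(
                f"block {name!r}: duplicate column names "
                f"{sorted(set(df.columns[df.columns.duplicated()]))}"
            )
        blocks[name] = _frame_to_matrix(df, f"block {name!r}")
        col_names[name] = list(df.columns)
    return BlockDataset(
        blocks=blocks,
        block_column_names=col_names,
        response=_frame_to_matrix(resp, "response"),
        response_names=list(resp.columns),
        row_ids=row_ids,
    )


def read_wide_dataset(
    path: str | os.PathLike,
    block_map: Mapping[str, Iterable[str]],
    response_columns: Iterable[str],
) -> BlockDataset:
    """Read a single wide CSV; ``block_map`` assigns columns to named blocks."""
    df = _read_indexed_csv(path)
    response_columns = list(response_columns)
    assigned: list[str] = []
    for cols in block_map.values():
        assigned.extend(cols)
    if len(set(assigned)) != len(assigned):
        raise SchemaError("block_map assigns a column to more than one block")
    for col in assigned + response_columns:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not present in {path}")
    blocks = {
        name: _frame_to_matrix(df[list(cols)], f"block {name!r}")
        for name, cols in block_map.items()
    }
    return BlockDataset(
        blocks=blocks,
        block_column_names={name: list(cols) for name, cols in block_map.items()},
        response=_frame_to_matrix(df[response_columns], "response"),
        response_names=response_columns,
        row_ids=list(df.index),
    )


def write_block_dataset(
    data: BlockDataset,
    directory: str | os.PathLike,
    id_column: str = "id",
) -> dict[str, str]:
    """Write one CSV per block plus ``response.csv``; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(name: str, matrix: np.ndarray, columns: list[str]) -> str:
        out = os.path.join(directory, f"{name}.csv")
        frame = pd.DataFrame(matrix, columns=columns)
        frame.insert(0, id_column, data.row_ids)
        frame.to_csv(out, index=False)
        return out

    for name, X in data.blocks.items():
        paths[name] = _write(name, X, data.block_column_names[name])
    paths["response"] = _write("response", data.response, data.response_names)
    return paths
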