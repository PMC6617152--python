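"""Synthetic multi-block data with known sparse low-rank structure.

The generator plants ``r_true`` latent factors: each factor loads on a small
index set of covariates per block ("support") and drives a subset of
responses.  Inactive covariates are pure noise.  The returned
:class:`GroundTruth` records everything needed for recovery, sign and
independence tests.

``study_preset`` emulates the 5-muscle x 20-biomarker dot-blot design with an
extra 2-column performance block (age/weight) carrying no signal and five
tenderness-like responses on a 0-100 scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .datasets import BlockDataset
from .errors import ParameterError

__all__ = ["SyntheticSpec", "GroundTruth", "generate_multiblock", "study_preset"]

MUSCLES = ["GB", "SM", "ST", "TB", "VL"]

# Antibody panel of the emulated design, grouped by biological function
# (heat-shock, oxidative resistance, structure, metabolism, signaling,
# proteolysis).
PROTEIN_NAMES = [
    "alphaB-crystallin",
    "Hsp20",
    "Hsp27",
    "Hsp40",
    "Hsp70-8",
    "Hsp70-1b",
    "GRP75",
    "Dj1",
    "PRDX6",
    "SOD1",
    "MyBP-H",
    "Mylc-1f",
    "MyHC-IIx",
    "ENO3",
    "h2afx",
    "PGM1",
    "TP53",
    "alpha-actin",
    "m-calpain",
    "mu-calpain",
]

# Mean relative dot-blot abundances per muscle (ST, SM, GB, TB, VL), used
# only by the optional cosmetic abundance rescaling.
ABUNDANCE_MEANS: dict[str, dict[str, float]] = {
    "Hsp20": dict(ST=95, SM=150, GB=152, TB=99, VL=68),
    "Hsp27": dict(ST=101, SM=129, GB=118, TB=111, VL=86),
    "Hsp40": dict(ST=118, SM=162, GB=112, TB=117, VL=99),
    "Hsp70-8": dict(ST=105, SM=141, GB=123, TB=129, VL=156),
    "Hsp70-1b": dict(ST=85, SM=188, GB=155, TB=146, VL=81),
    "GRP75": dict(ST=119, SM=153, GB=147, TB=155, VL=122),
    "alphaB-crystallin": dict(ST=147, SM=195, GB=211, TB=153, VL=156),
    "Dj1": dict(ST=95, SM=125, GB=110, TB=114, VL=101),
    "PRDX6": dict(ST=97, SM=110, GB=110, TB=110, VL=115),
    "SOD1": dict(ST=79, SM=95, GB=68, TB=62, VL=58),
    "MyBP-H": dict(ST=102, SM=128, GB=140, TB=144, VL=101),
    "Mylc-1f": dict(ST=78, SM=109, GB=74, TB=89, VL=47),
    "MyHC-IIx": dict(ST=27, SM=33, GB=28, TB=29, VL=45),
    "ENO3": dict(ST=103, SM=134, GB=121, TB=133, VL=83),
    "h2afx": dict(ST=137, SM=173, GB=127, TB=139, VL=226),
    "PGM1": dict(ST=121, SM=165, GB=132, TB=132, VL=306),
    "TP53": dict(ST=106, SM=142, GB=94, TB=104, VL=153),
    "alpha-actin": dict(ST=82, SM=89, GB=92, TB=96, VL=99),
    "m-calpain": dict(ST=106, SM=139, GB=120, TB=126, VL=214),
    "mu-calpain": dict(ST=123, SM=175, GB=136, TB=118, VL=134),
}


@dataclass
class SyntheticSpec:
    """Generator parameters; identical spec (incl. seed) => identical data.

    ``support[t][r]`` lists the active column indices of block ``t`` for
    factor ``r``; ``x_loadings`` holds the matching signed loading values.
    ``y_loadings[r][m]`` is the signed loading of factor ``r`` on response
    ``m`` (0 = that response carries no signal from the factor).
    """

    n: int
    block_sizes: list[int]
    q: int
    r_true: int
    support: list[list[list[int]]]
    x_loadings: list[list[list[float]]]
    y_loadings: list[list[float]]
    noise_sd_x: float = 0.1
    noise_sd_y: float = 0.1
    response_center: float = 50.0
    response_scale: float = 10.0
    seed: int = 0
    block_names: list[str] = field(default_factory=list)
    column_names: list[list[str]] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)
    abundance_scale: bool = False

    def __post_init__(self) -> None:
        T = len(self.block_sizes)
        if self.r_true < 1:
            raise ParameterError("r_true must be >= 1")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if len(self.support) != T or len(self.x_loadings) != T:
            raise ParameterError("support/x_loadings must have one entry per block")
        for t, (sup_t, load_t, p_t) in enumerate(
            zip(self.support, self.x_loadings, self.block_sizes)
        ):
            if len(sup_t) != self.r_true or len(load_t) != self.r_true:
                raise ParameterError(
                    f"block {t}: need one support/loading list per factor"
                )
            for r, (idx, vals) in enumerate(zip(sup_t, load_t)):
                if len(idx) != len(vals):
                    raise ParameterError(f"block {t} factor {r}: support/loading length mismatch")
                if any(j < 0 or j >= p_t for j in idx):
                    raise ParameterError(f"block {t} factor {r}: support index out of range")
        if len(self.y_loadings) != self.r_true or any(
            len(w) != self.q for w in self.y_loadings
        ):
            raise ParameterError("y_loadings must be r_true x q")
        if not self.block_names:
            self.block_names = [f"X{t + 1}" for t in range(T)]
        if not self.column_names:
            self.column_names = [
                [f"{b}_v{j + 1}" for j in range(p)]
                for b, p in zip(self.block_names, self.block_sizes)
            ]
        if not self.response_names:
            self.response_names = [f"Y{m + 1}" for m in range(self.q)]

    # block loading matrices A_t (p_t x r_true), zero off support
    def loading_matrices(self) -> list[np.ndarray]:
        mats = []
        for p_t, sup_t, load_t in zip(self.block_sizes, self.support, self.x_loadings):
            A = np.zeros((p_t, self.r_true))
            for r, (idx, vals) in enumerate(zip(sup_t, load_t)):
                A[list(idx), r] = vals
            mats.append(A)
        return mats

    def response_loading_matrix(self) -> np.ndarray:
        return np.asarray(self.y_loadings, dtype=float).T  # (q, r_true)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Planted structure: the oracle for recovery and sign tests."""

    factor_scores: np.ndarray  # (n, r_true)
    active_set: set[tuple[str, str]]  # (block name, column name)
    signal_responses: set[str]  # responses that carry planted signal
    coefficient_signs: dict[tuple[str, str, str], int]
    # (block, column, response) -> sign of the true standardized coefficient

    def signs_for_response(self, response: str) -> dict[tuple[str, str], int]:
        return {
            (b, c): s
            for (b, c, m), s in self.coefficient_signs.items()
            if m == response
        }


def generate_multiblock(spec: SyntheticSpec) -> tuple[BlockDataset, GroundTruth]:
    """Draw one dataset from the planted factor model.

    ``X_t = Z A_t' + noise`` and ``Y = (Z W' + noise) * scale + center`` with
    standard-normal factor scores ``Z``.
    """
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n, spec.r_true))
    A = spec.loading_matrices()
    W = spec.response_loading_matrix()  # (q, r_true)

    blocks: dict[str, np.ndarray] = {}
    for name, p_t, A_t in zip(spec.block_names, spec.block_sizes, A):
        X = Z @ A_t.T + spec.noise_sd_x * rng.standard_normal((spec.n, p_t))
        blocks[name] = X
    Y = Z @ W.T + spec.noise_sd_y * rng.standard_normal((spec.n, spec.q))
    Y = Y * spec.response_scale + spec.response_center

    if spec.abundance_scale:
        for name, cols in zip(spec.block_names, spec.column_names):
            means = np.array(
                [
                    ABUNDANCE_MEANS.get(c, {}).get(name, 100.0)
                    for c in cols
                ]
            )
            blocks[name] = means + 0.1 * means * blocks[name]

    data = BlockDataset(
        blocks=blocks,
        block_column_names={
            name: list(cols) for name, cols in zip(spec.block_names, spec.column_names)
        },
        response=Y,
        response_names=list(spec.response_names),
        row_ids=[f"ind{i + 1}" for i in range(spec.n)],
    )

    active: set[tuple[str, str]] = set()
    for name, cols, sup_t in zip(spec.block_names, spec.column_names, spec.support):
        for idx in sup_t:
            active.update((name, cols[j]) for j in idx)
    B_true = [A_t @ W.T for A_t in A]  # (p_t, q) on the latent scale
    signs: dict[tuple[str, str, str], int] = {}
    for name, cols, Bt in zip(spec.block_names, spec.column_names, B_true):
        for j, m in zip(*np.nonzero(Bt)):
            signs[(name, cols[j], spec.response_names[m])] = int(np.sign(Bt[j, m]))
    signal_responses = {
        spec.response_names[m] for m in np.flatnonzero(np.abs(W).sum(axis=1) > 0)
    }
    truth = GroundTruth(
        factor_scores=Z,
        active_set=active,
        signal_responses=signal_responses,
        coefficient_signs=signs,
    )
    return data, truth


def study_preset(
    noise_sd_x: float = 0.05,
    noise_sd_y: float = 0.0,
    seed: int = 0,
    abundance_scale: bool = False,
    cross_loading: float = 0.35,
) -> SyntheticSpec:
    """Spec emulating the 5-muscle study design.

    n = 10 individuals; five 20-biomarker muscle blocks (GB/SM/ST/TB/VL)
    plus a 2-column performance block (age, weight) carrying no signal;
    q = 5 muscle responses on a 0-100 scale.  Two planted factors load on a
    small subset of GB and TB biomarkers and drive only the SM and VL
    responses, so GB/ST/TB responses are best predicted by their mean.

    Factor 1 (carried by GB biomarkers) drives SM with weight 1 and VL with
    ``cross_loading``; factor 2 (TB biomarkers) does the reverse.  Keeping
    the cross-loading well below 1 keeps the planted biomarker-response
    correlations near ``1 / sqrt(1 + cross_loading**2)``, high enough that
    support recovery is feasible at n = 10 against ~100 noise covariates.
    Planted loading signs are mixed so coefficient-sign reports are
    non-trivial.
    """
    names = PROTEIN_NAMES
    j = {p: k for k, p in enumerate(names)}
    T = 6
    r = 2
    d = float(cross_loading)
    support: list[list[list[int]]] = [[[], []] for _ in range(T)]
    loadings: list[list[list[float]]] = [[[], []] for _ in range(T)]
    # block order: GB, SM, ST, TB, VL, performance
    support[0] = [[j["mu-calpain"], j["m-calpain"], j["h2afx"], j["Hsp40"]], []]
    loadings[0] = [[1.0, 1.0, -1.0, -1.0], []]
    support[3] = [[], [j["mu-calpain"], j["m-calpain"], j["Hsp70-8"]]]
    loadings[3] = [[], [1.0, 1.0, -1.0]]
    y_loadings = [
        [0.0, 1.0, 0.0, 0.0, d],  # factor 1: mostly SM
        [0.0, d, 0.0, 0.0, 1.0],  # factor 2: mostly VL
    ]
    return SyntheticSpec(
        n=10,
        block_sizes=[20, 20, 20, 20, 20, 2],
        q=5,
        r_true=r,
        support=support,
        x_loadings=loadings,
        y_loadings=y_loadings,
        noise_sd_x=noise_sd_x,
        noise_sd_y=noise_sd_y,
        response_center=50.0,
        response_scale=10.0,
        seed=seed,
        block_names=MUSCLES + ["performance"],
        column_names=[list(names) for _ in range(5)] + [["age", "weight"]],
        response_names=list(MUSCLES),
        abundance_scale=abundance_scale,
    )
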