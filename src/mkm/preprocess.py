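"""Preprocessing of mixed-type clinical tables into row-stochastic matrices.

A raw table (numeric + categorical predictors) is converted in three steps:

1. one-hot encoding of categorical predictors (numeric pass through),
2. per-column min-max scaling into [0, 1], fitted on training rows only and
   clamped at transform time,
3. row normalization, turning each patient's non-negative record into a
   probability distribution over the predictors.

The resulting row-stochastic matrix is the input of the moment kernel: each
patient is treated as a discrete probability distribution whose moments are
the extracted features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawTable",
    "EncodedMatrix",
    "one_hot_encode",
    "minmax_scale",
    "normalize_to_probability",
    "mean_impute",
]


@dataclass
class RawTable:
    """A patient table with declared column types.

    ``column_types`` maps every predictor column name to ``"numeric"`` or
    ``"categorical"``; ``outcome`` names the binary label column, which is
    never treated as a predictor.
    """

    data: pd.DataFrame
    column_types: Mapping[str, str]
    outcome: str | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ValueError("need at least two rows")
        predictors = [c for c in self.data.columns if c != self.outcome]
        missing = [c for c in predictors if c not in self.column_types]
        if missing:
            raise ValueError(f"columns without a declared type: {missing}")
        bad = {
            c: t
            for c, t in self.column_types.items()
            if t not in ("numeric", "categorical")
        }
        if bad:
            raise ValueError(f"unknown column types: {bad}")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c != self.outcome]

    @property
    def labels(self) -> np.ndarray | None:
        if self.outcome is None:
            return None
        return self.data[self.outcome].to_numpy()


@dataclass
class EncodedMatrix:
    """N x M non-negative design matrix with provenance of every column.

    ``feature_names`` traces each column back to its source predictor (and
    category for one-hot columns). ``categories`` stores the fitted category
    lists so that held-out rows encode consistently; ``scaler_state`` holds
    the per-column (min, max) fitted by :func:`minmax_scale`.
    """

    values: np.ndarray
    feature_names: list[str]
    categories: dict[str, list] = field(default_factory=dict)
    scaler_state: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def one_hot_encode(
    table: RawTable,
    *,
    categories: Mapping[str, Sequence] | None = None,
    unseen: str = "zeros",
) -> EncodedMatrix:
    """Expand categorical predictors into binary indicator columns.

    Numeric predictors pass through unchanged (as float). When ``categories``
    is given (the fitted state of a previous call) it is reused, so held-out
    rows map onto the training columns; a category unseen at fit time then
    yields an all-zero indicator group (``unseen="zeros"``, default) or raises
    (``unseen="error"``).
    """
    if unseen not in ("zeros", "error"):
        raise ValueError("unseen must be 'zeros' or 'error'")
    columns: list[np.ndarray] = []
    names: list[str] = []
    fitted: dict[str, list] = {}
    for col in table.predictors:
        kind = table.column_types[col]
        series = table.data[col]
        if kind == "numeric":
            columns.append(series.to_numpy(dtype=float))
            names.append(col)
            continue
        if categories is not None and col in categories:
            cats = list(categories[col])
        else:
            cats = sorted(series.dropna().unique().tolist())
            if not cats:
                raise ValueError(f"categorical column {col!r} has no observed category")
        fitted[col] = cats
        observed = set(series.dropna().unique().tolist())
        novel = observed.difference(cats)
        if novel and unseen == "error":
            raise ValueError(f"unseen categories in column {col!r}: {sorted(novel)}")
        for cat in cats:
            columns.append((series == cat).to_numpy(dtype=float))
            names.append(f"{col}={cat}")
    return EncodedMatrix(
        values=np.column_stack(columns), feature_names=names, categories=fitted
    )


def minmax_scale(
    encoded: EncodedMatrix,
    fit_rows: Sequence[int] | np.ndarray | None = None,
    *,
    state: tuple[np.ndarray, np.ndarray] | None = None,
) -> EncodedMatrix:
    """Linearly map every column into [0, 1] using statistics from fit rows.

    ``fit_rows`` defaults to all rows. Values outside the fitted range (e.g.
    held-out rows) are clamped into [0, 1]; a constant column maps to 0, which
    removes non-informative mass from the downstream distribution. Passing
    ``state`` re-applies a previous fit instead of fitting.
    """
    x = np.asarray(encoded.values, dtype=float)
    if state is None:
        rows = np.arange(x.shape[0]) if fit_rows is None else np.asarray(fit_rows)
        if rows.size == 0:
            raise ValueError("fit_rows must be non-empty")
        lo = np.min(x[rows], axis=0)
        hi = np.max(x[rows], axis=0)
    else:
        lo, hi = state
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((x - lo) / safe, 0.0, 1.0)
    scaled[:, span <= 0] = 0.0
    return EncodedMatrix(
        values=scaled,
        feature_names=list(encoded.feature_names),
        categories=dict(encoded.categories),
        scaler_state=(lo, hi),
    )


def normalize_to_probability(encoded: EncodedMatrix | np.ndarray) -> np.ndarray:
    """Divide each row by its sum, yielding a row-stochastic matrix.

    Every row of the result is a probability distribution over the M encoded
    predictors. A degenerate all-zero row has no well-defined normalization;
    it is replaced by the uniform distribution 1/M with a warning rather than
    dropped, so the row count is preserved.
    """
    x = np.asarray(
        encoded.values if isinstance(encoded, EncodedMatrix) else encoded,
        dtype=float,
    )
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("entries must lie in [0, 1]; scale before normalizing")
    sums = x.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero row(s) replaced by the uniform distribution",
            stacklevel=2,
        )
        x = x.copy()
        x[zero] = 1.0
        sums = x.sum(axis=1, keepdims=True)
    return x / sums


def mean_impute(
    x: np.ndarray,
    fit_rows: Sequence[int] | np.ndarray | None = None,
    *,
    means: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN entries with per-column means computed on fit rows.

    Returns the imputed matrix and the fitted column means (reusable on
    held-out rows via ``means=``). A column that is entirely NaN over the fit
    rows imputes to 0.
    """
    x = np.asarray(x, dtype=float)
    if means is None:
        rows = np.arange(x.shape[0]) if fit_rows is None else np.asarray(fit_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            means = np.nanmean(x[rows], axis=0)
        means = np.nan_to_num(means, nan=0.0)
    out = x.copy()
    nan_mask = np.isnan(out)
    out[nan_mask] = np.broadcast_to(means, out.shape)[nan_mask]
    return out, means
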