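"""Missing-value imputation of protein-level ratio matrices.

Two strategies with opposite assumptions:

* MIN x 0.5 — every missing cell becomes half the column's minimum
  observed value (on log2 input: column minimum minus 1). Encodes a
  limit-of-detection assumption: what is missing is missing because it
  is low.
* random forest — missForest-style iterative prediction of each
  column's missing cells from all other columns, appropriate when
  values are missing at random.

Non-missing cells are never modified by either method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, DegenerateSampleError, MethodUnavailableError

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    method: str = "min_half"  # or "random_forest"
    rf_trees: int = 100
    rf_max_iter: int = 10
    rf_tol: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("min_half", "random_forest"):
            raise ConfigError(f"unknown imputation method {self.method!r}")
        if self.method == "random_forest" and self.seed is None:
            raise ConfigError("random_forest imputation requires a seed")


def impute_min_half(matrix: pd.DataFrame, log_scale: bool = False) -> pd.DataFrame:
    """Replace missing cells with 0.5x the column minimum.

    With ``log_scale=True`` the fill is column minimum minus 1, which is
    the identical rule on log2 values.
    """
    out = matrix.copy()
    for col in out.columns:
        s = out[col]
        if s.notna().sum() == 0:
            raise DegenerateSampleError(f"column {col!r} is all-missing")
        fill = s.min() - 1.0 if log_scale else 0.5 * s.min()
        out[col] = s.fillna(fill)
    return out


def impute_random_forest(
    matrix: pd.DataFrame, config: ImputationConfig
) -> pd.DataFrame:
    """missForest-style iterative random-forest imputation.

    Missing cells start at column means; columns are revisited in order
    of increasing missingness, each regressed on all other columns and
    its missing cells re-predicted. Iteration stops when the summed
    squared change of imputed values increases (stall) or after
    ``rf_max_iter`` rounds. Deterministic given ``config.seed``.
    """
    if matrix.shape[1] < 2:
        raise MethodUnavailableError("random-forest imputation needs >= 2 columns")
    mask = matrix.isna()
    if not mask.to_numpy().any():
        return matrix.copy()
    heavy = mask.mean(axis=0)
    if (heavy >= 0.5).any():
        logger.warning(
            "column(s) with >= 50%% missing: %s", list(heavy[heavy >= 0.5].index)
        )

    rng = np.random.RandomState(config.seed)
    vals = matrix.to_numpy(dtype=float).copy()
    col_means = np.nanmean(vals, axis=0)
    miss = mask.to_numpy()
    for j in range(vals.shape[1]):
        vals[miss[:, j], j] = col_means[j]

    order = np.argsort(miss.sum(axis=0), kind="mergesort")
    prev_imputed = vals[miss].copy()
    prev_delta = np.inf
    best = vals.copy()
    for it in range(config.rf_max_iter):
        for j in order:
            rows = miss[:, j]
            if not rows.any():
                continue
            others = np.delete(np.arange(vals.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=config.rf_trees,
                random_state=rng.randint(0, 2**31 - 1),
                n_jobs=1,
            )
            rf.fit(vals[~rows][:, others], vals[~rows, j])
            vals[rows, j] = rf.predict(vals[rows][:, others])
        cur_imputed = vals[miss]
        delta = float(np.sum((cur_imputed - prev_imputed) ** 2)) / max(
            float(np.sum(cur_imputed**2)), 1e-300
        )
        logger.debug("rf imputation iteration %d: delta %.4g", it + 1, delta)
        if delta > prev_delta:  # stalled: previous round was the best
            logger.info("rf imputation stalled after %d iterations", it + 1)
            break
        best = vals.copy()
        if delta <= config.rf_tol:
            break
        prev_imputed = cur_imputed.copy()
        prev_delta = delta

    out = pd.DataFrame(best, index=matrix.index, columns=matrix.columns)
    out[~mask] = matrix[~mask]  # guard: observed cells untouched
    return out


def impute(
    matrix: pd.DataFrame, config: ImputationConfig, log_scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dispatch on method; returns (imputed matrix, imputed-cell mask)."""
    mask = matrix.isna()
    if config.method == "min_half":
        return impute_min_half(matrix, log_scale=log_scale), mask
    return impute_random_forest(matrix, config), mask
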