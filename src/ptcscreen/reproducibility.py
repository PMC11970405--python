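"""Replicate reproducibility QC: per-pair CV and pair-resampling correlation.

Between-well consistency of the assay is summarized two ways:

* the coefficient of variation (sample SD / mean) of the replicate
  viabilities of each drug-sample pair, reported as the mean CV and the
  fraction of pairs with CV < 0.50;
* a resampling check -- B times (default 1,000), pick two distinct
  replicate columns at random and correlate them across all drug-sample
  pairs (Pearson and Spearman), summarizing the resulting coefficient
  distributions by mean and SD.

"Two randomly selected results" is read as two replicate measurement
vectors over the same set of pairs: that is the only reading under which a
correlation across hundreds of pairs is defined.  Column pairs are drawn
with replacement across repeats.  An alternative mode additionally
bootstraps the row set on each draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CVSummary",
    "PairSamplingResult",
    "replicate_cv",
    "cv_summary",
    "paired_resampling_correlation",
    "replicate_columns",
]


@dataclass(frozen=True)
class CVSummary:
    per_row_cv: pd.Series
    mean_cv: float
    fraction_below: float
    cv_threshold: float
    n_rows: int
    n_excluded: int


@dataclass(frozen=True)
class PairSamplingResult:
    pearson: np.ndarray
    spearman: np.ndarray
    pearson_mean: float
    pearson_sd: float
    spearman_mean: float
    spearman_sd: float
    n_draws: int
    seed: int | None


def replicate_cv(values: Sequence[float]) -> float:
    """CV = sample SD (ddof=1) / mean of one pair's replicate viabilities."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 replicate values")
    if np.any(arr < 0):
        raise ValueError("replicate values must be >= 0")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined: replicate mean is zero")
    return float(arr.std(ddof=1) / mean)


def replicate_columns(matrix: pd.DataFrame) -> list[str]:
    cols = [c for c in matrix.columns if str(c).startswith("replicate_")]
    if not cols:
        raise ValueError("matrix has no replicate_* columns")
    return cols


def cv_summary(matrix: pd.DataFrame, cv_threshold: float = 0.50) -> CVSummary:
    """Mean per-pair CV and the fraction strictly below ``cv_threshold``.

    Rows violating CV preconditions (zero mean, < 2 finite replicates) are
    excluded and counted, never silently dropped.
    """
    cols = replicate_columns(matrix)
    cvs, excluded = {}, 0
    for idx, row in matrix[cols].iterrows():
        vals = row.to_numpy(float)
        vals = vals[np.isfinite(vals)]
        try:
            cvs[idx] = replicate_cv(vals)
        except ValueError:
            excluded += 1
    per_row = pd.Series(cvs, name="cv")
    if per_row.empty:
        raise ValueError("no rows with computable CV")
    return CVSummary(
        per_row_cv=per_row,
        mean_cv=float(per_row.mean()),
        fraction_below=float((per_row < cv_threshold).mean()),
        cv_threshold=cv_threshold,
        n_rows=int(per_row.size),
        n_excluded=excluded,
    )


def paired_resampling_correlation(matrix: pd.DataFrame, b: int = 1000,
                                  seed: int | None = None,
                                  mode: Literal["columns", "columns+rows"] = "columns",
                                  ) -> PairSamplingResult:
    """Correlate two randomly chosen replicate columns, B times.

    Per draw: choose an unordered pair of distinct replicate columns
    uniformly at random, then compute Pearson and Spearman correlation of
    the two vectors over the rows.  ``mode="columns+rows"`` additionally
    resamples rows with replacement on each draw (an alternative reading of
    the procedure; off by default).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    cols = replicate_columns(matrix)
    if len(cols) < 2:
        raise ValueError("need at least 2 replicate columns")
    data = matrix[cols].to_numpy(float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    rng = np.random.default_rng(seed)
    pear = np.empty(b)
    spear = np.empty(b)
    for k in range(b):
        i, j = rng.choice(len(cols), size=2, replace=False)
        x, y = data[:, i], data[:, j]
        if mode == "columns+rows":
            rows = rng.integers(0, data.shape[0], size=data.shape[0])
            x, y = x[rows], y[rows]
        if np.all(x == y):
            pear[k] = spear[k] = 1.0
            continue
        pear[k] = stats.pearsonr(x, y).statistic
        spear[k] = stats.spearmanr(x, y).statistic
    return PairSamplingResult(
        pearson=pear,
        spearman=spear,
        pearson_mean=float(pear.mean()),
        pearson_sd=float(pear.std(ddof=1)) if b > 1 else 0.0,
        spearman_mean=float(spear.mean()),
        spearman_sd=float(spear.std(ddof=1)) if b > 1 else 0.0,
        n_draws=b,
        seed=seed,
    )
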