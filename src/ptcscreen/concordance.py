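"""Concordance between PTC drug tests and RECIST clinical outcomes.

The analysis unit is the treatment: one (patient sample, regimen) pair
with a mean PTC viability pA and a RECIST outcome merged to three classes
(CR/PR, SD, PD).  Agreement is evaluated with

* a 2x3 contingency table of the effective / not-effective call (pA < 0.7)
  against outcome class;
* concordance accuracy in two modes -- CR/PR vs PD (SD dropped; the
  20-treatment headline analysis) and CR/PR vs SD+PD (all 60 treatments);
* two-sample Mann-Whitney (Wilcoxon rank-sum) comparison of viabilities;
* ROC analysis scoring each treatment by -pA, so lower viability scores
  toward clinical response and AUC > 0.5 means the assay is predictive;
  AUC by pairwise counting, P(score+ > score-) + 0.5 P(tie), with a
  DeLong confidence interval (stratified bootstrap as fallback for the
  degenerate AUC in {0, 1} case, where the DeLong variance collapses);
* Fisher's exact test for 2x2 restrictions, and Benjamini-Hochberg
  adjustment when batches of p-values are reported;
* a plot-ready waterfall table sorted by viability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ptcscreen.scoring import DEFAULT_CUTOFF, EFFECTIVE, classify_drug

__all__ = [
    "RECIST_CLASSES",
    "normalize_recist",
    "standardize_viability",
    "build_contingency",
    "concordance_accuracy",
    "mann_whitney",
    "roc_auc",
    "auc_confidence_interval",
    "fisher_exact",
    "waterfall_table",
    "bh_adjust",
    "RocResult",
    "GroupComparison",
]

RECIST_CLASSES = ("CR/PR", "SD", "PD")
_MERGE = {"CR": "CR/PR", "PR": "CR/PR", "CR/PR": "CR/PR", "SD": "SD", "PD": "PD"}


def normalize_recist(label: str) -> str:
    """Map raw RECIST labels onto the three merged classes (CR and PR merge)."""
    key = str(label).strip().upper().replace(" ", "")
    if key not in _MERGE:
        raise ValueError(f"unknown RECIST label: {label!r}")
    return _MERGE[key]


@dataclass(frozen=True)
class RocResult:
    """AUC with sample sizes; orientation: lower viability predicts response."""

    auc: float
    n_positive: int
    n_negative: int
    positive_class: str
    orientation: str = "lower viability => predicted sensitive"


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of two viability groups."""

    u_statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


def standardize_viability(values: Sequence[float]) -> np.ndarray:
    """z = (x - mean) / SD (ddof=1); rejects constant input."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("standardization needs >= 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("standardization undefined for constant input")
    return (arr - arr.mean()) / sd


def _outcome_frame(outcomes: pd.DataFrame) -> pd.DataFrame:
    if outcomes.empty:
        raise ValueError("outcome table is empty")
    missing = {"pA", "recist"} - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    df = outcomes.copy()
    df["recist"] = df["recist"].map(normalize_recist)
    return df


def build_contingency(outcomes: pd.DataFrame,
                      cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """2x3 table: effective / not_effective rows vs CR/PR, SD, PD columns."""
    df = _outcome_frame(outcomes)
    df["call"] = [classify_drug(v, cutoff) for v in df["pA"]]
    table = pd.crosstab(df["call"], df["recist"])
    table = table.reindex(index=["effective", "not_effective"],
                          columns=list(RECIST_CLASSES), fill_value=0)
    table.index.name = "ptc_call"
    table.columns.name = "recist"
    return table


def concordance_accuracy(outcomes: pd.DataFrame,
                         mode: Literal["CRPR_vs_PD", "CRPR_vs_SDPD"],
                         cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of included treatments whose PTC call matches the outcome.

    A treatment is concordant when it is CR/PR and called effective, or in
    the resistant class and called not effective.  ``CRPR_vs_PD`` drops SD
    treatments (the 8 + 12 = 20 analysis); ``CRPR_vs_SDPD`` counts SD with
    PD as resistant (the all-60 analysis).
    """
    df = _outcome_frame(outcomes)
    if mode == "CRPR_vs_PD":
        df = df[df["recist"] != "SD"]
    elif mode != "CRPR_vs_SDPD":
        raise ValueError(f"unknown mode: {mode!r}")
    if df.empty:
        raise ValueError("no treatments included under this mode")
    effective = np.array([classify_drug(v, cutoff) == EFFECTIVE for v in df["pA"]])
    sensitive = (df["recist"] == "CR/PR").to_numpy()
    return float(np.mean(effective == sensitive))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test on two viability groups.

    U is reported in the A-orientation (number of (a, b) pairs with a < b,
    counting ties as half).  The exact null distribution is used when both
    groups have n <= 8 and the pooled data are tie-free; otherwise the
    normal approximation with tie and continuity correction.  If every
    pooled value is identical the comparison is vacuous: p = 1 with a
    warning.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; Mann-Whitney p set to 1",
                      stacklevel=2)
        return GroupComparison(u_statistic=a.size * b.size / 2.0, p_value=1.0,
                               method="degenerate", n_a=a.size, n_b=b.size)
    ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "normal-approximation"
    return GroupComparison(u_statistic=float(res.statistic),
                           p_value=float(min(res.pvalue, 1.0)),
                           method=method, n_a=a.size, n_b=b.size)


def _scores_and_labels(outcomes: pd.DataFrame, positive_class: str,
                       negative_classes: Sequence[str] | None):
    df = _outcome_frame(outcomes)
    positive_class = normalize_recist(positive_class)
    if negative_classes is None:
        negative_classes = [c for c in RECIST_CLASSES if c != positive_class]
    negative_classes = [normalize_recist(c) for c in negative_classes]
    pos = -df.loc[df["recist"] == positive_class, "pA"].to_numpy(float)
    neg = -df.loc[df["recist"].isin(negative_classes), "pA"].to_numpy(float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both the positive and negative class must be represented")
    return pos, neg, positive_class


def _pairwise_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    diff = pos_scores[:, None] - neg_scores[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))
                 / diff.size)


def roc_auc(outcomes: pd.DataFrame, positive_class: str = "CR/PR",
            negative_classes: Sequence[str] | None = None) -> RocResult:
    """AUC by pairwise counting; score is -pA so response ranks first.

    AUC = P(score+ > score-) + 0.5 P(tie), which equals the trapezoidal
    area under the empirical ROC curve.
    """
    pos, neg, positive_class = _scores_and_labels(outcomes, positive_class,
                                                  negative_classes)
    return RocResult(auc=_pairwise_auc(pos, neg), n_positive=pos.size,
                     n_negative=neg.size, positive_class=positive_class)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, alpha: float):
    """DeLong variance of the AUC via placement values."""
    m, n = pos.size, neg.size
    auc = _pairwise_auc(pos, neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.count_nonzero(p > neg) + 0.5 * np.count_nonzero(p == neg)) / n
                    for p in pos])
    v01 = np.array([(np.count_nonzero(pos > q) + 0.5 * np.count_nonzero(pos == q)) / m
                    for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half), var


def _bootstrap_ci(pos: np.ndarray, neg: np.ndarray, alpha: float,
                  n_boot: int, seed: int | None):
    """Stratified bootstrap percentile CI (resample each class separately)."""
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for k in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        aucs[k] = _pairwise_auc(bp, bn)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def auc_confidence_interval(outcomes: pd.DataFrame,
                            positive_class: str = "CR/PR",
                            negative_classes: Sequence[str] | None = None,
                            method: Literal["delong", "bootstrap"] = "delong",
                            alpha: float = 0.05,
                            n_boot: int = 2000,
                            seed: int | None = None) -> tuple[float, float]:
    """CI for the AUC; DeLong by default, truncated to [0, 1].

    When the observed AUC is exactly 0 or 1 the DeLong variance degenerates
    to zero, so the stratified bootstrap is used instead (with a warning).
    """
    pos, neg, _ = _scores_and_labels(outcomes, positive_class, negative_classes)
    auc = _pairwise_auc(pos, neg)
    if method == "delong":
        if auc in (0.0, 1.0):
            warnings.warn("degenerate AUC for DeLong; falling back to "
                          "stratified bootstrap", stacklevel=2)
            lo, hi = _bootstrap_ci(pos, neg, alpha, n_boot, seed)
        else:
            lo, hi, _ = _delong_ci(pos, neg, alpha)
    elif method == "bootstrap":
        lo, hi = _bootstrap_ci(pos, neg, alpha, n_boot, seed)
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return min(lo, auc), max(hi, auc)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by summation of all hypergeometric tables (with the observed
    margins) whose probability does not exceed the observed table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        arr = arr.astype(int)
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def waterfall_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table sorted by descending viability; ties keep input order."""
    df = _outcome_frame(outcomes)
    out = df.sort_values("pA", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in the raw p ordering)."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
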