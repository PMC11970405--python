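"""Viability scoring, negative-control QC and cutoff classification.

The per-replicate viability of well i is the ratio of summed cluster areas

    p_Ai = S_Ai,t1 / S_Ai,t0

and the drug-level score is the arithmetic mean over replicate wells,
pA = (1/n) * sum_i p_Ai (n = 3 wells by default).  A drug is called
effective when pA < 0.7 and not effective when pA >= 0.7, for single and
combined regimens alike.  The untreated negative control gates the whole
test: when its viability pNC falls below 0.9 the clusters are presumed to
be in the decline phase and every result for that sample is discarded.
pA is deliberately NOT normalized by pNC -- the control is a quality gate,
not a denominator (a flag exists for exploratory control-normalization).

This module also labels growth phases (exponential / stationary / decline)
on daily total-area trajectories, used to verify that simulated wells show
the 5-25 day plateau typical of PTCs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ptcscreen.synthetic import NEGATIVE_CONTROL

__all__ = [
    "DegenerateWellError",
    "ViabilitySummary",
    "GrowthPhaseLabel",
    "replicate_viability",
    "mean_viability",
    "qc_negative_control",
    "classify_drug",
    "classify_growth_phases",
    "score_assay",
    "EFFECTIVE",
    "NOT_EFFECTIVE",
    "DEFAULT_CUTOFF",
    "DEFAULT_QC_THRESHOLD",
]

EFFECTIVE = "effective"
NOT_EFFECTIVE = "not_effective"
DEFAULT_CUTOFF = 0.7
DEFAULT_QC_THRESHOLD = 0.9


class DegenerateWellError(ValueError):
    """Raised when a well has zero baseline area (no measurable clusters)."""


@dataclass(frozen=True)
class ViabilitySummary:
    """Mean, SD and count of replicate viability ratios."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class GrowthPhaseLabel:
    """Per-transition phase labels and the longest stationary run."""

    phases: tuple[str, ...]
    plateau_length_days: int


def replicate_viability(s_t0: float, s_t1: float, well: str = "") -> float:
    """p_Ai = S_t1 / S_t0 for one replicate well.

    Ratios above 1 are valid (the well grew under drug).  A zero baseline
    area is a degenerate well and raises :class:`DegenerateWellError`.
    """
    if s_t0 < 0 or s_t1 < 0:
        raise ValueError("areas must be >= 0")
    if s_t0 == 0:
        raise DegenerateWellError(
            f"well {well or '<unnamed>'} has zero baseline area; "
            "viability is undefined"
        )
    return s_t1 / s_t0


def mean_viability(ratios: Sequence[float]) -> ViabilitySummary:
    """pA = arithmetic mean of replicate ratios, with SD (ddof=1) for CV use."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate ratio is required")
    if np.any(arr < 0):
        raise ValueError("viability ratios must be >= 0")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ViabilitySummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def qc_negative_control(pnc: float, threshold: float = DEFAULT_QC_THRESHOLD) -> bool:
    """True when the test is usable: pNC >= threshold.

    The discard rule is strict ("less than 0.9"), so pNC = 0.9 passes.
    """
    if pnc < 0:
        raise ValueError("pNC must be >= 0")
    return pnc >= threshold


def classify_drug(pa: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Effective iff pA < cutoff; the boundary pA == cutoff is not effective."""
    if pa < 0:
        raise ValueError("pA must be >= 0")
    return EFFECTIVE if pa < cutoff else NOT_EFFECTIVE


def classify_growth_phases(daily_areas: Sequence[float],
                           rel_change_tolerance: float = 0.05) -> GrowthPhaseLabel:
    """Label each day-over-day transition and measure the plateau.

    The relative change r = A_t/A_{t-1} - 1 maps to "exponential" when
    r > tol, "stationary" when |r| <= tol, "decline" when r < -tol; the
    plateau length is the longest stationary run.  Needs >= 3 days of
    strictly positive areas.
    """
    areas = np.asarray(list(daily_areas), dtype=float)
    if areas.size < 3:
        raise ValueError("need at least 3 days of areas")
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        raise ValueError("areas must be positive and finite")
    r = areas[1:] / areas[:-1] - 1.0
    phases = tuple(
        "exponential" if ri > rel_change_tolerance
        else "decline" if ri < -rel_change_tolerance
        else "stationary"
        for ri in r
    )
    longest = run = 0
    for p in phases:
        run = run + 1 if p == "stationary" else 0
        longest = max(longest, run)
    return GrowthPhaseLabel(phases=phases, plateau_length_days=longest)


def score_assay(wells: pd.DataFrame,
                cutoff: float = DEFAULT_CUTOFF,
                qc_threshold: float = DEFAULT_QC_THRESHOLD,
                min_replicates: int = 2,
                normalize_by_control: bool = False) -> tuple[pd.DataFrame, dict]:
    """Score a WellRecord table into per-(sample, drug, concentration) results.

    ``wells`` needs columns sample_id, drug_id, concentration_um, replicate,
    S_t0_um2, S_t1_um2.  Negative-control rows carry drug_id "NC" and NaN
    concentration.

    Per sample: compute pNC from control wells and discard the entire
    sample's test when pNC < ``qc_threshold``.  Per drug-concentration
    group: replicates with zero baseline are excluded (and counted); groups
    left with fewer than ``min_replicates`` usable wells are dropped.

    Returns the ViabilityResult table (sample_id, drug_id, concentration_um,
    pA, sd, n, classification) and a QC report dict listing discarded
    samples, excluded replicates and dropped groups with reasons.
    """
    required = {"sample_id", "drug_id", "concentration_um", "replicate",
                "S_t0_um2", "S_t1_um2"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")

    report: dict = {
        "qc_threshold": qc_threshold,
        "cutoff": cutoff,
        "samples": {},
        "discarded_samples": [],
        "excluded_replicates": [],
        "dropped_groups": [],
        "n_input_wells": int(len(wells)),
    }
    results = []

    for sample_id, sdf in wells.groupby("sample_id", sort=True):
        is_nc = sdf["drug_id"] == NEGATIVE_CONTROL
        nc = sdf[is_nc]
        pnc = np.nan
        qc_pass = True
        if len(nc):
            ratios = []
            for _, row in nc.iterrows():
                try:
                    ratios.append(replicate_viability(
                        row["S_t0_um2"], row["S_t1_um2"],
                        well=f"{sample_id}/NC/r{int(row['replicate'])}"))
                except DegenerateWellError as err:
                    report["excluded_replicates"].append(str(err))
            if ratios:
                pnc = mean_viability(ratios).mean
                qc_pass = qc_negative_control(pnc, qc_threshold)
        report["samples"][str(sample_id)] = {
            "pNC": None if math.isnan(pnc) else float(pnc),
            "qc_pass": bool(qc_pass),
        }
        if not qc_pass:
            report["discarded_samples"].append({
                "sample_id": str(sample_id),
                "pNC": float(pnc),
                "reason": f"negative-control viability {pnc:.3f} < {qc_threshold}",
            })
            continue

        treated = sdf[~is_nc]
        for (drug_id, conc), gdf in treated.groupby(
                ["drug_id", "concentration_um"], dropna=False, sort=True):
            ratios = []
            for _, row in gdf.iterrows():
                try:
                    ratios.append(replicate_viability(
                        row["S_t0_um2"], row["S_t1_um2"],
                        well=f"{sample_id}/{drug_id}/{conc}/r{int(row['replicate'])}"))
                except DegenerateWellError as err:
                    report["excluded_replicates"].append(str(err))
            if len(ratios) < min_replicates:
                report["dropped_groups"].append({
                    "sample_id": str(sample_id), "drug_id": str(drug_id),
                    "concentration_um": None if pd.isna(conc) else float(conc),
                    "reason": f"only {len(ratios)} usable replicates "
                              f"(minimum {min_replicates})",
                })
                continue
            summ = mean_viability(ratios)
            pa = summ.mean
            if normalize_by_control and not math.isnan(pnc) and pnc > 0:
                pa = pa / pnc
            results.append({
                "sample_id": sample_id,
                "drug_id": drug_id,
                "concentration_um": conc,
                "pA": pa,
                "sd": summ.sd,
                "n": summ.n,
                "classification": classify_drug(pa, cutoff),
            })

    out = pd.DataFrame(
        results,
        columns=["sample_id", "drug_id", "concentration_um", "pA", "sd", "n",
                 "classification"],
    )
    report["n_output_groups"] = int(len(out))
    return out, report
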