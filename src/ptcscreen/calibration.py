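"""Efficacy-concentration (Ec) calibration against clinical ORR.

The PTC assay fixes, per drug, a single testing concentration Ec rather
than fitting dose-response curves.  Each drug is screened across its 3-6
gradient concentrations on an assay-set of samples; the efficacy rate
ER(c) is the fraction of samples called effective (pA < 0.7) at
concentration c.  Ec is the tested concentration whose ER is closest to
the drug's objective response rate (ORR) from clinical trials, with ties
broken toward the lowest concentration.

Panels arrive as long-format tables (drug_id, sample_id, concentration_um,
pA); ORR references as a per-drug mapping in [0, 1].  Samples missing a
concentration are simply absent from that concentration's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ptcscreen.scoring import DEFAULT_CUTOFF

__all__ = ["EcRecord", "efficacy_rate", "calibrate_ec", "calibrate_panel"]

PANEL_COLUMNS = ("drug_id", "sample_id", "concentration_um", "pA")


@dataclass(frozen=True)
class EcRecord:
    """Calibrated testing concentration of one drug."""

    drug_id: str
    er_by_concentration: dict[float, float]
    orr_ref: float
    ec_um: float
    achieved_gap: float  # |ER(Ec) - ORR|


def _drug_panel(panel: pd.DataFrame, drug_id: str | None) -> tuple[pd.DataFrame, str]:
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if drug_id is None:
        drugs = panel["drug_id"].unique()
        if len(drugs) != 1:
            raise ValueError("panel holds multiple drugs; pass drug_id")
        drug_id = drugs[0]
    sub = panel[panel["drug_id"] == drug_id]
    if sub.empty:
        raise ValueError(f"no panel rows for drug {drug_id!r}")
    return sub, str(drug_id)


def efficacy_rate(panel: pd.DataFrame, concentration: float,
                  drug_id: str | None = None,
                  cutoff: float = DEFAULT_CUTOFF) -> float:
    """ER(c): fraction of samples with pA < cutoff at one tested concentration."""
    sub, drug_id = _drug_panel(panel, drug_id)
    at_c = sub[np.isclose(sub["concentration_um"].to_numpy(float), concentration)]
    if at_c.empty:
        raise ValueError(
            f"concentration {concentration} uM was not measured for {drug_id!r}")
    pa = at_c["pA"].to_numpy(float)
    return float(np.count_nonzero(pa < cutoff) / pa.size)


def calibrate_ec(panel: pd.DataFrame, orr_ref: float,
                 drug_id: str | None = None,
                 cutoff: float = DEFAULT_CUTOFF) -> EcRecord:
    """Pick Ec = argmin_c |ER(c) - ORR| over the tested concentrations.

    Ties go to the lowest concentration (least off-target stress on the
    assay).  The full ER profile and the achieved gap are returned so the
    calibration can be audited.
    """
    if not 0.0 <= orr_ref <= 1.0:
        raise ValueError("orr_ref must be in [0, 1]")
    sub, drug_id = _drug_panel(panel, drug_id)
    concs = np.sort(sub["concentration_um"].unique())
    er = {float(c): efficacy_rate(sub, float(c), drug_id, cutoff) for c in concs}
    gaps = {c: abs(r - orr_ref) for c, r in er.items()}
    # ascending concentration order makes min() break ties toward the lowest
    ec = min(sorted(gaps), key=lambda c: gaps[c])
    return EcRecord(drug_id=drug_id, er_by_concentration=er, orr_ref=float(orr_ref),
                    ec_um=float(ec), achieved_gap=float(gaps[ec]))


def calibrate_panel(panel: pd.DataFrame, orr_table: Mapping[str, float],
                    cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Calibrate every drug in a multi-drug panel.

    ``orr_table`` maps drug_id -> clinical ORR; drugs without a reference
    ORR are skipped.  Returns one row per calibrated drug.
    """
    rows = []
    for drug_id in sorted(panel["drug_id"].unique()):
        if drug_id not in orr_table:
            continue
        rec = calibrate_ec(panel, orr_table[drug_id], drug_id=drug_id, cutoff=cutoff)
        rows.append({
            "drug_id": rec.drug_id,
            "ec_um": rec.ec_um,
            "orr_ref": rec.orr_ref,
            "er_at_ec": rec.er_by_concentration[rec.ec_um],
            "achieved_gap": rec.achieved_gap,
            "n_concentrations": len(rec.er_by_concentration),
        })
    return pd.DataFrame(
        rows, columns=["drug_id", "ec_um", "orr_ref", "er_at_ec",
                       "achieved_gap", "n_concentrations"])
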