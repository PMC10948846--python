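"""Intracranial compliance (ICC) and FSI-based brain stiffness.

From per-stage scalar outputs (ICP in cmH2O, intracranial volume in ml,
brain surface area in cm^2, cyclic brain deformation in mm) the two derived
quantities are computed per consecutive stage interval:

    ICC_i       = (V_{i+1} - V_i) / (ICP_{i+1} - ICP_i)        [ml/cmH2O]
    stiffness_i = Delta(ICP x area) / Delta(deformation)        [N/m]

The stiffness numerator is the CSF force on the brain (pressure times the
stage-specific brain surface area, converted to SI); both quantities are
signed — negative ICC and negative stiffness intervals are meaningful
month-to-month outcomes, not errors. Intervals whose denominator is smaller
than ``eps`` are flagged undefined and excluded from downstream correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import CM2_TO_M2, CMH2O_TO_PA, MM_TO_M

#: denominator guard in working units (cmH2O for ICC, mm for stiffness)
EPS_DENOM = 1e-9

REQUIRED_COLUMNS = (
    "patient_id",
    "stage",
    "icp_cmH2O",
    "intracranial_volume_ml",
    "brain_surface_area_cm2",
    "deformation_mm",
)


@dataclass(frozen=True)
class StageRecord:
    """Scalar outputs of one patient-stage (stage 0 = pre-surgery)."""

    patient_id: int
    stage: int
    icp_cmH2O: float
    intracranial_volume_ml: float
    brain_surface_area_cm2: float
    deformation_mm: float

    def __post_init__(self):
        if self.intracranial_volume_ml <= 0 or self.brain_surface_area_cm2 <= 0:
            raise ValueError("volume and area must be positive")
        if not np.isfinite(self.icp_cmH2O):
            raise ValueError("icp must be finite")


def _sorted_stages(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    if mode not in ("consecutive", "vs_baseline"):
        raise ValueError("mode must be 'consecutive' or 'vs_baseline'")
    df = records.sort_values("stage")
    if df["stage"].duplicated().any():
        raise ValueError("duplicate stages for one patient")
    if len(df) < 2:
        raise ValueError("need at least two stages")
    return df


def _deltas(df: pd.DataFrame, col: str, mode: str) -> np.ndarray:
    v = df[col].to_numpy(dtype=float)
    if mode == "consecutive":
        return np.diff(v)
    return v[1:] - v[0]


def compute_icc(records: pd.DataFrame, mode: str = "consecutive") -> pd.DataFrame:
    """Per-interval ICC (ml/cmH2O) for one patient's stage records.

    Returns a frame with columns interval (label "i->i+1"), icc_ml_per_cmH2O,
    defined (bool). Undefined intervals (|ΔICP| < eps) carry NaN.
    """
    df = _sorted_stages(records, mode)
    dv = _deltas(df, "intracranial_volume_ml", mode)
    dp = _deltas(df, "icp_cmH2O", mode)
    defined = np.abs(dp) >= EPS_DENOM
    icc = np.where(defined, dv / np.where(defined, dp, 1.0), np.nan)
    stages = df["stage"].to_numpy()
    base = stages[0]
    labels = [
        f"{stages[i]}->{stages[i + 1]}" if mode == "consecutive" else f"{base}->{s}"
        for i, s in enumerate(stages[1:])
    ]
    return pd.DataFrame(
        {"interval": labels, "icc_ml_per_cmH2O": icc, "defined": defined}
    )


def compute_stiffness(records: pd.DataFrame, mode: str = "consecutive") -> pd.DataFrame:
    """Per-interval FSI-based brain stiffness (N/m) for one patient.

    Force = ICP x stage-specific brain surface area, in newtons; deformation
    differences in meters. Sign conveys whether force and deformation move
    together (positive) or oppositely (negative).
    """
    df = _sorted_stages(records, mode)
    force_n = (
        df["icp_cmH2O"].to_numpy(dtype=float)
        * CMH2O_TO_PA
        * df["brain_surface_area_cm2"].to_numpy(dtype=float)
        * CM2_TO_M2
    )
    tmp = df.assign(_force=force_n)
    dfc = _deltas(tmp, "_force", mode)
    dd = _deltas(df, "deformation_mm", mode)
    defined = np.abs(dd) >= EPS_DENOM
    stiff = np.where(defined, dfc / (np.where(defined, dd, 1.0) * MM_TO_M), np.nan)
    stages = df["stage"].to_numpy()
    base = stages[0]
    labels = [
        f"{stages[i]}->{stages[i + 1]}" if mode == "consecutive" else f"{base}->{s}"
        for i, s in enumerate(stages[1:])
    ]
    return pd.DataFrame(
        {"interval": labels, "stiffness_N_per_m": stiff, "defined": defined}
    )


def build_cohort_table(
    records: pd.DataFrame, mode: str = "consecutive", logger=None
) -> pd.DataFrame:
    """Flat patient-interval analysis table with defined ICC and stiffness.

    One row per patient per interval; intervals where either quantity is
    undefined are dropped (count reported through ``logger`` if given).
    Columns: patient_id, interval, icc_ml_per_cmH2O, stiffness_N_per_m.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns {missing}")
    rows = []
    n_dropped = 0
    for pid, grp in records.groupby("patient_id"):
        icc = compute_icc(grp, mode)
        st = compute_stiffness(grp, mode)
        ok = icc["defined"].to_numpy() & st["defined"].to_numpy()
        n_dropped += int((~ok).sum())
        for i in np.nonzero(ok)[0]:
            rows.append(
                {
                    "patient_id": pid,
                    "interval": icc["interval"].iloc[i],
                    "icc_ml_per_cmH2O": float(icc["icc_ml_per_cmH2O"].iloc[i]),
                    "stiffness_N_per_m": float(st["stiffness_N_per_m"].iloc[i]),
                }
            )
    if n_dropped and logger is not None:
        logger.warning("dropped %d undefined interval(s)", n_dropped)
    return pd.DataFrame(rows, columns=["patient_id", "interval", "icc_ml_per_cmH2O", "stiffness_N_per_m"])
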