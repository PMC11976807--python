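"""Microdialysis catheter calibration by retrodialysis-by-drug.

A microdialysis catheter never equilibrates fully with the surrounding
tissue, so the dialysate concentration is only a fraction — the *relative
recovery* (RR) — of the true extracellular concentration.  RR is calibrated
per catheter by perfusing drug-spiked fluid and measuring its loss across
the membrane::

    RR (%) = 100 · (1 − C_dialysate / C_perfusate)

and dialysate measurements are then corrected to absolute free tissue
concentrations::

    C_tissue = 100 · C_dialysate / RR
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationRecord",
    "RecoveryEstimate",
    "relative_recovery",
    "tissue_concentration",
    "catheter_recoveries",
    "pool_recovery",
    "correct_observations",
]


@dataclass(frozen=True)
class CalibrationRecord:
    """One retrodialysis calibration sample for one catheter."""

    catheter_id: str
    c_perfusate: float  # µg/mL, drug-spiked perfusate entering the catheter
    c_dialysate: float  # µg/mL, fluid exiting the catheter

    def __post_init__(self) -> None:
        if not self.c_perfusate > 0:
            raise ValueError(f"c_perfusate must be > 0, got {self.c_perfusate}")
        if self.c_dialysate < 0:
            raise ValueError(f"c_dialysate must be >= 0, got {self.c_dialysate}")


@dataclass(frozen=True)
class RecoveryEstimate:
    """Relative recovery of one catheter, percent of true tissue concentration.

    ``valid`` is False for physically impossible recoveries (≤ 0 or > 100),
    which mark a malfunctioning probe; such catheters are excluded downstream.
    """

    catheter_id: str
    rr_percent: float
    valid: bool = True


def relative_recovery(cal: CalibrationRecord) -> RecoveryEstimate:
    """Relative recovery from one calibration sample.

    RR = 100 · (1 − C_dialysate/C_perfusate).  An RR outside (0, 100]
    (dialysate gained drug, or lost none/all implausibly) is returned with
    ``valid=False`` rather than raising: probe failure is data, not a bug.
    """
    rr = 100.0 * (1.0 - cal.c_dialysate / cal.c_perfusate)
    return RecoveryEstimate(cal.catheter_id, rr, valid=0.0 < rr <= 100.0)


def tissue_concentration(c_dialysate: float, rr_percent: float):
    """Absolute free tissue concentration: 100 · C_dialysate / RR.

    Linear in ``c_dialysate``; accepts scalars or arrays.
    """
    if np.any(np.asarray(rr_percent) <= 0):
        raise ValueError("relative recovery must be > 0 percent")
    if np.any(np.asarray(c_dialysate) < 0):
        raise ValueError("dialysate concentration must be >= 0")
    return 100.0 * np.asarray(c_dialysate) / rr_percent if np.ndim(c_dialysate) else 100.0 * c_dialysate / rr_percent


def catheter_recoveries(calibration: pd.DataFrame) -> pd.DataFrame:
    """Per-catheter RR from a calibration table.

    Expects columns ``catheter_id, c_perfusate_ug_ml, c_dialysate_ug_ml`` and
    optionally ``animal_id, tissue, sample_label``.  When a catheter has
    several calibration samples (the usual two, C1 and C2), the mean of the
    per-sample RRs is used.  Returns one row per catheter with columns
    ``catheter_id, rr_percent, valid`` plus any grouping columns present.
    """
    required = {"catheter_id", "c_perfusate_ug_ml", "c_dialysate_ug_ml"}
    missing = required - set(calibration.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")

    rows = []
    keep = [c for c in ("animal_id", "tissue", "organ") if c in calibration.columns]
    for cath, grp in calibration.groupby("catheter_id", sort=True):
        rrs = [
            relative_recovery(
                CalibrationRecord(str(cath), row.c_perfusate_ug_ml, row.c_dialysate_ug_ml)
            ).rr_percent
            for row in grp.itertuples()
        ]
        rr = float(np.mean(rrs))
        rec = {"catheter_id": cath, "rr_percent": rr, "valid": 0.0 < rr <= 100.0}
        for c in keep:
            rec[c] = grp[c].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def pool_recovery(recoveries: pd.DataFrame, group_col: str = "tissue") -> pd.DataFrame:
    """Mean and sample SD (n−1) of valid catheter RRs per tissue compartment.

    Mirrors how recovery tables are reported: compartment, mean, SD, n.
    Groups with a single catheter get SD = NaN; empty groups (all catheters
    invalid) are dropped with a warning.
    """
    if group_col not in recoveries.columns:
        raise ValueError(f"no column {group_col!r} in recovery table")
    out = []
    for tissue, grp in recoveries.groupby(group_col, sort=True):
        ok = grp[grp["valid"]] if "valid" in grp.columns else grp
        if len(ok) == 0:
            warnings.warn(f"no valid calibrated catheters for {tissue!r}; omitted")
            continue
        vals = ok["rr_percent"].to_numpy(float)
        out.append(
            {
                group_col: tissue,
                "mean_rr": float(vals.mean()),
                "sd_rr": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(out)


def correct_observations(
    observations: pd.DataFrame,
    recoveries: pd.DataFrame,
    *,
    lloq: float | None = None,
    censored_handling: str = "drop",
) -> pd.DataFrame:
    """Convert dialysate observations to tissue concentrations.

    Parameters
    ----------
    observations : DataFrame
        Columns ``animal_id, tissue, catheter_id, t_start_min, t_end_min,
        c_dialysate_ug_ml, censored``.
    recoveries : DataFrame
        Output of :func:`catheter_recoveries`; catheters flagged invalid are
        excluded entirely.
    lloq : float, optional
        Assay quantification limit (µg/mL) used for ``lloq_half`` imputation.
    censored_handling : {"drop", "keep", "lloq_half"}
        ``drop`` removes censored rows (the conservative default), ``keep``
        retains them flagged, ``lloq_half`` imputes LLOQ/2 on the dialysate
        scale before correction and clears the flag.

    Returns the observation table with an added ``c_tissue_ug_ml`` column.
    """
    if censored_handling not in {"drop", "keep", "lloq_half"}:
        raise ValueError(f"unknown censored_handling {censored_handling!r}")
    rr = recoveries.set_index("catheter_id")["rr_percent"]
    valid = recoveries.set_index("catheter_id")["valid"] if "valid" in recoveries.columns else None

    obs = observations.copy()
    known = obs["catheter_id"].isin(rr.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        warnings.warn(f"dropping {n_unknown} observations from uncalibrated catheters")
        obs = obs[known]
    if valid is not None:
        obs = obs[obs["catheter_id"].map(valid).astype(bool)]

    obs = obs.copy()
    if censored_handling == "drop":
        obs = obs[~obs["censored"].astype(bool)].copy()
    elif censored_handling == "lloq_half":
        if lloq is None:
            raise ValueError("lloq must be given for lloq_half imputation")
        cens = obs["censored"].astype(bool)
        obs.loc[cens, "c_dialysate_ug_ml"] = lloq / 2.0
        obs["censored"] = False

    obs["c_tissue_ug_ml"] = 100.0 * obs["c_dialysate_ug_ml"] / obs["catheter_id"].map(rr)
    return obs.reset_index(drop=True)
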