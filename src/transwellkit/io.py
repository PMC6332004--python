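"""CSV readers and writers for the pipeline's interchange schemas.

CSV is the interchange format throughout (there is no domain-standard
container for transwell transport data).  Readers validate column
presence up front and raise
:class:`~transwellkit.errors.InputValidationError` naming the missing
columns, so a schema slip fails loudly at the boundary rather than
deep in an estimator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationStandard
from .errors import InputValidationError
from .kinetics import InsertGeometry, PappEstimate, TransportSeries, normalize_direction
from .qspr import CompoundRecord

__all__ = [
    "require_columns",
    "read_transport_csv",
    "read_calibration_csv",
    "read_compounds_csv",
    "read_fluorescence_csv",
    "papp_estimates_frame",
    "read_papp_estimates_csv",
    "write_transport_csv",
]


def require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputValidationError(
            f"{what}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_transport_csv(
    path: str | Path,
    geometry: InsertGeometry | None = None,
) -> list[TransportSeries]:
    """Read per-timepoint receiver amounts into TransportSeries objects.

    Required columns: compound_id, direction, replicate, time_min,
    receiver_amount_umol, donor_conc_uM.  Optional: teer_ohm_cm2,
    area_cm2 (overrides the geometry default per row group).
    Rows are grouped by (compound_id, direction, replicate); each group
    becomes one series, with a ``source_rows`` provenance not carried
    on the frozen series but recoverable from the returned ordering.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    require_columns(
        df,
        ["compound_id", "direction", "replicate", "time_min",
         "receiver_amount_umol", "donor_conc_uM"],
        f"transport CSV {path}",
    )
    geometry = geometry or InsertGeometry()
    series: list[TransportSeries] = []
    df = df.assign(_row=np.arange(len(df)))
    df["direction"] = df["direction"].map(normalize_direction)
    for (cid, direction, rep), grp in df.groupby(
        ["compound_id", "direction", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        geo = geometry
        if "area_cm2" in grp.columns and grp["area_cm2"].notna().any():
            geo = InsertGeometry(
                area=float(grp["area_cm2"].dropna().iloc[0]),
                vol_ap=geometry.vol_ap,
                vol_bl=geometry.vol_bl,
            )
        teer = None
        if "teer_ohm_cm2" in grp.columns and grp["teer_ohm_cm2"].notna().any():
            teer = float(grp["teer_ohm_cm2"].dropna().iloc[0])
        series.append(
            TransportSeries(
                compound_id=str(cid),
                direction=direction,
                replicate=int(rep),
                times=tuple(grp["time_min"]),
                q_cum=tuple(grp["receiver_amount_umol"]),
                c0=float(grp["donor_conc_uM"].iloc[0]),
                geometry=geo,
                teer=teer,
            )
        )
    if not series:
        raise InputValidationError(f"transport CSV {path} holds no data rows")
    return series


def write_transport_csv(series: Sequence[TransportSeries], path: str | Path) -> None:
    """Inverse of :func:`read_transport_csv` (one row per timepoint)."""
    rows = []
    for s in series:
        for t, q in zip(s.times, s.q_cum):
            rows.append(
                {
                    "compound_id": s.compound_id,
                    "direction": s.direction,
                    "replicate": s.replicate,
                    "time_min": t,
                    "receiver_amount_umol": q,
                    "donor_conc_uM": s.c0,
                    "teer_ohm_cm2": s.teer,
                    "area_cm2": s.geometry.area,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> pd.DataFrame:
    """Calibration/QC table: compound_id, day, level_uM, peak_area[, cycle]."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    require_columns(
        df, ["compound_id", "level_uM", "peak_area"], f"calibration CSV {path}"
    )
    return df


def standards_from_frame(df: pd.DataFrame) -> list[CalibrationStandard]:
    return [
        CalibrationStandard(
            compound_id=str(r.compound_id),
            nominal_conc=float(r.level_uM),
            peak_area=float(r.peak_area),
        )
        for r in df.itertuples(index=False)
    ]


def read_compounds_csv(path: str | Path) -> dict[str, CompoundRecord]:
    """Compound table: compound_id, mw, logd[, name]."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    require_columns(df, ["compound_id", "mw", "logd"], f"compound CSV {path}")
    records = {}
    for r in df.itertuples(index=False):
        records[str(r.compound_id)] = CompoundRecord(
            compound_id=str(r.compound_id),
            name=str(getattr(r, "name", r.compound_id)),
            mw=float(r.mw),
            logd=float(r.logd),
        )
    return records


def read_fluorescence_csv(path: str | Path) -> pd.DataFrame:
    """Fluorescence table: arm, replicate, intensity."""
    df = pd.read_csv(path)
    require_columns(df, ["arm", "intensity"], f"fluorescence CSV {path}")
    return df


def papp_estimates_frame(estimates: Sequence[PappEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [e.compound_id for e in estimates],
            "direction": [e.direction for e in estimates],
            "papp_mean_cm_s": [e.mean for e in estimates],
            "papp_sd_cm_s": [e.sd for e in estimates],
            "n": [e.n for e in estimates],
        }
    )


def read_papp_estimates_csv(path: str | Path) -> list[PappEstimate]:
    df = pd.read_csv(path, dtype={"compound_id": str})
    require_columns(
        df,
        ["compound_id", "direction", "papp_mean_cm_s", "papp_sd_cm_s", "n"],
        f"Papp estimate CSV {path}",
    )
    return [
        PappEstimate(
            compound_id=str(r.compound_id),
            direction=str(r.direction),
            mean=float(r.papp_mean_cm_s),
            sd=float(r.papp_sd_cm_s),
            n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]
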