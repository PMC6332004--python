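"""Packaged reference tables for the twelve-coumarin BBB transport study.

Bidirectional Papp means ± SD (n = 6, 50 µM donor, 90 min endpoint,
MDCK-pHaMDR monolayer), log D at pH 7.4, TEER readings, and the
rhodamine-123 / verapamil P-gp control runs (n = 4) are shipped as
small CSV fixtures and exposed here as DataFrames and domain objects.

Molecular weights are a fixture computed by this package's authors
from molecular formulas — they are not part of the measured tables.
Angepubebisin's formula is not published; its entry is a constructed
stand-in (``source == "assumed_formula"``) and should be treated as
approximate.

The compound labelled ``3`` carries a known internal inconsistency:
its printed efflux ratio (0.96) does not equal the ratio of its
printed directional means (27.38/37.10 ≈ 0.74).  This package always
computes ratios from the means and flags the discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

from .kinetics import AP_TO_BL, BL_TO_AP, PappEstimate
from .qspr import CompoundRecord

__all__ = [
    "coumarin_table",
    "rh123_table",
    "molecular_weights",
    "ReferenceStudy",
    "reference_study",
    "COUMARIN_IDS",
    "MARKER_IDS",
]

COUMARIN_IDS = tuple(str(i) for i in range(1, 13))
MARKER_IDS = ("caffeine", "atenolol")

_DATA = files("transwellkit") / "data"


def coumarin_table() -> pd.DataFrame:
    """Bidirectional permeability table: 12 coumarins + 2 marker compounds.

    Papp columns are in units of 1e-6 cm/s, as conventionally printed.
    """
    return pd.read_csv(_DATA / "coumarin_transport.csv", dtype={"compound_id": str})


def rh123_table() -> pd.DataFrame:
    """Rh123 transport and intracellular accumulation, ± 100 µM verapamil.

    Papp columns are in units of 1e-7 cm/s.
    """
    return pd.read_csv(_DATA / "rh123_transport.csv")


def molecular_weights() -> pd.DataFrame:
    """Molecular-weight fixture (g/mol), derived from molecular formulas."""
    return pd.read_csv(_DATA / "coumarin_mw_fixture.csv", dtype={"compound_id": str})


@dataclass(frozen=True)
class ReferenceStudy:
    """The reference tables lifted into domain objects."""

    papp: dict[tuple[str, str], PappEstimate]  # (compound_id, direction) → estimate
    compounds: dict[str, CompoundRecord]
    teer: dict[str, float]
    printed_ratios: dict[str, float]
    rh123: pd.DataFrame


def reference_study() -> ReferenceStudy:
    """Assemble the packaged tables into analysis-ready objects."""
    tab = coumarin_table()
    mw = molecular_weights().set_index("compound_id")
    papp: dict[tuple[str, str], PappEstimate] = {}
    teer: dict[str, float] = {}
    printed: dict[str, float] = {}
    compounds: dict[str, CompoundRecord] = {}
    for row in tab.itertuples(index=False):
        cid = row.compound_id
        n = int(row.n)
        papp[(cid, AP_TO_BL)] = PappEstimate(
            cid, AP_TO_BL, row.papp_apbl_1e6 * 1e-6, row.papp_apbl_sd_1e6 * 1e-6, n
        )
        if pd.notna(row.papp_blap_1e6):
            papp[(cid, BL_TO_AP)] = PappEstimate(
                cid, BL_TO_AP, row.papp_blap_1e6 * 1e-6, row.papp_blap_sd_1e6 * 1e-6, n
            )
        teer[cid] = float(row.teer_mean)
        if pd.notna(row.printed_efflux_ratio):
            printed[cid] = float(row.printed_efflux_ratio)
        if cid in mw.index and pd.notna(row.logd_ph74):
            compounds[cid] = CompoundRecord(
                compound_id=cid,
                name=row.name,
                mw=float(mw.loc[cid, "mw"]),
                logd=float(row.logd_ph74),
            )
    return ReferenceStudy(
        papp=papp,
        compounds=compounds,
        teer=teer,
        printed_ratios=printed,
        rh123=rh123_table(),
    )
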