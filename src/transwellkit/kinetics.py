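"""Transwell transport kinetics: cumulative amounts → appearance rates → Papp.

The apparent permeability coefficient is

    Papp = (dQ/dt) / (A · C0)        [cm/s]

with Q the cumulative amount in the receiver compartment (µmol), dQ/dt
its linear appearance rate (µmol/s), A the insert membrane area (cm²)
and C0 the initial donor concentration.  Internally all amounts are
µmol, times seconds and concentrations µmol/cm³; donor concentrations
enter the API in µM and are divided by 1000 exactly once, at the
boundary, so a silent 1000× unit slip cannot occur downstream.

dQ/dt is estimated by through-origin least squares (Q(0) = 0 is
physical, so no intercept is granted); a single-timepoint endpoint
experiment reduces to Q/t automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputValidationError, MissingTeerWarning

__all__ = [
    "AP_TO_BL",
    "BL_TO_AP",
    "InsertGeometry",
    "TransportSeries",
    "PappEstimate",
    "MassBalance",
    "normalize_direction",
    "teer_gate",
    "appearance_rate",
    "papp",
    "papp_estimate",
    "mass_balance",
    "rate_profile",
    "rate_vs_concentration",
]

AP_TO_BL = "AP-BL"
BL_TO_AP = "BL-AP"

_DIRECTION_ALIASES = {
    "ap-bl": AP_TO_BL,
    "ap->bl": AP_TO_BL,
    "ap→bl": AP_TO_BL,
    "apbl": AP_TO_BL,
    "a-b": AP_TO_BL,
    "bl-ap": BL_TO_AP,
    "bl->ap": BL_TO_AP,
    "bl→ap": BL_TO_AP,
    "blap": BL_TO_AP,
    "b-a": BL_TO_AP,
}


def normalize_direction(direction: str) -> str:
    """Map the common spellings of a transport direction onto AP-BL / BL-AP."""
    key = direction.strip().lower().replace(" ", "")
    try:
        return _DIRECTION_ALIASES[key]
    except KeyError:
        raise InputValidationError(
            f"unrecognized transport direction {direction!r}; "
            f"expected one of AP-BL / BL-AP"
        ) from None


@dataclass(frozen=True)
class InsertGeometry:
    """Transwell insert geometry (12-well format defaults).

    area is the membrane surface in cm²; the default 1.12 cm² is the
    standard 12 mm insert.  Compartment volumes are in mL (≡ cm³):
    0.5 mL apical, 1.5 mL basolateral.
    """

    area: float = 1.12
    vol_ap: float = 0.5
    vol_bl: float = 1.5

    def __post_init__(self) -> None:
        for name in ("area", "vol_ap", "vol_bl"):
            if not getattr(self, name) > 0:
                raise InputValidationError(f"{name} must be > 0")

    def donor_receiver_volumes(self, direction: str) -> tuple[float, float]:
        """(donor, receiver) volumes in cm³ for a transport direction."""
        if normalize_direction(direction) == AP_TO_BL:
            return self.vol_ap, self.vol_bl
        return self.vol_bl, self.vol_ap


@dataclass(frozen=True)
class TransportSeries:
    """Cumulative receiver-side amounts over time for one replicate.

    times are minutes (strictly increasing), q_cum the cumulative
    amount in the receiver (µmol), c0 the initial donor concentration
    in µM.  teer (Ω·cm²) is optional monolayer-integrity metadata.
    """

    compound_id: str
    direction: str
    replicate: int
    times: tuple[float, ...]
    q_cum: tuple[float, ...]
    c0: float
    geometry: InsertGeometry = field(default_factory=InsertGeometry)
    teer: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", normalize_direction(self.direction))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "q_cum", tuple(float(q) for q in self.q_cum))
        if len(self.times) != len(self.q_cum):
            raise InputValidationError("times and q_cum must have equal length")
        if len(self.times) == 0:
            raise InputValidationError("a series needs at least one time point")
        t = np.asarray(self.times)
        if np.any(np.diff(t) <= 0):
            raise InputValidationError("times must be strictly increasing")
        if np.any(np.asarray(self.q_cum) < 0):
            raise InputValidationError("q_cum must be non-negative")
        if not self.c0 > 0:
            raise InputValidationError(f"c0 must be > 0, got {self.c0!r}")

    @property
    def times_s(self) -> np.ndarray:
        return np.asarray(self.times) * 60.0

    @property
    def c0_umol_cm3(self) -> float:
        """Donor concentration converted µM → µmol/cm³."""
        return self.c0 / 1000.0


@dataclass(frozen=True)
class PappEstimate:
    """Aggregated apparent permeability for one compound × direction (cm/s)."""

    compound_id: str
    direction: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", normalize_direction(self.direction))
        if self.n < 1:
            raise InputValidationError("n must be ≥ 1")
        if self.sd < 0:
            raise InputValidationError("sd must be ≥ 0")


@dataclass(frozen=True)
class MassBalance:
    """Recovery and intracellular accumulation as % of the dosed amount."""

    compound_id: str
    recovery_pct: float
    intracellular_pct: float
    flags: tuple[str, ...] = ()


def teer_gate(series: TransportSeries, threshold: float = 1000.0) -> bool:
    """Monolayer-integrity gate: TEER must exceed ``threshold`` Ω·cm².

    A series with no TEER reading passes, with a
    :class:`~transwellkit.errors.MissingTeerWarning`.
    """
    if not threshold > 0:
        raise InputValidationError("TEER threshold must be > 0")
    if series.teer is None:
        warnings.warn(
            f"series {series.compound_id!r} {series.direction} rep "
            f"{series.replicate} has no TEER reading; gate passes by default",
            MissingTeerWarning,
            stacklevel=2,
        )
        return True
    return series.teer > threshold


def appearance_rate(series: TransportSeries) -> float:
    """Linear appearance rate dQ/dt in the receiver, µmol/s.

    Through-origin least squares of cumulative amount on time; for a
    single-timepoint endpoint measurement this reduces to Q(t)/t.
    """
    t = series.times_s
    q = np.asarray(series.q_cum)
    nonzero = t != 0.0
    if not nonzero.any():
        raise DegenerateInputError("all sampling times are zero; rate undefined")
    if len(t) == 1:
        return float(q[0] / t[0])
    # Through-origin slope: argmin_b sum (q - b t)^2 = Σtq / Σt².
    return float(np.dot(t, q) / np.dot(t, t))


def papp(series: TransportSeries) -> float:
    """Apparent permeability for one replicate series, cm/s."""
    rate = appearance_rate(series)  # µmol/s
    denom = series.geometry.area * series.c0_umol_cm3
    if denom <= 0:
        raise InputValidationError("area·C0 must be positive")
    return rate / denom


def papp_estimate(series_group: Iterable[TransportSeries]) -> PappEstimate:
    """Aggregate replicate series into a mean ± SD permeability estimate.

    All series must share compound and direction; SD is the sample SD
    (ddof=1), reported as 0 for a single replicate.
    """
    group = list(series_group)
    if not group:
        raise InputValidationError("empty series group")
    keys = {(s.compound_id, s.direction) for s in group}
    if len(keys) != 1:
        raise InputValidationError(
            f"series group mixes compound/direction: {sorted(keys)}"
        )
    values = np.array([papp(s) for s in group])
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    (compound_id, direction), = keys
    return PappEstimate(
        compound_id=compound_id,
        direction=direction,
        mean=float(values.mean()),
        sd=sd,
        n=values.size,
    )


def mass_balance(
    compound_id: str,
    donor_initial: float,
    donor_final: float,
    receiver_final: float,
    intracellular: float,
    *,
    recovery_min_pct: float = 85.0,
    intracellular_max_pct: float = 7.0,
) -> MassBalance:
    """Mass balance across donor, receiver and cell compartments (µmol in).

    recovery_pct = (donor_final + receiver_final + intracellular) /
    donor_initial × 100; intracellular_pct analogously.  A recovery
    below ``recovery_min_pct`` or intracellular accumulation above
    ``intracellular_max_pct`` adds a flag (the pattern of a compound
    retained in or lost to the monolayer).
    """
    if not donor_initial > 0:
        raise InputValidationError("donor_initial must be > 0")
    for name, v in (
        ("donor_final", donor_final),
        ("receiver_final", receiver_final),
        ("intracellular", intracellular),
    ):
        if v < 0:
            raise InputValidationError(f"{name} must be ≥ 0, got {v!r}")
    recovery = (donor_final + receiver_final + intracellular) / donor_initial * 100.0
    intra = intracellular / donor_initial * 100.0
    flags: list[str] = []
    if recovery < recovery_min_pct:
        flags.append(f"low_recovery(<{recovery_min_pct:g}%)")
    if intra > intracellular_max_pct:
        flags.append(f"high_intracellular(>{intracellular_max_pct:g}%)")
    return MassBalance(
        compound_id=compound_id,
        recovery_pct=float(recovery),
        intracellular_pct=float(intra),
        flags=tuple(flags),
    )


def _trend(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """OLS slope of y on x and its sign (0 for flat within fp noise)."""
    if np.unique(x).size < 2:
        return 0.0, 0
    slope = float(stats.linregress(x, y).slope)
    scale = max(abs(y).max(), 1e-300)
    sign = 0 if abs(slope) * (x.max() - x.min()) < 1e-9 * scale else int(np.sign(slope))
    return slope, sign


def rate_profile(series: TransportSeries) -> tuple[pd.DataFrame, dict]:
    """Per-interval transport rates and their trend over time.

    Returns a table with one row per sampling interval (ΔQ/Δt in
    µmol/s, interval midpoint in min) and a summary dict holding the
    slope of rate vs midpoint time and its sign — the time-dependence
    diagnostic: constant rates under sink conditions, linearly
    declining rates as the receiver saturates.
    """
    t = series.times_s
    q = np.asarray(series.q_cum)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        q = np.concatenate([[0.0], q])
    if len(t) < 3:
        raise DegenerateInputError("rate profile needs ≥2 intervals")
    rates = np.diff(q) / np.diff(t)
    mid_min = (t[:-1] + t[1:]) / 2.0 / 60.0
    table = pd.DataFrame(
        {
            "compound_id": series.compound_id,
            "direction": series.direction,
            "replicate": series.replicate,
            "t_start_min": t[:-1] / 60.0,
            "t_end_min": t[1:] / 60.0,
            "t_mid_min": mid_min,
            "rate_umol_s": rates,
        }
    )
    slope, sign = _trend(mid_min, rates)
    return table, {"slope_umol_s_per_min": slope, "trend_sign": sign}


def rate_vs_concentration(
    series_by_conc: Sequence[TransportSeries],
) -> tuple[pd.DataFrame, dict]:
    """Appearance rate as a function of donor concentration.

    Takes one series per donor concentration (a concentration sweep at
    a fixed endpoint), returns the per-concentration rates plus the
    overall rate-vs-C0 slope, and — when ≥4 concentrations are present —
    the low-half vs high-half slopes whose ratio exposes saturation
    (transport rate bending over above the saturating concentration).
    """
    if len(series_by_conc) < 2:
        raise DegenerateInputError("concentration sweep needs ≥2 concentrations")
    c0 = np.array([s.c0 for s in series_by_conc])
    order = np.argsort(c0)
    c0 = c0[order]
    rates = np.array([appearance_rate(series_by_conc[i]) for i in order])
    table = pd.DataFrame(
        {
            "compound_id": [series_by_conc[i].compound_id for i in order],
            "direction": [series_by_conc[i].direction for i in order],
            "c0_uM": c0,
            "rate_umol_s": rates,
        }
    )
    slope, sign = _trend(c0, rates)
    summary = {"slope_umol_s_per_uM": slope, "trend_sign": sign}
    if len(c0) >= 4:
        half = len(c0) // 2
        lo, _ = _trend(c0[:half], rates[:half])
        hi, _ = _trend(c0[half:], rates[half:])
        summary["low_half_slope"] = lo
        summary["high_half_slope"] = hi
        summary["saturating"] = bool(hi < 0.8 * lo) if lo > 0 else False
    return table, summary
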