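"""Linear HPLC calibration curves and bioanalytical QC metrics.

Detector response for the compounds handled here is linear in
concentration over the validated range, so each compound gets an
ordinary least-squares line ``peak_area = slope * conc + intercept``
with the Pearson correlation ``r`` reported alongside, exactly as
bioanalytical method-validation reports print it.  Concentrations of
unknowns are recovered by inverting the line (back-calculation), and
method performance is summarised by intraday / interday precision
(relative standard deviations), accuracy against nominal, and
freeze–thaw stability — all in percent.

Units: concentrations are µM throughout this module; peak areas are
unitless detector response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InputValidationError,
    OutOfRangeWarning,
)

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "QcReport",
    "fit_calibration",
    "back_calculate",
    "qc_metrics",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: nominal concentration and its peak area."""

    compound_id: str
    nominal_conc: float  # µM
    peak_area: float

    def __post_init__(self) -> None:
        if not self.nominal_conc > 0:
            raise InputValidationError(
                f"nominal_conc must be > 0, got {self.nominal_conc!r} "
                f"for {self.compound_id!r}"
            )
        if not np.isfinite(self.peak_area):
            raise InputValidationError(
                f"peak_area must be finite, got {self.peak_area!r} "
                f"for {self.compound_id!r}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line ``area = slope * conc + intercept`` with its validated range."""

    compound_id: str
    slope: float  # area per µM
    intercept: float  # area
    r: float  # Pearson correlation of (conc, area)
    range_low: float  # µM
    range_high: float  # µM

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise DegenerateInputError(
                f"calibration slope must be > 0, got {self.slope!r}"
            )
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise InputValidationError(f"r out of [-1, 1]: {self.r!r}")
        if not self.range_low < self.range_high:
            raise InputValidationError(
                f"range_low must be < range_high, got "
                f"[{self.range_low}, {self.range_high}]"
            )

    def predict(self, conc: float) -> float:
        """Forward model: expected peak area at a concentration (µM)."""
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class QcReport:
    """Precision / accuracy / stability summary at one QC level.

    All fields are percentages.  ``interday_rsd`` is ``None`` when only a
    single day of replicates was supplied; ``freeze_thaw_pct`` is ``None``
    when no freeze–thaw arm was measured.
    """

    compound_id: str
    level: float  # µM nominal
    intraday_rsd: float
    interday_rsd: float | None
    accuracy: float
    freeze_thaw_pct: float | None = None
    freeze_thaw_ok: bool | None = None


def fit_calibration(
    standards: Iterable[CalibrationStandard],
    *,
    weighting: str | None = None,
) -> CalibrationCurve:
    """Fit a linear calibration curve for one compound.

    Parameters
    ----------
    standards
        Calibration points for a single compound, at ≥3 distinct
        nominal concentrations.
    weighting
        ``None`` (default) for unweighted OLS, or ``"1/x"`` for
        inverse-concentration weighted least squares.  ``r`` is always
        the plain Pearson correlation of (x, y).

    Raises
    ------
    InputValidationError
        If standards mix compounds or the list is empty.
    DegenerateInputError
        If fewer than 3 distinct concentration levels are present, or
        the fitted slope is not positive (flat / inverted response).
    """
    stds = list(standards)
    if not stds:
        raise InputValidationError("no calibration standards supplied")
    ids = {s.compound_id for s in stds}
    if len(ids) != 1:
        raise InputValidationError(
            f"standards mix compounds: {sorted(ids)}; fit one compound at a time"
        )
    x = np.array([s.nominal_conc for s in stds], dtype=float)
    y = np.array([s.peak_area for s in stds], dtype=float)
    if np.unique(x).size < 3:
        raise DegenerateInputError(
            f"need ≥3 distinct concentration levels, got {np.unique(x).size}"
        )

    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif weighting == "1/x":
        w = 1.0 / x
        xm = np.average(x, weights=w)
        ym = np.average(y, weights=w)
        slope = float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))
        intercept = float(ym - slope * xm)
    else:
        raise InputValidationError(f"unknown weighting {weighting!r}")

    # r is reported as the Pearson correlation irrespective of weighting,
    # matching how linearity is quoted on validation reports.
    if np.ptp(y) == 0.0:
        r = 0.0  # flat response; the slope check below rejects it anyway
    else:
        r = float(stats.pearsonr(x, y).statistic)

    if slope <= 0:
        raise DegenerateInputError(
            f"non-positive calibration slope ({slope:g}) for {stds[0].compound_id!r}: "
            "flat or inverted detector response"
        )
    return CalibrationCurve(
        compound_id=stds[0].compound_id,
        slope=slope,
        intercept=intercept,
        r=r,
        range_low=float(x.min()),
        range_high=float(x.max()),
    )


def back_calculate(
    curve: CalibrationCurve, peak_area: float, *, warn: bool = True
) -> float:
    """Invert a calibration curve: peak area → concentration (µM).

    Values outside the validated range are returned unchanged but a
    :class:`~transwellkit.errors.OutOfRangeWarning` is emitted (set
    ``warn=False`` to silence); they are never clipped, so downstream
    code sees the data as measured.
    """
    conc = (peak_area - curve.intercept) / curve.slope
    if warn and not (curve.range_low <= conc <= curve.range_high):
        warnings.warn(
            f"back-calculated concentration {conc:.4g} µM for "
            f"{curve.compound_id!r} is outside the validated range "
            f"[{curve.range_low:g}, {curve.range_high:g}] µM",
            OutOfRangeWarning,
            stacklevel=2,
        )
    return float(conc)


def _as_day_groups(
    replicate_concs: Mapping[object, Sequence[float]] | Sequence[Sequence[float]],
) -> list[np.ndarray]:
    if isinstance(replicate_concs, Mapping):
        groups = [np.asarray(v, dtype=float) for _, v in sorted(replicate_concs.items(), key=lambda kv: str(kv[0]))]
    else:
        groups = [np.asarray(v, dtype=float) for v in replicate_concs]
    if not groups:
        raise InputValidationError("no QC replicate groups supplied")
    return groups


def qc_metrics(
    replicate_concs: Mapping[object, Sequence[float]] | Sequence[Sequence[float]],
    nominal: float,
    *,
    compound_id: str = "",
    freeze_thaw: tuple[Sequence[float], Sequence[float]] | None = None,
    freeze_thaw_window_pct: float = 5.0,
) -> QcReport:
    """Compute precision/accuracy QC metrics at one nominal level.

    ``replicate_concs`` groups back-calculated concentrations by day
    (mapping day → replicates, or a sequence of per-day sequences).

    * intraday RSD = pooled within-day SD / grand mean × 100
    * interday RSD = SD of day means / grand mean × 100 (needs ≥2 days)
    * accuracy     = grand mean / nominal × 100
    * freeze_thaw_pct = post-cycle mean / baseline mean × 100, with
      ``freeze_thaw_ok`` true when within ±``freeze_thaw_window_pct``
      of 100%.

    Raises
    ------
    DegenerateInputError
        If any day holds a single replicate (within-day SD undefined).
    """
    if not nominal > 0:
        raise InputValidationError(f"nominal must be > 0, got {nominal!r}")
    groups = _as_day_groups(replicate_concs)
    for g in groups:
        if g.size < 2:
            raise DegenerateInputError(
                "precision undefined: every day needs ≥2 replicates"
            )
    allvals = np.concatenate(groups)
    grand_mean = float(allvals.mean())
    if grand_mean == 0.0:
        raise DegenerateInputError("grand mean is zero; RSD undefined")

    dof = sum(g.size - 1 for g in groups)
    pooled_var = sum((g.size - 1) * g.var(ddof=1) for g in groups) / dof
    intraday = float(np.sqrt(pooled_var) / grand_mean * 100.0)

    interday: float | None = None
    if len(groups) >= 2:
        day_means = np.array([g.mean() for g in groups])
        interday = float(day_means.std(ddof=1) / grand_mean * 100.0)

    accuracy = grand_mean / nominal * 100.0

    ft_pct: float | None = None
    ft_ok: bool | None = None
    if freeze_thaw is not None:
        baseline, post = (np.asarray(a, dtype=float) for a in freeze_thaw)
        if baseline.size == 0 or post.size == 0:
            raise InputValidationError("freeze_thaw arms must be nonempty")
        ft_pct = float(post.mean() / baseline.mean() * 100.0)
        ft_ok = abs(ft_pct - 100.0) <= freeze_thaw_window_pct

    return QcReport(
        compound_id=compound_id,
        level=float(nominal),
        intraday_rsd=intraday,
        interday_rsd=interday,
        accuracy=float(accuracy),
        freeze_thaw_pct=ft_pct,
        freeze_thaw_ok=ft_ok,
    )
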