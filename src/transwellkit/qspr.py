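"""Piecewise-sigmoid lipophilicity–permeability model.

Permeability across a lipid barrier depends non-monotonically on
lipophilicity: too hydrophilic and the membrane rejects the solute,
too lipophilic and it partitions into (and stays in) the membrane.
This module models log10(Papp·MW^0.5) — the MW^0.5 factor absorbs the
diffusivity contribution of molecular size — as a function of log D at
pH 7.4 with two unit-amplitude logistic branches sharing a breakpoint:

    f(x) = 1/(1 + exp(-(b1·x - a1))) + c      x ≤ x0   (rising)
    f(x) = 1/(1 + exp(  b2·x - a2 )) + c      x > x0   (falling)

Continuity at the breakpoint is enforced structurally: the right
offset is derived, a2 = (b1 + b2)·x0 − a1, which makes both exponent
arguments equal at x0, so every representable model is continuous
there to machine precision.  ``PUBLISHED_MODEL`` holds the reference
parameterization (b1=2.9, a1=2.25, b2=3.3, c=−4.227, x0=2.5), whose
right offset is a2 = 13.25.

Fitting is bounded multi-start least squares over (b1, a1, b2, c) with
a2 eliminated by the constraint; the breakpoint is fixed by default
and can optionally be scanned over a grid with SSE selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInputError, InputValidationError
from .kinetics import AP_TO_BL, PappEstimate

__all__ = [
    "CompoundRecord",
    "QsprPoint",
    "SigmoidModel",
    "SigmoidFit",
    "PUBLISHED_MODEL",
    "qspr_point",
    "evaluate_sigmoid",
    "sigmoid_derivative",
    "fit_sigmoid",
    "permeability_band",
]

SLOPE_MAX = 20.0
C_BOUNDS = (-8.0, 0.0)
PLATEAU_THRESHOLD = 0.6  # |df/dx| per log D unit; see permeability_band


@dataclass(frozen=True)
class CompoundRecord:
    """Identity, molecular weight (g/mol) and log D (pH 7.4) of a compound."""

    compound_id: str
    name: str
    mw: float
    logd: float

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise InputValidationError(f"mw must be > 0, got {self.mw!r}")


@dataclass(frozen=True)
class QsprPoint:
    """One point of the model plane: x = log D, y = log10(Papp·MW^0.5)."""

    compound_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise InputValidationError("y must be finite")


@dataclass(frozen=True)
class SigmoidModel:
    """Two logistic branches linked continuously at breakpoint x0.

    b1/b2 are the left/right slopes (>0), a1 the left offset, c the
    vertical offset; the right offset a2 is derived from the continuity
    constraint and exposed as a property.  ``amplitude`` defaults to 1
    (the standard form); it is only ≠1 when fitted with the amplitude
    freed.
    """

    b1: float
    a1: float
    b2: float
    c: float
    x0: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.b1 > 0 and self.b2 > 0):
            raise InputValidationError("branch slopes b1, b2 must be > 0")
        if not self.amplitude > 0:
            raise InputValidationError("amplitude must be > 0")

    @property
    def a2(self) -> float:
        """Right-branch offset implied by continuity at x0."""
        return (self.b1 + self.b2) * self.x0 - self.a1

    def to_dict(self) -> dict:
        return {
            "b1": self.b1,
            "a1": self.a1,
            "b2": self.b2,
            "a2": self.a2,
            "c": self.c,
            "x0": self.x0,
            "amplitude": self.amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidModel":
        return cls(
            b1=d["b1"], a1=d["a1"], b2=d["b2"], c=d["c"], x0=d["x0"],
            amplitude=d.get("amplitude", 1.0),
        )


PUBLISHED_MODEL = SigmoidModel(b1=2.9, a1=2.25, b2=3.3, c=-4.227, x0=2.5)


def qspr_point(papp_est: PappEstimate, compound: CompoundRecord) -> QsprPoint:
    """Map an AP→BL permeability estimate onto the model plane.

    y = log10(Papp · MW^0.5) with Papp in cm/s; x = log D.
    """
    if papp_est.compound_id != compound.compound_id:
        raise InputValidationError(
            f"mismatched compounds: {papp_est.compound_id!r} vs "
            f"{compound.compound_id!r}"
        )
    if papp_est.direction != AP_TO_BL:
        raise InputValidationError("QSPR uses the AP→BL estimate")
    if not papp_est.mean > 0:
        raise InputValidationError("Papp must be > 0 to take its logarithm")
    y = math.log10(papp_est.mean * math.sqrt(compound.mw))
    return QsprPoint(compound_id=compound.compound_id, x=compound.logd, y=y)


def _branch_argument(model: SigmoidModel, x: np.ndarray) -> np.ndarray:
    return np.where(x <= model.x0, model.b1 * x - model.a1, model.a2 - model.b2 * x)


def evaluate_sigmoid(model: SigmoidModel, x):
    """Evaluate the piecewise model at x (scalar or array of log D)."""
    xa = np.asarray(x, dtype=float)
    z = _branch_argument(model, xa)
    out = model.amplitude / (1.0 + np.exp(-z)) + model.c
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def sigmoid_derivative(model: SigmoidModel, x):
    """df/dx of the piecewise model (negative on the falling branch)."""
    xa = np.asarray(x, dtype=float)
    z = _branch_argument(model, xa)
    s = 1.0 / (1.0 + np.exp(-z))
    slope = np.where(xa <= model.x0, model.b1, -model.b2)
    out = model.amplitude * slope * s * (1.0 - s)
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


@dataclass(frozen=True)
class SigmoidFit:
    """Result of :func:`fit_sigmoid`: model, goodness of fit, diagnostics."""

    model: SigmoidModel
    sse: float
    residuals: tuple[float, ...]
    n_points: int
    degenerate: bool
    x0_scanned: tuple[float, ...] | None = None

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sse / self.n_points)


def _fit_fixed_x0(
    x: np.ndarray,
    y: np.ndarray,
    x0: float,
    free_amplitude: bool,
) -> tuple[np.ndarray, float]:
    """Multi-start bounded least squares at one breakpoint; returns (params, sse)."""

    def residuals(p: np.ndarray) -> np.ndarray:
        b1, a1, b2, c = p[:4]
        amp = p[4] if free_amplitude else 1.0
        a2 = (b1 + b2) * x0 - a1
        z = np.where(x <= x0, b1 * x - a1, a2 - b2 * x)
        return amp / (1.0 + np.exp(-z)) + c - y

    left = x[x <= x0]
    a1_anchor = float(np.median(left)) if left.size else x0 - 1.0
    c0 = float(np.clip(y.min() - 0.1, C_BOUNDS[0], C_BOUNDS[1]))
    lo = [1e-6, -np.inf, 1e-6, C_BOUNDS[0]]
    hi = [SLOPE_MAX, np.inf, SLOPE_MAX, C_BOUNDS[1]]
    if free_amplitude:
        lo.append(1e-6)
        hi.append(5.0)

    best: tuple[np.ndarray, float] | None = None
    starts = [0.5, 1.5, 3.0, 6.0]
    for b1_0 in starts:  # 16 deterministic starts: slope grid × slope grid
        for b2_0 in starts:
            p0 = [b1_0, b1_0 * a1_anchor, b2_0, c0]
            if free_amplitude:
                p0.append(1.0)
            try:
                res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if not res.success:
                continue
            sse = float(2.0 * res.cost)
            if best is None or sse < best[1]:
                best = (res.x, sse)
    if best is None:
        raise DegenerateInputError(
            "sigmoid fit failed to converge from any start; inspect the points"
        )
    return best


def fit_sigmoid(
    points: Sequence[QsprPoint],
    x0: float | Iterable[float] = 2.5,
    *,
    free_amplitude: bool = False,
) -> SigmoidFit:
    """Fit the linked two-branch sigmoid to QSPR points.

    Parameters
    ----------
    points
        At least 5 points with support on both sides of the breakpoint.
    x0
        A fixed breakpoint (default 2.5 log D units) or an iterable of
        candidate breakpoints, in which case the one minimising SSE is
        selected.
    free_amplitude
        Free the sigmoid amplitude (default fixed at 1).

    The fit is flagged ``degenerate`` when a branch slope lands on its
    bound (the data do not constrain that branch, e.g. constant y).
    """
    if len(points) < 5:
        raise DegenerateInputError("need ≥5 points to fit the sigmoid")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)

    candidates = [float(x0)] if np.isscalar(x0) else [float(v) for v in x0]
    if not candidates:
        raise InputValidationError("empty breakpoint grid")
    for cand in candidates:
        if not ((x <= cand).any() and (x > cand).any()):
            raise DegenerateInputError(
                f"all points on one side of breakpoint {cand:g}; fit under-determined"
            )

    best_params, best_sse, best_x0 = None, np.inf, candidates[0]
    for cand in candidates:
        params, sse = _fit_fixed_x0(x, y, cand, free_amplitude)
        if sse < best_sse:
            best_params, best_sse, best_x0 = params, sse, cand

    b1, a1, b2, c = best_params[:4]
    amp = float(best_params[4]) if free_amplitude else 1.0
    model = SigmoidModel(
        b1=float(b1), a1=float(a1), b2=float(b2), c=float(c), x0=best_x0,
        amplitude=amp,
    )
    resid = evaluate_sigmoid(model, x) - y
    degenerate = bool(
        np.ptp(y) < 1e-12
        or min(b1, b2) <= 2e-6
        or max(b1, b2) >= SLOPE_MAX - 1e-6
    )
    return SigmoidFit(
        model=model,
        sse=float(np.sum(resid**2)),
        residuals=tuple(float(r) for r in resid),
        n_points=len(points),
        degenerate=degenerate,
        x0_scanned=None if np.isscalar(x0) else tuple(candidates),
    )


def permeability_band(
    model: SigmoidModel,
    logd: float,
    *,
    plateau_threshold: float = PLATEAU_THRESHOLD,
) -> str:
    """Assign a log D value to a region of the permeability curve.

    "high-plateau" where the model is locally flat (|df/dx| below
    ``plateau_threshold`` per log D unit), otherwise "descending-left"
    below the breakpoint and "descending-right" above it.  The default
    threshold 0.6 is calibrated on the reference model so that the
    moderate-lipophilicity compounds (log D ≈ 1.0–3.5) land on the
    plateau while the extremes fall on the descending flanks; it is a
    tuning parameter, not a physical constant.
    """
    if abs(sigmoid_derivative(model, logd)) < plateau_threshold:
        return "high-plateau"
    return "descending-left" if logd <= model.x0 else "descending-right"
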