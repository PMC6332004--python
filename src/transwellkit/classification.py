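"""Efflux ratios, absorption classes, P-gp candidacy and inhibitor contrasts.

The efflux ratio Papp(BL→AP)/Papp(AP→BL) summarises directional
asymmetry across the monolayer: ratios near 1 are consistent with
passive diffusion, ratios well above 1 (or well below, for a polarised
uptake/efflux mix) implicate a transporter such as P-glycoprotein.
Absorption classes follow the conventional Papp thresholds for
well- (> 1×10⁻⁵ cm/s) and poorly (< 1×10⁻⁶ cm/s) absorbed compounds,
anchored by caffeine and atenolol marker runs.  Inhibitor experiments
(verapamil for P-gp) are summarised by the percent drop in efflux
ratio with a Welch two-sample test on per-replicate ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputValidationError
from .kinetics import AP_TO_BL, BL_TO_AP, PappEstimate

__all__ = [
    "EffluxResult",
    "InhibitionResult",
    "AccumulationResult",
    "ValidationReport",
    "absorption_class",
    "efflux_ratio",
    "inhibition_contrast",
    "accumulation_fold",
    "model_validation_report",
]

WELL_CUTOFF = 1e-5  # cm/s; strictly above → well absorbed
POOR_CUTOFF = 1e-6  # cm/s; strictly below → poorly absorbed
PASSIVE_RATIO_CUTOFF = 2.0
PGP_HIGH_BAND = 1.9
PGP_LOW_BAND = 0.55


@dataclass(frozen=True)
class EffluxResult:
    compound_id: str
    ratio: float
    ratio_sd: float | None
    ratio_sd_method: str | None  # "paired" | "propagated" | None
    absorption_class: str  # well | moderate | poor
    pgp_candidate: bool
    transport_mode: str  # passive-consistent | efflux-suspected


@dataclass(frozen=True)
class InhibitionResult:
    compound_id: str
    ratio_without: float
    ratio_with: float
    pct_change: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class AccumulationResult:
    probe_id: str
    fold_change: float


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    reasons: tuple[str, ...]


def absorption_class(
    ap_bl: PappEstimate,
    *,
    well_cutoff: float = WELL_CUTOFF,
    poor_cutoff: float = POOR_CUTOFF,
) -> str:
    """Classify AP→BL permeability as well / moderate / poor.

    Strict inequalities: a mean exactly on either cutoff is moderate.
    """
    if not ap_bl.mean > 0:
        raise InputValidationError("AP→BL mean Papp must be > 0")
    if ap_bl.mean > well_cutoff:
        return "well"
    if ap_bl.mean < poor_cutoff:
        return "poor"
    return "moderate"


def efflux_ratio(
    ap_bl: PappEstimate,
    bl_ap: PappEstimate,
    *,
    paired_replicates: tuple[Sequence[float], Sequence[float]] | None = None,
    passive_cutoff: float = PASSIVE_RATIO_CUTOFF,
    pgp_high: float = PGP_HIGH_BAND,
    pgp_low: float = PGP_LOW_BAND,
    well_cutoff: float = WELL_CUTOFF,
    poor_cutoff: float = POOR_CUTOFF,
) -> EffluxResult:
    """Efflux ratio Papp(BL→AP)/Papp(AP→BL) with classification flags.

    ``paired_replicates`` optionally supplies the per-replicate
    (AP→BL, BL→AP) permeabilities from the same insert pairing; when
    present the ratio SD is the sample SD of the paired per-replicate
    ratios, otherwise it falls back to first-order error propagation
    from the two means ± SDs (labelled ``"propagated"``).

    A ratio at or above ``pgp_high`` or at or below ``pgp_low`` marks a
    P-gp candidate (asymmetry strong enough to warrant an inhibitor
    experiment); a ratio below ``passive_cutoff`` is labelled
    passive-consistent.
    """
    if ap_bl.compound_id != bl_ap.compound_id:
        raise InputValidationError(
            f"mismatched compounds: {ap_bl.compound_id!r} vs {bl_ap.compound_id!r}"
        )
    if {ap_bl.direction, bl_ap.direction} != {AP_TO_BL, BL_TO_AP}:
        raise InputValidationError("need one AP-BL and one BL-AP estimate")
    if ap_bl.direction != AP_TO_BL:
        raise InputValidationError("first argument must be the AP-BL estimate")
    if not ap_bl.mean > 0:
        raise InputValidationError("AP→BL mean is zero; ratio undefined")
    if not bl_ap.mean > 0:
        raise InputValidationError("BL→AP mean must be > 0")

    ratio = bl_ap.mean / ap_bl.mean

    ratio_sd: float | None
    method: str | None
    if paired_replicates is not None:
        a, b = (np.asarray(v, dtype=float) for v in paired_replicates)
        if a.shape != b.shape or a.size < 2:
            raise InputValidationError(
                "paired_replicates needs two equal-length arrays of ≥2 values"
            )
        ratio_sd = float((b / a).std(ddof=1))
        method = "paired"
    elif ap_bl.sd > 0 or bl_ap.sd > 0:
        ratio_sd = ratio * math.sqrt(
            (ap_bl.sd / ap_bl.mean) ** 2 + (bl_ap.sd / bl_ap.mean) ** 2
        )
        method = "propagated"
    else:
        ratio_sd, method = None, None

    return EffluxResult(
        compound_id=ap_bl.compound_id,
        ratio=float(ratio),
        ratio_sd=ratio_sd,
        ratio_sd_method=method,
        absorption_class=absorption_class(
            ap_bl, well_cutoff=well_cutoff, poor_cutoff=poor_cutoff
        ),
        pgp_candidate=bool(ratio >= pgp_high or ratio <= pgp_low),
        transport_mode=(
            "passive-consistent" if ratio < passive_cutoff else "efflux-suspected"
        ),
    )


def inhibition_contrast(
    without: Sequence[float],
    with_inhibitor: Sequence[float],
    *,
    compound_id: str = "",
    alpha: float = 0.01,
) -> InhibitionResult:
    """Contrast per-replicate efflux ratios with vs without an inhibitor.

    pct_change = (ratio_without − ratio_with) / ratio_without × 100,
    computed on the arm means.  Significance is a Welch (unequal
    variance) two-sample t-test at ``alpha`` (default 0.01).  With a
    single replicate in either arm no test is run: the percent change
    is still reported, p is NaN, and a warning is emitted.
    """
    a = np.asarray(without, dtype=float)
    b = np.asarray(with_inhibitor, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputValidationError("both arms must be nonempty")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a == 0:
        raise DegenerateInputError("baseline mean ratio is zero")
    pct = (mean_a - mean_b) / mean_a * 100.0
    if a.size < 2 or b.size < 2:
        warnings.warn(
            "single replicate in an arm: percent change reported, no test run",
            UserWarning,
            stacklevel=2,
        )
        return InhibitionResult(compound_id, mean_a, mean_b, pct, math.nan, False)
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return InhibitionResult(
        compound_id=compound_id,
        ratio_without=mean_a,
        ratio_with=mean_b,
        pct_change=float(pct),
        p_value=p,
        significant=bool(p < alpha),
    )


def accumulation_fold(
    baseline: Sequence[float],
    inhibited: Sequence[float],
    *,
    probe_id: str = "Rh123",
) -> AccumulationResult:
    """Fold change of intracellular probe fluorescence under inhibition."""
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(inhibited, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputValidationError("both fluorescence arms must be nonempty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise InputValidationError("fluorescence intensities must be positive")
    return AccumulationResult(probe_id, float(b.mean() / a.mean()))


def model_validation_report(
    caffeine: PappEstimate | None,
    atenolol: PappEstimate | None,
    rh123_inhibited_ratio: float | None,
    teer_values: Sequence[float],
    *,
    teer_threshold: float = 1000.0,
    well_cutoff: float = WELL_CUTOFF,
    poor_cutoff: float = POOR_CUTOFF,
) -> ValidationReport:
    """Monolayer-model suitability check from marker and probe runs.

    Passes when the well-absorbed marker (caffeine) classifies "well",
    the poorly absorbed marker (atenolol) classifies "poor", every TEER
    reading exceeds the gate threshold, and the P-gp probe's efflux
    ratio under inhibitor falls below 2.0 (functional, inhibitable
    efflux).  Missing markers are an error, not a silent pass.
    """
    missing = [
        name
        for name, v in (("caffeine", caffeine), ("atenolol", atenolol))
        if v is None
    ]
    if missing:
        raise InputValidationError(f"incomplete validation: missing marker(s) {missing}")
    reasons: list[str] = []
    if absorption_class(caffeine, well_cutoff=well_cutoff, poor_cutoff=poor_cutoff) != "well":
        reasons.append("well-marker (caffeine) not classified well")
    if absorption_class(atenolol, well_cutoff=well_cutoff, poor_cutoff=poor_cutoff) != "poor":
        reasons.append("poor-marker not poor")
    teers = np.asarray(teer_values, dtype=float)
    if teers.size and np.any(teers <= teer_threshold):
        reasons.append(
            f"TEER at or below {teer_threshold:g} Ω·cm² "
            f"(min {teers.min():g})"
        )
    if rh123_inhibited_ratio is not None and not rh123_inhibited_ratio < 2.0:
        reasons.append("P-gp probe efflux ratio not suppressed below 2.0 by inhibitor")
    return ValidationReport(passed=not reasons, reasons=tuple(reasons))
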