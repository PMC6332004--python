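"""Synthetic transwell experiments with known ground truth.

Generates the data-generating process the analysis assumes, so every
pipeline stage can be validated end-to-end without instrument data:

* **Sink mode** — receiver concentration stays negligible, cumulative
  receiver amount is exactly linear: Q(t) = Papp·A·C0·t.
* **Non-sink mode** — two well-mixed compartments exchanging through
  the monolayer; the receiver amount follows the closed form
  Q(t) = C0·Vd·(Vr/(Vd+Vr))·(1 − e^(−kt)) with
  k = Papp·A·(1/Vd + 1/Vr).  Cumulative transport still looks nearly
  linear early on while the interval transport *rate* declines — the
  signature of concentration saturation.
* **Efflux asymmetry** — phenomenological: Papp(BL→AP) =
  Papp(AP→BL)·(1 + asym) where the asymmetric component
  asym = (efflux_multiplier − 1)/(1 + C0/Km) saturates with donor
  concentration (Michaelis–Menten form; Km = ∞ disables saturation).
  An inhibitor arm shrinks the asymmetric component by
  ``inhibitor_effect`` (1.0 = full reversal to symmetric transport).
* **Noise** — multiplicative log-normal with unit mean, parameterized
  by a coefficient of variation in percent, emulating detector
  peak-area error that scales with signal.

One scenario seed drives an independent deterministic stream per
(arm, direction, replicate), so any subset of the design is
reproducible on its own.

Defaults mirror the bidirectional 12-well study conditions this
package targets: 50 µM donor concentration, 90-minute endpoint,
n = 6 replicates, 5% CV, 1.12 cm² insert with 0.5/1.5 mL compartments.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .calibration import CalibrationStandard
from .errors import InputValidationError
from .kinetics import AP_TO_BL, BL_TO_AP, InsertGeometry, TransportSeries

__all__ = [
    "SimScenario",
    "SimOutput",
    "directional_papp",
    "closed_form_q",
    "simulate_transport",
    "simulate_calibration",
]

_ARM_CODES = {"baseline": 0, "inhibited": 1}
_DIR_CODES = {AP_TO_BL: 0, BL_TO_AP: 1}


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth description of one simulated transport experiment."""

    true_papp: float = 2e-5  # cm/s, AP→BL
    efflux_multiplier: float = 2.0  # BL→AP = multiplier × AP→BL (before saturation)
    inhibitor_effect: float = 1.0  # 1.0 = inhibitor fully restores symmetry
    km: float = math.inf  # µM; saturation constant of the efflux component
    c0: float = 50.0  # µM donor concentration
    geometry: InsertGeometry = field(default_factory=InsertGeometry)
    times: tuple[float, ...] = (90.0,)  # minutes
    n_replicates: int = 6
    noise_cv: float = 5.0  # % multiplicative noise
    sink: bool = True
    seed: int = 0
    compound_id: str = "SIM"

    def __post_init__(self) -> None:
        if not self.true_papp > 0:
            raise InputValidationError("true_papp must be > 0")
        if not self.efflux_multiplier > 0:
            raise InputValidationError("efflux_multiplier must be > 0")
        if not 0.0 <= self.inhibitor_effect <= 1.0:
            raise InputValidationError("inhibitor_effect must be in [0, 1]")
        if not self.km > 0:
            raise InputValidationError("km must be > 0 (use inf for no saturation)")
        if not self.c0 > 0:
            raise InputValidationError("c0 must be > 0")
        if self.n_replicates < 1:
            raise InputValidationError("n_replicates must be ≥ 1")
        if self.noise_cv < 0:
            raise InputValidationError("noise_cv must be ≥ 0")
        if not self.times or any(t <= 0 for t in self.times):
            raise InputValidationError("times must be positive minutes")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))


@dataclass(frozen=True)
class SimOutput:
    """Simulated series plus the scenario they were generated from."""

    baseline: tuple[TransportSeries, ...]
    inhibited: tuple[TransportSeries, ...] | None
    ground_truth: dict

    def series_for(self, direction: str, arm: str = "baseline") -> list[TransportSeries]:
        pool = self.baseline if arm == "baseline" else (self.inhibited or ())
        return [s for s in pool if s.direction == direction]


def directional_papp(scenario: SimScenario, direction: str, inhibited: bool = False) -> float:
    """True permeability for a direction/arm implied by the scenario."""
    if direction == AP_TO_BL:
        return scenario.true_papp
    asym = (scenario.efflux_multiplier - 1.0) / (1.0 + scenario.c0 / scenario.km)
    if inhibited:
        asym *= 1.0 - scenario.inhibitor_effect
    return scenario.true_papp * (1.0 + asym)


def closed_form_q(
    papp_cm_s: float,
    c0_uM: float,
    geometry: InsertGeometry,
    direction: str,
    t_min: np.ndarray,
    sink: bool,
) -> np.ndarray:
    """Noiseless cumulative receiver amount (µmol) at times t (minutes)."""
    t_s = np.asarray(t_min, dtype=float) * 60.0
    c0 = c0_uM / 1000.0  # µmol/cm³
    a = geometry.area
    if sink:
        return papp_cm_s * a * c0 * t_s
    vd, vr = geometry.donor_receiver_volumes(direction)
    k = papp_cm_s * a * (1.0 / vd + 1.0 / vr)
    return c0 * vd * (vr / (vd + vr)) * (1.0 - np.exp(-k * t_s))


def _noise_factors(rng: np.random.Generator, cv_pct: float, n: int) -> np.ndarray:
    if cv_pct == 0.0:
        return np.ones(n)
    cv = cv_pct / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    # unit-mean log-normal: E[exp(N(-σ²/2, σ²))] = 1
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def simulate_transport(
    scenario: SimScenario,
    arms: Sequence[str] = ("baseline",),
) -> SimOutput:
    """Generate transport series for every direction × replicate × arm.

    The replicate index pairs series across directions (same index =
    same insert pairing), which downstream per-replicate efflux-ratio
    statistics rely on.
    """
    for arm in arms:
        if arm not in _ARM_CODES:
            raise InputValidationError(f"unknown arm {arm!r}")
    out: dict[str, list[TransportSeries]] = {a: [] for a in arms}
    t = np.asarray(scenario.times)
    for arm in arms:
        inhibited = arm == "inhibited"
        for direction in (AP_TO_BL, BL_TO_AP):
            p_true = directional_papp(scenario, direction, inhibited=inhibited)
            q_clean = closed_form_q(
                p_true, scenario.c0, scenario.geometry, direction, t, scenario.sink
            )
            for rep in range(scenario.n_replicates):
                rng = np.random.default_rng(
                    [scenario.seed, _ARM_CODES[arm], _DIR_CODES[direction], rep]
                )
                q = q_clean * _noise_factors(rng, scenario.noise_cv, t.size)
                out[arm].append(
                    TransportSeries(
                        compound_id=scenario.compound_id,
                        direction=direction,
                        replicate=rep,
                        times=tuple(t),
                        q_cum=tuple(q),
                        c0=scenario.c0,
                        geometry=scenario.geometry,
                    )
                )
    truth = asdict(scenario)
    truth["papp_ap_bl"] = directional_papp(scenario, AP_TO_BL)
    truth["papp_bl_ap"] = directional_papp(scenario, BL_TO_AP)
    truth["papp_bl_ap_inhibited"] = directional_papp(scenario, BL_TO_AP, inhibited=True)
    return SimOutput(
        baseline=tuple(out.get("baseline", ())),
        inhibited=tuple(out["inhibited"]) if "inhibited" in out else None,
        ground_truth=truth,
    )


def simulate_calibration(
    true_slope: float,
    true_intercept: float,
    levels: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    compound_id: str = "SIM",
    replicates: int = 1,
) -> list[CalibrationStandard]:
    """Peak areas on a known line with multiplicative detector noise."""
    if not levels:
        raise InputValidationError("levels must be nonempty")
    rng = np.random.default_rng([seed, 2])
    standards = []
    for _ in range(replicates):
        for x in levels:
            clean = true_slope * x + true_intercept
            area = float(clean * _noise_factors(rng, noise_cv, 1)[0])
            standards.append(
                CalibrationStandard(
                    compound_id=compound_id, nominal_conc=float(x), peak_area=area
                )
            )
    return standards
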