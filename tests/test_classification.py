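"""Efflux ratios, absorption classes, inhibitor contrasts, model validation."""

import numpy as np
import pytest

from transwellkit import (
    AP_TO_BL,
    BL_TO_AP,
    InputValidationError,
    PappEstimate,
    absorption_class,
    accumulation_fold,
    efflux_ratio,
    inhibition_contrast,
    model_validation_report,
    papp,
)
from transwellkit.simulate import SimScenario, simulate_transport


def est(mean, direction=AP_TO_BL, cid="X", sd=0.0, n=6):
    return PappEstimate(cid, direction, mean, sd, n)


class TestEffluxRatio:
    def test_asymmetric_transport_reference_compound(self, ref):
        r = efflux_ratio(ref.papp[("4", AP_TO_BL)], ref.papp[("4", BL_TO_AP)])
        assert round(r.ratio, 2) == 1.91
        assert r.pgp_candidate is True
        assert r.transport_mode == "passive-consistent"  # 1.91 < 2.0

    def test_symmetric_transport(self):
        r = efflux_ratio(est(2e-5), est(2e-5, BL_TO_AP))
        assert r.ratio == pytest.approx(1.0)
        assert r.transport_mode == "passive-consistent"
        assert r.pgp_candidate is False

    def test_low_band_candidate(self, ref):
        r = efflux_ratio(ref.papp[("10", AP_TO_BL)], ref.papp[("10", BL_TO_AP)])
        assert round(r.ratio, 2) == 0.51
        assert r.pgp_candidate is True

    def test_reciprocal_pairs_multiply_to_one(self):
        a, b = 9.91e-6, 18.97e-6
        fwd = efflux_ratio(est(a), est(b, BL_TO_AP))
        rev = efflux_ratio(est(b), est(a, BL_TO_AP))
        assert fwd.ratio * rev.ratio == pytest.approx(1.0, rel=1e-12)

    def test_paired_replicate_sd(self):
        ap = np.array([1.0, 1.1, 0.9]) * 1e-5
        bl = np.array([2.0, 2.3, 1.7]) * 1e-5
        r = efflux_ratio(
            est(ap.mean()), est(bl.mean(), BL_TO_AP), paired_replicates=(ap, bl)
        )
        assert r.ratio_sd == pytest.approx((bl / ap).std(ddof=1))
        assert r.ratio_sd_method == "paired"

    def test_propagated_sd_labelled(self):
        r = efflux_ratio(est(1e-5, sd=1e-6), est(2e-5, BL_TO_AP, sd=2e-6))
        assert r.ratio_sd_method == "propagated"
        assert r.ratio_sd == pytest.approx(2.0 * np.sqrt(0.1**2 + 0.1**2))

    def test_mismatched_compounds_rejected(self):
        with pytest.raises(InputValidationError):
            efflux_ratio(est(1e-5, cid="A"), est(1e-5, BL_TO_AP, cid="B"))


class TestAbsorptionClass:
    @pytest.mark.parametrize(
        "mean, expected",
        [
            (4.36e-5, "well"),  # caffeine marker
            (7.61e-7, "poor"),  # atenolol marker
            (9.91e-6, "moderate"),  # between the marker levels
            (1e-5, "moderate"),  # boundary is strict
            (1e-6, "moderate"),
        ],
    )
    def test_thresholds(self, mean, expected):
        assert absorption_class(est(mean)) == expected

    def test_monotone_in_papp(self):
        order = {"poor": 0, "moderate": 1, "well": 2}
        means = np.logspace(-7, -4, 40)
        classes = [order[absorption_class(est(m))] for m in means]
        assert classes == sorted(classes)


class TestInhibitionContrast:
    def test_probe_ratio_drop_from_arm_means(self):
        # arm means 4.47 and 1.58 → 64.65% decrease
        res = inhibition_contrast([4.51, 4.43], [1.60, 1.56], compound_id="Rh123")
        assert res.pct_change == pytest.approx((4.47 - 1.58) / 4.47 * 100, rel=1e-12)

    def test_identical_arms_not_significant(self):
        res = inhibition_contrast([2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        assert res.pct_change == pytest.approx(0.0)
        assert res.significant is False

    def test_single_replicate_reports_without_test(self):
        with pytest.warns(UserWarning):
            res = inhibition_contrast([4.47], [1.58])
        assert np.isnan(res.p_value)
        assert res.significant is False

    def test_power_abolished_efflux_detected(self):
        """Efflux multiplier 2 fully reversed, n=6, 5% CV → detected in ≥95% of 500 runs."""
        hits = 0
        for rep in range(500):
            scen = SimScenario(seed=rep)
            sim = simulate_transport(scen, arms=("baseline", "inhibited"))
            base = _paired_ratios(sim, "baseline")
            inh = _paired_ratios(sim, "inhibited")
            if inhibition_contrast(base, inh).significant:
                hits += 1
        assert hits / 500 >= 0.95

    def test_type_one_error_calibrated_under_null(self):
        """Symmetric-transport null: rejections at α=0.01 within binomial noise of 1%."""
        n_rep = 2000
        hits = 0
        for rep in range(n_rep):
            scen = SimScenario(efflux_multiplier=1.0, seed=100_000 + rep)
            sim = simulate_transport(scen, arms=("baseline", "inhibited"))
            if inhibition_contrast(
                _paired_ratios(sim, "baseline"), _paired_ratios(sim, "inhibited")
            ).significant:
                hits += 1
        rate = hits / n_rep
        assert rate <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n_rep)


def _paired_ratios(sim, arm):
    ap = sorted(sim.series_for(AP_TO_BL, arm), key=lambda s: s.replicate)
    bl = sorted(sim.series_for(BL_TO_AP, arm), key=lambda s: s.replicate)
    return [papp(b) / papp(a) for a, b in zip(ap, bl)]


class TestAccumulationFold:
    def test_probe_fold_change(self, ref):
        base = ref.rh123.loc[ref.rh123.arm == "baseline", "fluorescence_mean"].iloc[0]
        inh = ref.rh123.loc[
            ref.rh123.arm == "verapamil_100uM", "fluorescence_mean"
        ].iloc[0]
        assert round(accumulation_fold([base], [inh]).fold_change, 2) == 4.45

    @pytest.mark.parametrize(
        "base, inh, expected", [([10, 10], [30, 30], 3.0), ([5.0], [5.0], 1.0)]
    )
    def test_simple_folds(self, base, inh, expected):
        assert accumulation_fold(base, inh).fold_change == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(InputValidationError):
            accumulation_fold([0.0], [1.0])


class TestModelValidation:
    def _markers(self, ref):
        return (
            ref.papp[("caffeine", AP_TO_BL)],
            ref.papp[("atenolol", AP_TO_BL)],
        )

    def test_reference_markers_pass(self, ref):
        caffeine, atenolol = self._markers(ref)
        rep = model_validation_report(
            caffeine, atenolol, 1.58, list(ref.teer.values())
        )
        assert rep.passed is True
        assert rep.reasons == ()

    def test_poor_marker_not_poor_fails(self, ref):
        caffeine, _ = self._markers(ref)
        bad = est(5e-5, cid="atenolol")
        rep = model_validation_report(caffeine, bad, 1.58, [1500.0])
        assert rep.passed is False
        assert any("poor-marker not poor" in r for r in rep.reasons)

    def test_low_teer_fails(self, ref):
        caffeine, atenolol = self._markers(ref)
        rep = model_validation_report(caffeine, atenolol, 1.58, [1500.0, 800.0])
        assert rep.passed is False
        assert any("TEER" in r for r in rep.reasons)

    def test_missing_marker_is_error(self, ref):
        caffeine, _ = self._markers(ref)
        with pytest.raises(InputValidationError):
            model_validation_report(caffeine, None, 1.58, [1500.0])

    def test_uninhibited_probe_fails(self, ref):
        caffeine, atenolol = self._markers(ref)
        rep = model_validation_report(caffeine, atenolol, 4.47, [1500.0])
        assert rep.passed is False
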