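"""Appearance rates, Papp, TEER gate, mass balance and rate profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transwellkit import (
    AP_TO_BL,
    BL_TO_AP,
    DegenerateInputError,
    InputValidationError,
    InsertGeometry,
    MissingTeerWarning,
    appearance_rate,
    mass_balance,
    papp,
    papp_estimate,
    rate_profile,
    rate_vs_concentration,
    teer_gate,
)
from transwellkit.simulate import SimScenario, closed_form_q, directional_papp, simulate_transport
from conftest import make_series


class TestTeerGate:
    @pytest.mark.parametrize("teer, expected", [(1321.0, True), (999.9, False), (1000.0, False)])
    def test_threshold_is_strict(self, teer, expected):
        s = make_series([90.0], [0.5], teer=teer)
        assert teer_gate(s, 1000.0) is expected

    def test_missing_teer_passes_with_warning(self):
        s = make_series([90.0], [0.5], teer=None)
        with pytest.warns(MissingTeerWarning):
            assert teer_gate(s) is True


class TestAppearanceRate:
    def test_single_endpoint_uses_q_over_t(self):
        # 0.54 µmol over 90 min = 5400 s
        s = make_series([90.0], [0.54])
        assert appearance_rate(s) == pytest.approx(1.0e-4, rel=1e-12)

    def test_zero_transport_gives_zero_rate(self):
        s = make_series([30.0, 60.0, 90.0], [0.0, 0.0, 0.0])
        assert appearance_rate(s) == 0.0

    @pytest.mark.parametrize(
        "times", [[30, 60, 90], [10, 45, 60, 120, 180], [90]]
    )
    def test_exact_line_rate_independent_of_grid(self, times):
        q = [2e-4 * t * 60.0 for t in times]
        s = make_series(times, q)
        assert appearance_rate(s) == pytest.approx(2e-4, rel=1e-12)


class TestPapp:
    def test_hand_computed_value(self):
        # rate 1e-4 µmol/s, A = 1.12 cm², C0 = 50 µM = 0.05 µmol/cm³
        s = make_series([90.0], [0.54], c0=50.0)
        assert papp(s) == pytest.approx(1e-4 / (1.12 * 0.05), rel=1e-12)

    def test_zero_transport_zero_papp(self):
        s = make_series([30.0, 60.0], [0.0, 0.0])
        assert papp(s) == 0.0

    def test_sink_simulation_round_trip_exact(self):
        scen = SimScenario(true_papp=2e-5, noise_cv=0.0, times=(30, 60, 90))
        out = simulate_transport(scen)
        for s in out.series_for(AP_TO_BL):
            assert papp(s) == pytest.approx(2e-5, rel=1e-12)

    @given(factor=st.floats(0.1, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_joint_rescaling(self, factor):
        """Papp is unchanged when Q and C0 scale together (Eq. linearity)."""
        base = make_series([30, 90], [0.1, 0.3], c0=50.0)
        scaled = make_series(
            [30, 90], [0.1 * factor, 0.3 * factor], c0=50.0 * factor
        )
        assert papp(scaled) == pytest.approx(papp(base), rel=1e-9)

    def test_nonsink_estimate_converges_at_early_times(self):
        scen_early = SimScenario(noise_cv=0.0, sink=False, times=(1.0,))
        scen_late = SimScenario(noise_cv=0.0, sink=False, times=(180.0,))
        early = papp(simulate_transport(scen_early).series_for(AP_TO_BL)[0])
        late = papp(simulate_transport(scen_late).series_for(AP_TO_BL)[0])
        assert abs(early - 2e-5) / 2e-5 < 0.01  # early-time limit
        assert abs(late - 2e-5) > abs(early - 2e-5)  # saturation biases late sampling

    def test_aggregation_mixed_groups_rejected(self):
        a = make_series([90], [0.5], compound_id="A")
        b = make_series([90], [0.5], compound_id="B")
        with pytest.raises(InputValidationError):
            papp_estimate([a, b])

    def test_aggregation_mean_sd_n(self):
        group = [
            make_series([90], [q], replicate=i) for i, q in enumerate([0.5, 0.54, 0.58])
        ]
        est = papp_estimate(group)
        vals = np.array([papp(s) for s in group])
        assert est.mean == pytest.approx(vals.mean())
        assert est.sd == pytest.approx(vals.std(ddof=1))
        assert est.n == 3


class TestMassBalance:
    def test_complete_recovery(self):
        mb = mass_balance("x", 1.0, 0.40, 0.50, 0.05)
        assert mb.recovery_pct == pytest.approx(95.0)
        assert mb.intracellular_pct == pytest.approx(5.0)
        assert mb.flags == ()

    def test_low_recovery_high_intracellular_flagged(self):
        mb = mass_balance("11", 1.0, 0.30, 0.25, 0.11)
        assert mb.recovery_pct == pytest.approx(66.0)
        assert mb.intracellular_pct == pytest.approx(11.0)
        assert any("low_recovery" in f for f in mb.flags)
        assert any("high_intracellular" in f for f in mb.flags)

    def test_all_mass_in_donor(self):
        mb = mass_balance("x", 1.0, 1.0, 0.0, 0.0)
        assert mb.recovery_pct == pytest.approx(100.0)
        assert mb.intracellular_pct == 0.0

    def test_negative_amount_rejected(self):
        with pytest.raises(InputValidationError):
            mass_balance("x", 1.0, -0.1, 0.5, 0.0)

    def test_noiseless_simulation_conserves_mass(self):
        """Donor + receiver of the non-sink closed form is exactly the dose."""
        scen = SimScenario(noise_cv=0.0, sink=False, times=(30, 90, 180), n_replicates=1)
        geo = scen.geometry
        s = simulate_transport(scen).series_for(AP_TO_BL)[0]
        dose = scen.c0 / 1000.0 * geo.vol_ap
        q_end = s.q_cum[-1]
        mb = mass_balance("sim", dose, dose - q_end, q_end, 0.0)
        assert mb.recovery_pct == pytest.approx(100.0, abs=1e-10)


class TestRateProfiles:
    def test_nonsink_interval_rates_strictly_decrease(self):
        scen = SimScenario(
            noise_cv=0.0, sink=False, times=(30, 60, 90, 120, 150, 180), n_replicates=1
        )
        s = simulate_transport(scen).series_for(AP_TO_BL)[0]
        table, summary = rate_profile(s)
        rates = table["rate_umol_s"].to_numpy()
        assert np.all(np.diff(rates) < 0)
        assert summary["trend_sign"] == -1

    def test_sink_interval_rates_constant(self):
        scen = SimScenario(noise_cv=0.0, sink=True, times=(30, 60, 90, 120), n_replicates=1)
        s = simulate_transport(scen).series_for(AP_TO_BL)[0]
        table, summary = rate_profile(s)
        assert np.allclose(np.diff(table["rate_umol_s"]), 0.0, atol=1e-18)
        assert summary["trend_sign"] == 0

    def test_two_points_insufficient(self):
        with pytest.raises(DegenerateInputError):
            rate_profile(make_series([90.0], [0.5]))

    def test_saturable_efflux_bends_concentration_response(self):
        """BL→AP rate vs C0 flattens above Km; oracle is the closed form."""
        km = 50.0
        sweep = []
        expected = []
        for c0 in (10.0, 25.0, 50.0, 75.0, 100.0, 125.0):
            scen = SimScenario(km=km, c0=c0, noise_cv=0.0, n_replicates=1)
            s = simulate_transport(scen).series_for(BL_TO_AP)[0]
            sweep.append(s)
            p = directional_papp(scen, BL_TO_AP)
            expected.append(
                closed_form_q(p, c0, scen.geometry, BL_TO_AP, np.array([90.0]), True)[0]
                / 5400.0
            )
        table, summary = rate_vs_concentration(sweep)
        assert np.allclose(table["rate_umol_s"], expected, rtol=1e-12)
        assert summary["saturating"] is True
        assert summary["high_half_slope"] < summary["low_half_slope"]

    def test_linear_sweep_not_saturating(self):
        sweep = [
            make_series([90.0], [1e-5 * c0], c0=c0)
            for c0 in (10.0, 25.0, 50.0, 75.0, 100.0, 125.0)
        ]
        _, summary = rate_vs_concentration(sweep)
        assert summary["saturating"] is False


class TestGeometry:
    def test_donor_receiver_volumes_by_direction(self):
        g = InsertGeometry()
        assert g.donor_receiver_volumes(AP_TO_BL) == (0.5, 1.5)
        assert g.donor_receiver_volumes(BL_TO_AP) == (1.5, 0.5)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InputValidationError):
            InsertGeometry(area=0.0)
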