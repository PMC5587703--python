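"""Oxygen mass balance: closed-form breath-hold decline, tidal
integration, arterial transmission, and FIO2 calibration."""

import numpy as np
import pytest

from tidalox import (
    GasExchangeParams,
    SampledTrace,
    VentilatorSettings,
    alveolar_volume_at_eelv,
    arterial_transmission,
    calibrate_fio2,
    o2_content,
    o2_saturation,
    oscillation_stats,
    predict_breath_hold_decline,
    simulate_breath_hold,
    simulate_tidal,
)
from tidalox.errors import CalibrationError, InvalidParameterError
from tidalox.gas_exchange import PO2Trace, vo2_stpd_to_btps


class TestParamsAndVolumes:
    def test_alveolar_volume_from_eelv_minus_dead_space(self, params):
        # (22.3 - 3) ml/kg * 29 kg
        assert alveolar_volume_at_eelv(params) == pytest.approx(559.7)

    def test_zero_dead_space_degenerate(self):
        p = GasExchangeParams(vd_per_kg=0.0)
        assert alveolar_volume_at_eelv(p) == pytest.approx(22.3 * 29)

    def test_linearity_in_mass(self):
        p1 = GasExchangeParams(mass=29)
        p2 = GasExchangeParams(mass=58)
        assert alveolar_volume_at_eelv(p2) == pytest.approx(
            2 * alveolar_volume_at_eelv(p1)
        )

    def test_default_vo2_calibrated_from_end_expiratory_decline(self, params):
        # vo2 such that the decline is 6.9 mmHg/s at 559.7 ml
        assert params.vo2 == pytest.approx(6.9 * 559.7 / 713.0, rel=1e-9)
        assert params.vo2 == pytest.approx(5.416, abs=1e-3)

    def test_stpd_btps_conversion(self):
        v = vo2_stpd_to_btps(1.0, pb=760, ph2o=47)
        assert v == pytest.approx((760 / 713) * (310 / 273))

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParameterError):
            GasExchangeParams(eelv_per_kg=2.0, vd_per_kg=3.0)
        with pytest.raises(InvalidParameterError):
            GasExchangeParams(shunt=1.0)


class TestBreathHoldDecline:
    def test_inverse_proportionality(self, params):
        va = alveolar_volume_at_eelv(params)
        r1 = predict_breath_hold_decline(params, va)
        assert predict_breath_hold_decline(params, 2 * va) == pytest.approx(r1 / 2)

    def test_invalid_volume(self, params):
        with pytest.raises(InvalidParameterError):
            predict_breath_hold_decline(params, -10)

    def test_simulated_slope_matches_closed_form(self, params):
        va = alveolar_volume_at_eelv(params)
        tr = simulate_breath_hold(params, va, duration=20, initial_pao2=270)
        slope = -np.polyfit(tr.t, tr.pao2_alv, 1)[0]
        assert slope == pytest.approx(
            predict_breath_hold_decline(params, va), rel=0.005
        )

    def test_linear_extrapolation_20s(self, params):
        va = alveolar_volume_at_eelv(params)  # decline 6.9 mmHg/s
        tr = simulate_breath_hold(params, va, duration=20, initial_pao2=270)
        assert tr.pao2_alv[-1] == pytest.approx(270 - 6.9 * 20, abs=0.01)

    def test_decline_ordering_across_hold_volumes(self, params):
        va0 = alveolar_volume_at_eelv(params)
        rates = [
            predict_breath_hold_decline(params, va0 + dv * params.mass)
            for dv in (0.0, 10.0, 20.0)
        ]
        assert rates[0] > rates[1] > rates[2]

    def test_truncation_at_zero_fraction_floor(self, params):
        with pytest.warns(RuntimeWarning):
            tr = simulate_breath_hold(
                params, 100.0, duration=60, initial_pao2=150
            )
        assert tr.pao2_alv.min() > 0
        assert tr.t[-1] < 60


class TestTidalSimulation:
    def test_zero_uptake_equilibrates_to_fio2(self, mech):
        p = GasExchangeParams(vo2=1e-9)
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290,
                               peep=5, fio2=0.30)
        tr = simulate_tidal(s, mech, p, duration=240).last(30)
        fao2 = tr.pao2_alv / (p.pb - p.ph2o)
        assert np.allclose(fao2, 0.30, atol=1e-3)
        assert np.ptp(tr.pao2_alv) < 0.5

    def test_expiratory_rate_equals_inverse_volume_law(self, vc_rr12_trace, params):
        """During expiration the dilution term cancels: dP/dt is exactly
        -vo2*(pb-ph2o)/V_A."""
        tr = vc_rr12_trace
        exp = np.flatnonzero(tr.phase[:-1] == 1)[2000:4000]
        dpdt = np.diff(tr.pao2_alv)[exp] / tr.dt
        pred = -params.vo2 * (params.pb - params.ph2o) / tr.volume_ml[exp + 1]
        assert np.max(np.abs(dpdt - pred) / np.abs(pred)) < 0.01

    def test_o2_conservation_per_breath(self, vc_rr12_trace, params):
        """At periodic steady state, inspired minus expired O2 volume per
        breath equals vo2 times the breath period within 0.5%."""
        budget = vc_rr12_trace.meta["o2_budget"].iloc[-2]
        expected = params.vo2 * 5.0
        net = budget.inspired_ml - budget.expired_ml
        assert net == pytest.approx(expected, rel=0.005)

    def test_frozen_volume_matches_breath_hold_closed_form(self, mech, params):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290,
                               peep=5, fio2=0.33)
        tr = simulate_tidal(s, mech, params, duration=60, hold_s=10,
                            hold_phase="expiration")
        hold = tr.phase == 2
        slope = -np.polyfit(tr.t[hold], tr.pao2_alv[hold], 1)[0]
        va = tr.volume_ml[hold][0]
        assert slope == pytest.approx(
            predict_breath_hold_decline(params, va), rel=0.01
        )

    def test_oscillation_in_phase_with_volume(self, vc_rr12_trace):
        """Alveolar PO2 peaks shortly after end-inspiration: positive
        correlation with lung volume at steady state."""
        w = vc_rr12_trace.last(60)
        r = np.corrcoef(w.pao2_alv, w.volume_ml)[0, 1]
        assert r > 0.5


class TestArterialTransmission:
    def _trace(self, y, dt=0.01):
        n = len(y)
        z = np.zeros(n)
        return PO2Trace(t=np.arange(n) * dt, pao2_alv=np.asarray(y, float),
                        pao2_art=z.copy(), volume_ml=z + 500, paw_cmh2o=z)

    def test_identity_when_all_transforms_off(self):
        p = GasExchangeParams(transit_delay=0, sensor_tau=0, shunt=0)
        tr = self._trace(130 + 10 * np.sin(np.linspace(0, 20, 2000)))
        out = arterial_transmission(tr, p)
        assert np.allclose(out.pao2_art, tr.pao2_alv)

    def test_first_order_gain_on_sinusoid(self):
        """Amplitude attenuation 1/sqrt(1 + (2*pi*tau/T)^2) for a
        sinusoid of period T through the first-order sensor filter."""
        tau, period, dt = 0.8, 5.0, 0.005
        p = GasExchangeParams(transit_delay=0, sensor_tau=tau, shunt=0)
        t = np.arange(0, 120, dt)
        tr = self._trace(130 + 10 * np.sin(2 * np.pi * t / period), dt=dt)
        out = arterial_transmission(tr, p)
        gain = np.ptp(out.pao2_art[-4000:]) / 20.0
        expected = 1 / np.sqrt(1 + (2 * np.pi * tau / period) ** 2)
        assert gain == pytest.approx(expected, rel=0.02)

    def test_shunt_attenuates_amplitude_not_frequency(self, vc_rr12_trace):
        p0 = GasExchangeParams(shunt=0.0)
        ps = GasExchangeParams(shunt=0.15)
        a0 = arterial_transmission(vc_rr12_trace, p0).last(60)
        a1 = arterial_transmission(vc_rr12_trace, ps).last(60)
        s0 = oscillation_stats(SampledTrace(a0.t, a0.pao2_art, a0.paw_cmh2o), 12, 60)
        s1 = oscillation_stats(SampledTrace(a1.t, a1.pao2_art, a1.paw_cmh2o), 12, 60)
        assert s1.amplitude_mean < s0.amplitude_mean
        assert s1.mean_pao2 < s0.mean_pao2
        assert s1.n_breaths == s0.n_breaths

    def test_delay_longer_than_trace_rejected(self):
        p = GasExchangeParams(transit_delay=100.0)
        tr = self._trace(np.full(100, 130.0))
        with pytest.raises(InvalidParameterError):
            arterial_transmission(tr, p)


class TestDissociationCurve:
    def test_saturation_monotone_and_saturating(self):
        po2 = np.linspace(1, 600, 200)
        s = o2_saturation(po2)
        assert np.all(np.diff(s) > 0)
        assert o2_saturation(5000.0) > 0.999
        assert 0.4 < o2_saturation(27.0) < 0.6  # near P50

    def test_content_formula_at_full_saturation(self):
        # at saturation ~1: content = 1.34*hb + 0.003*po2
        c = o2_content(600.0, hb=10)
        assert c == pytest.approx(13.4 * o2_saturation(600.0) + 1.8, rel=1e-6)


class TestCalibrateFio2:
    def test_reaches_target_mean_130(self, vc_rr12_settings, mech, params):
        cal = calibrate_fio2(vc_rr12_settings, mech, params, target_mean=130)
        assert abs(cal.mean_pao2 - 130) <= 1.0
        assert 0.21 < cal.fio2 <= 1.0

    def test_monotone_in_target(self, vc_rr12_settings, mech, params):
        lo = calibrate_fio2(vc_rr12_settings, mech, params, target_mean=110)
        hi = calibrate_fio2(vc_rr12_settings, mech, params, target_mean=150)
        assert hi.fio2 > lo.fio2

    def test_unreachable_targets_raise(self, vc_rr12_settings, mech, params):
        with pytest.raises(CalibrationError):
            # below the physiologic floor
            calibrate_fio2(vc_rr12_settings, mech, params, target_mean=50.0)
        with pytest.raises(CalibrationError):
            # above the FIO2 = 1.0 ceiling
            calibrate_fio2(vc_rr12_settings, mech, params, target_mean=650.0)
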