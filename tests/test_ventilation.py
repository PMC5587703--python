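"""Ventilator waveform generation: timing, VC/PC breath shapes, steady
state, and pressure-volume relationships of the RC lung."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tidalox import (
    Mode,
    Phase,
    RespiratoryMechanics,
    VentilatorSettings,
    breath_timing,
    pc_breath,
    pc_pressure_for_vt,
    simulate_volume_trace,
    vc_breath,
)
from tidalox.errors import InvalidParameterError, ResolutionError


class TestBreathTiming:
    @pytest.mark.parametrize(
        "rr, ie, expected",
        [
            (12, 1.0, (2.5, 2.5)),
            (6, 0.25, (2.0, 8.0)),
            (12, 4.0, (4.0, 1.0)),
        ],
    )
    def test_known_splits(self, rr, ie, expected):
        assert breath_timing(rr, ie) == pytest.approx(expected)

    @pytest.mark.parametrize("rr, ie", [(0, 1), (-5, 1), (12, 0), (12, -2)])
    def test_nonpositive_inputs_rejected(self, rr, ie):
        with pytest.raises(InvalidParameterError):
            breath_timing(rr, ie)

    @given(
        rr=st.floats(1, 60, allow_nan=False),
        ie=st.floats(0.05, 20, allow_nan=False),
    )
    def test_partition_and_inversion(self, rr, ie):
        ti, te = breath_timing(rr, ie)
        assert ti > 0 and te > 0
        assert ti + te == pytest.approx(60.0 / rr)
        # inverting the I:E ratio swaps Ti and Te exactly
        ti2, te2 = breath_timing(rr, 1.0 / ie)
        assert ti2 == pytest.approx(te, rel=1e-9)
        assert te2 == pytest.approx(ti, rel=1e-9)


class TestVentilatorSettings:
    def test_mode_target_requirements(self):
        with pytest.raises(InvalidParameterError):
            VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0)  # no vt
        with pytest.raises(InvalidParameterError):
            VentilatorSettings(mode="PC", rr=12, ie_ratio=1.0)  # no p_insp

    def test_inverted_swaps_phase_durations(self):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=0.25, vt=290)
        inv = s.inverted()
        assert inv.ti == pytest.approx(s.te)
        assert inv.te == pytest.approx(s.ti)


class TestVCBreath:
    def test_constant_inspiratory_flow_and_delivered_volume(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        br = vc_breath(s, mech)
        insp = br.phase == Phase.INSP
        assert np.allclose(br.flow[insp], 290 / 2.5)  # vt / Ti = 116 ml/s
        # end-inspiratory volume above EELV equals the tidal volume
        assert br.volume_above_eelv.max() == pytest.approx(290, rel=1e-6)

    def test_expiration_decays_exponentially(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        br = vc_breath(s, mech)  # Te = 2.5 s of passive decay
        assert br.volume_above_eelv[-1] <= 290 * math.exp(-2.5 / mech.tau) * 1.05

    def test_peak_pressure_physiologic_at_10ml_per_kg(self, mech):
        # the reported peak airway pressure stayed below 13.6 cmH2O
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        br = vc_breath(s, mech)
        assert br.paw.max() < 13.6

    def test_resolution_guard(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290)
        with pytest.raises(ResolutionError):
            vc_breath(s, mech, dt=0.2)  # dt >= tau/5


class TestPCBreath:
    def test_rc_charging_closed_form(self):
        # C=25, tau=0.5, p_insp=12, Ti=2 s -> V(Ti) = 300*(1-e^-4)
        mech = RespiratoryMechanics(compliance=25, resistance=0.02)
        s = VentilatorSettings(
            mode="PC", rr=15, ie_ratio=1.0, p_insp=12, peep=5, rise_time=0.0
        )
        br = pc_breath(s, mech, dt=0.005)
        v_ti = br.volume_above_eelv[br.phase == Phase.INSP][-1]
        expected = 25 * 12 * (1 - math.exp(-2 / 0.5))
        assert v_ti == pytest.approx(expected, rel=2e-3)
        assert expected == pytest.approx(294.5, abs=0.1)

    def test_initial_flow_is_pressure_over_resistance(self, mech):
        s = VentilatorSettings(
            mode="PC", rr=12, ie_ratio=1.0, p_insp=10, peep=5, rise_time=0.0
        )
        br = pc_breath(s, mech)
        assert br.flow[0] == pytest.approx(10 / mech.resistance)

    def test_delivered_volume_monotone_in_pressure_and_ti(self, mech):
        def delivered(p_insp, ie):
            s = VentilatorSettings(
                mode="PC", rr=12, ie_ratio=ie, p_insp=p_insp, peep=5
            )
            br = pc_breath(s, mech)
            return br.volume_above_eelv.max()

        assert delivered(8, 1.0) < delivered(10, 1.0) < delivered(12, 1.0)
        assert delivered(10, 0.5) < delivered(10, 1.0) < delivered(10, 2.0)


class TestPCPressureForVT:
    def test_closed_form_value(self):
        mech = RespiratoryMechanics(compliance=25, resistance=0.02)
        p = pc_pressure_for_vt(290, mech, ti=2.0)
        assert p == pytest.approx(290 / (25 * (1 - math.exp(-4))), rel=1e-9)
        assert p == pytest.approx(11.81, abs=0.01)

    def test_long_ti_limit_is_vt_over_compliance(self, mech):
        p = pc_pressure_for_vt(290, mech, ti=50.0)
        assert p == pytest.approx(290 / mech.compliance, rel=1e-6)

    @pytest.mark.parametrize("rise_time", [0.0, 0.1])
    def test_round_trip_delivers_requested_volume(self, mech, rise_time):
        ti = 2.0
        p = pc_pressure_for_vt(580, mech, ti, rise_time=rise_time)
        s = VentilatorSettings(
            mode="PC", rr=6, ie_ratio=1.0 / 4.0, p_insp=p, peep=5,
            rise_time=rise_time,
        )
        br = pc_breath(s, mech, dt=0.002)
        assert br.volume_above_eelv.max() == pytest.approx(580, rel=1e-3)

    def test_steady_state_solution_compensates_incomplete_expiration(self, mech):
        """At 4:1 inverse ratio (Te = 1 s) expiration is incomplete; the
        steady-state pressure still delivers the target VT breath after
        breath."""
        from tidalox.ventilation import breath_timing

        ti, te = breath_timing(12, 4.0)
        p = pc_pressure_for_vt(290, mech, ti, rise_time=0.1, te=te)
        s = VentilatorSettings(mode="PC", rr=12, ie_ratio=4.0, p_insp=p,
                               peep=5, rise_time=0.1)
        tr = simulate_volume_trace(s, mech, n_breaths=12)
        last = tr.volume_above_eelv[-int(5 / tr.dt):]
        assert last.max() - last.min() == pytest.approx(290, rel=1e-3)
        # and it exceeds the single-breath pressure
        assert p > pc_pressure_for_vt(290, mech, ti, rise_time=0.1)

    def test_invalid_ti(self, mech):
        with pytest.raises(InvalidParameterError):
            pc_pressure_for_vt(290, mech, ti=0.0)


class TestSimulateVolumeTrace:
    def test_vc_peak_to_peak_equals_vt_every_breath(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        tr = simulate_volume_trace(s, mech, n_breaths=10)
        per_breath = tr.volume_above_eelv.reshape(10, -1)
        ptp = per_breath.max(axis=1) - per_breath.min(axis=1)
        assert np.allclose(ptp, 290, rtol=0.01)
        assert tr.converged

    def test_volume_never_below_eelv(self, mech):
        for ie in (0.25, 4.0):
            s = VentilatorSettings(mode="VC", rr=12, ie_ratio=ie, vt=290, peep=5)
            tr = simulate_volume_trace(s, mech, n_breaths=8)
            assert tr.volume_above_eelv.min() >= 0

    def test_mean_paw_increases_with_ie_ratio(self, mech):
        means = []
        for ie in (0.25, 0.5, 1.0, 2.0, 4.0):
            s = VentilatorSettings(mode="VC", rr=12, ie_ratio=ie, vt=290, peep=5)
            tr = simulate_volume_trace(s, mech, n_breaths=8)
            # steady-state breath only
            means.append(tr.paw[-int(5 / tr.dt):].mean())
        assert np.all(np.diff(means) > 0)

    def test_pc_inverse_ratio_raises_mean_paw_at_same_vt(self, mech):
        def mean_paw(ie):
            ti = breath_timing_ti = (ie / (1 + ie)) * 10.0
            p = pc_pressure_for_vt(580, mech, breath_timing_ti, rise_time=0.1)
            s = VentilatorSettings(
                mode="PC", rr=6, ie_ratio=ie, p_insp=p, peep=5, rise_time=0.1
            )
            tr = simulate_volume_trace(s, mech, n_breaths=6)
            return tr.paw[-int(10 / tr.dt):].mean()

        assert mean_paw(4.0) > mean_paw(0.25)

    def test_zero_breaths_rejected(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290)
        with pytest.raises(InvalidParameterError):
            simulate_volume_trace(s, mech, n_breaths=0)

    def test_hold_phases(self, mech):
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        tr = simulate_volume_trace(s, mech, 6, hold_s=10, hold_phase="inspiration")
        hold = tr.phase == Phase.HOLD
        assert hold.sum() == pytest.approx(1000, abs=2)
        v_hold = tr.volume_above_eelv[hold]
        assert np.allclose(v_hold, v_hold[0])
        assert np.all(tr.flow[hold] == 0)
        # inspiratory hold sits near end-inspiratory volume
        assert v_hold[0] == pytest.approx(290, rel=0.05)

    def test_nonconvergence_warns(self):
        slow = RespiratoryMechanics(compliance=25, resistance=0.2)  # tau 5 s
        s = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
        with pytest.warns(RuntimeWarning):
            tr = simulate_volume_trace(s, slow, n_breaths=2)
        assert not tr.converged
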