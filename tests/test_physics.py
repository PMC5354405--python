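"""Weak-shock heating, time-to-boil, derating, pulse timing and scheduling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bhkit.errors import InvalidInputError, NoBoilError
from bhkit.physics import (
    AcousticPulse,
    Medium,
    PressureMeasurement,
    SonicationPattern,
    derate_pressure,
    heating_rate,
    layer_target_area,
    pulse_timing,
    schedule,
    time_to_boil,
)
from bhkit.units import truncate

F0 = 1.2e6


class TestHeatingRate:
    def test_zero_amplitude_gives_zero(self, medium):
        assert heating_rate(0.0, medium, F0) == 0.0

    def test_hand_evaluated_value(self, medium):
        # beta f0 As^3 / (6 rho^2 c^4) at the 500 W peak-to-peak amplitude
        a_s = (65.97 + 10.98) * 1e6
        h = heating_rate(a_s, medium, F0)
        expected = 4 * 1.2e6 * a_s**3 / (6 * 1020**2 * 1544**4)
        assert h == pytest.approx(expected, rel=1e-12)
        assert h == pytest.approx(6.17e10, rel=5e-3)

    @given(
        a=st.floats(1e5, 1e8),
        scale=st.floats(1.1, 4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cubic_in_amplitude_linear_in_f_and_beta(self, a, scale):
        medium = Medium(beta=4.0, rho0=1020.0, c0=1544.0, cv=5.3e6)
        h1 = heating_rate(a, medium, F0)
        assert heating_rate(scale * a, medium, F0) == pytest.approx(
            scale**3 * h1, rel=1e-9
        )
        assert heating_rate(a, medium, scale * F0) == pytest.approx(scale * h1, rel=1e-9)
        medium2 = Medium(beta=4.0 * scale, rho0=1020.0, c0=1544.0, cv=5.3e6)
        assert heating_rate(a, medium2, F0) == pytest.approx(scale * h1, rel=1e-9)

    def test_negative_amplitude_rejected(self, medium):
        with pytest.raises(InvalidInputError):
            heating_rate(-1.0, medium, F0)


class TestTimeToBoil:
    def test_conservation_product(self, medium):
        # t_b * H = dT * cv identically
        for h in (1e9, 6.17e10, 3.3e12):
            assert time_to_boil(h, medium) * h == pytest.approx(
                medium.delta_t_boil * medium.cv, rel=1e-14
            )

    def test_zero_delta_t_boils_instantly(self):
        m = Medium(beta=4, rho0=1020, c0=1544, cv=5.3e6, baseline_temp=99.999999)
        assert time_to_boil(1e10, m) == pytest.approx(0.0, abs=1e-8)

    def test_non_positive_heating_raises_no_boil(self, medium):
        with pytest.raises(NoBoilError):
            time_to_boil(0.0, medium)

    def test_cubic_ratio_between_powers(self, medium, measurements):
        by_power = {m.acoustic_power: m for m in measurements}
        tb = {
            p: time_to_boil(heating_rate(m.shock_amplitude, medium, F0), medium)
            for p, m in by_power.items()
        }
        ratio = tb[500] / tb[650]
        expected = (by_power[650].shock_amplitude / by_power[500].shock_amplitude) ** 3
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(1.517, rel=1e-3)

    def test_strictly_decreasing_in_power(self, medium, measurements):
        tbs = [
            time_to_boil(heating_rate(m.shock_amplitude, medium, F0), medium)
            for m in sorted(measurements, key=lambda m: m.acoustic_power)
        ]
        assert all(a > b for a, b in zip(tbs, tbs[1:]))


class TestDerating:
    def test_identity_at_zero_depth_and_zero_attenuation(self):
        assert derate_pressure(5e6, 0.676, F0, 0.0) == 5e6
        assert derate_pressure(5e6, 0.0, F0, 3.0) == 5e6

    def test_hand_evaluated_factor(self):
        # 0.676 dB/cm/MHz * 1.2 MHz * 3 cm = 2.4336 dB -> 10^(-2.4336/20)
        factor = derate_pressure(1.0, 0.676, F0, 3.0)
        assert factor == pytest.approx(0.7557, abs=2e-4)

    @given(
        d1=st.floats(0.0, 5.0),
        d2=st.floats(0.0, 5.0),
        att=st.floats(0.0, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_composes_over_depth(self, d1, d2, att):
        p = 7e6
        two_step = derate_pressure(derate_pressure(p, att, F0, d1), att, F0, d2)
        assert two_step == pytest.approx(derate_pressure(p, att, F0, d1 + d2), rel=1e-12)


class TestPulseTiming:
    @pytest.mark.parametrize(
        "cycles, printed_ms",
        [(10000, 8.3), (12000, 10.0), (14000, 11.6), (15000, 12.5),
         (16000, 13.3), (18000, 15.0), (20000, 16.6)],
    )
    def test_pulse_length_matches_printed_truncated(self, cycles, printed_ms):
        pulse = AcousticPulse(600, F0, cycles, 1.0)
        ms, _ = pulse_timing(pulse)
        assert truncate(ms, 1) == pytest.approx(printed_ms, abs=1e-9)

    @pytest.mark.parametrize(
        "prf, printed_pct",
        [(0.5, 0.66), (1.0, 1.33), (2.0, 2.66), (3.0, 4.00), (4.0, 5.33), (5.0, 6.66)],
    )
    def test_duty_cycle_matches_printed_truncated(self, prf, printed_pct):
        pulse = AcousticPulse(600, F0, 16000, prf)
        _, pct = pulse_timing(pulse)
        assert truncate(pct, 2) == pytest.approx(printed_pct, abs=0.01)

    def test_invalid_pulse_rejected(self):
        with pytest.raises(InvalidInputError):
            AcousticPulse(600, 0.0, 15000, 1.0)
        with pytest.raises(InvalidInputError):
            AcousticPulse(600, F0, 1.2e6, 2.0)  # 100% duty cycle x2

    def test_cycles_roundtrip_within_half_cycle(self):
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        assert abs(pulse.pulse_length * pulse.frequency - 15000) < 0.5


class TestPressureMeasurement:
    def test_shock_amplitude_is_peak_to_peak(self):
        m = PressureMeasurement(500, 65.97, 10.98)
        assert m.shock_amplitude == pytest.approx((65.97 + 10.98) * 1e6)
        assert m.shock_amplitude > m.peak_positive * 1e6

    def test_ordering_invariant_enforced(self):
        with pytest.raises(InvalidInputError):
            PressureMeasurement(500, 10.0, 11.0)


class TestPattern:
    def test_coordinate_count_and_spacing(self):
        pat = SonicationPattern()
        coords = pat.focus_coordinates()
        assert coords.shape == (27, 3)
        # nearest neighbor distance equals the spacing for every focus
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1), pat.spacing_mm)

    def test_traversal_proximal_layer_first(self):
        coords = SonicationPattern().focus_coordinates()
        # beam axis z: first nine foci in the layer closest to the transducer
        assert np.all(coords[:9, 2] == coords[:9, 2].min())
        assert np.all(np.diff(coords[:, 2]) >= 0)


class TestLayerTargetArea:
    def test_matches_printed_13_mm2(self):
        area = layer_target_area(SonicationPattern(), 1.6)
        assert area == pytest.approx(12.96, abs=1e-9)
        assert round(area) == 13

    def test_degenerate_single_point(self):
        pat = SonicationPattern(grid_shape=(1, 1, 1))
        assert layer_target_area(pat, 2.0) == pytest.approx(4.0)

    def test_rectangular_layer(self):
        pat = SonicationPattern(grid_shape=(2, 2, 1), spacing_mm=2.0)
        assert layer_target_area(pat, 1.0) == pytest.approx(9.0)


class TestSchedule:
    def test_27_points_five_repeats(self):
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        sched = schedule(SonicationPattern(), pulse, repeats=5)
        assert len(sched) == 135
        assert sched.time_s.iloc[0] == 0.0
        assert sched.time_s.iloc[-1] == pytest.approx(134.0)

    def test_single_point_single_pulse(self):
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        sched = schedule(SonicationPattern(grid_shape=(1, 1, 1)), pulse, repeats=1)
        assert len(sched) == 1 and sched.time_s.iloc[0] == 0.0

    def test_prf_sweep_counts(self):
        pulse = AcousticPulse(600, F0, 16000, 5.0)
        sched = schedule(SonicationPattern(), pulse, repeats=15)
        assert len(sched) == 405
        # one pulse per location per visit: focus advances every pulse
        assert (sched.focus_index[:27] == np.arange(27)).all()

    def test_overhead_extends_duration(self):
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        base = schedule(SonicationPattern(), pulse, repeats=5)
        slow = schedule(
            SonicationPattern(), pulse, repeats=5, overhead_per_location_s=0.0148
        )
        assert slow.time_s.iloc[-1] > base.time_s.iloc[-1]

    def test_zero_repeats_rejected(self):
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        with pytest.raises(InvalidInputError):
            schedule(SonicationPattern(), pulse, repeats=0)
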