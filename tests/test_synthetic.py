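"""Forward models: pulsed heating simulation, PRFS rendering, lesion phantoms."""

import math

import numpy as np
import pytest

from bhkit.errors import InvalidInputError
from bhkit.physics import AcousticPulse, Medium, SonicationPattern, heating_rate
from bhkit.synthetic import (
    FocalField,
    GridSpec,
    LesionPhantomSpec,
    ThermometryGeometry,
    make_lesion_volume,
    max_stable_step,
    render_thermometry,
    simulate_sonication,
    voxel_average_temperature,
)

F0 = 1.2e6
SINGLE = SonicationPattern(grid_shape=(1, 1, 1))


def small_medium(**kw):
    defaults = dict(beta=4.0, rho0=1020.0, c0=1544.0, cv=5.3e6)
    defaults.update(kw)
    return Medium(**defaults)


def focal(a_s0: float) -> FocalField:
    return FocalField.from_minus6db_widths(a_s0)


class TestFocalField:
    def test_half_amplitude_at_minus6db_radius(self):
        f = focal(1.0e6)
        assert f.amplitude(0.8, 0.0, 0.0) == pytest.approx(0.5e6, rel=1e-9)
        assert f.amplitude(0.0, 0.0, 5.0) == pytest.approx(0.5e6, rel=1e-9)

    def test_nonnegative_and_peaked_at_center(self):
        f = focal(2.0e6)
        x = np.linspace(-5, 5, 21)
        vals = f.amplitude(x, 0.0, 0.0)
        assert (vals >= 0).all()
        assert vals.max() == pytest.approx(2.0e6)


class TestSimulate:
    def test_source_only_limit_no_diffusion(self):
        # diffusivity 0, single focus: peak rise is exactly N * H * tau / cv
        m = small_medium(thermal_diffusivity=0.0)
        pulse = AcousticPulse(600, F0, 6000, 1.0)  # 5 ms pulses
        a_s0 = 2.0e7  # modest amplitude: no clamping
        sim = simulate_sonication(
            SINGLE, pulse, m, focal(a_s0), GridSpec((9, 9, 9), 0.5),
            repeats=4, record_dt_s=1.0,
        )
        h = heating_rate(a_s0, m, F0)
        expected = 4 * h * pulse.pulse_length / m.cv
        rise = sim.temperature[-1].max() - m.baseline_temp
        assert rise == pytest.approx(expected, rel=1e-6)

    def test_boiling_within_one_pulse_clamps_and_fractionates(self):
        # H ~ 6e10 at tau = 12.5 ms implies a 141 degC jump: one pulse boils
        m = small_medium(thermal_diffusivity=0.0)
        pulse = AcousticPulse(500, F0, 15000, 1.0)
        a_s0 = (65.97 + 10.98) * 1e6
        h = heating_rate(a_s0, m, F0)
        assert h * pulse.pulse_length / m.cv == pytest.approx(145.4, abs=1.0)
        sim = simulate_sonication(
            SINGLE, pulse, m, focal(a_s0), GridSpec((9, 9, 9), 0.5),
            repeats=1, record_dt_s=0.5,
        )
        assert sim.temperature[-1].max() == pytest.approx(m.boiling_temp)
        assert sim.fractionated[-1].any()

    def test_zero_amplitude_stays_at_baseline(self):
        m = small_medium()
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        sim = simulate_sonication(
            SINGLE, pulse, m, FocalField(0.0, 0.68, 4.25), GridSpec((9, 9, 9), 0.5),
            repeats=2,
        )
        assert np.allclose(sim.temperature, m.baseline_temp)
        assert not sim.fractionated.any()

    def test_energy_bookkeeping_without_clamp(self):
        # with no diffusion and no clamp, total added heat equals
        # n_pulses * sum_vox H(r) * tau * voxel_volume
        m = small_medium(thermal_diffusivity=0.0)
        pulse = AcousticPulse(600, F0, 15000, 2.0)
        a_s0 = 5.0e7
        grid = GridSpec((15, 15, 21), 0.5)
        n_pulses = 6
        sim = simulate_sonication(
            SINGLE, pulse, m, focal(a_s0), grid,
            repeats=n_pulses, clamp_boiling=False, record_dt_s=1.0,
        )
        x, y, z = grid.meshgrid_mm()
        h_field = heating_rate(1.0, m, F0) * focal(a_s0).amplitude(x, y, z) ** 3
        vol_m3 = (grid.voxel_mm * 1e-3) ** 3
        expected_j = n_pulses * (h_field * pulse.pulse_length).sum() * vol_m3
        added_j = (
            (sim.temperature[-1].astype(np.float64) - m.baseline_temp).sum()
            * m.cv
            * vol_m3
        )
        assert added_j == pytest.approx(expected_j, rel=1e-5)

    def test_clamp_bounds_temperature(self):
        m = small_medium()
        pulse = AcousticPulse(650, F0, 15000, 2.0)
        sim = simulate_sonication(
            SonicationPattern(), pulse, m, focal(8.8e7), GridSpec((17, 17, 17), 0.6),
            repeats=2,
        )
        assert sim.temperature.max() <= m.boiling_temp + 1e-9

    def test_fractionated_mask_monotone_in_time(self):
        m = small_medium()
        pulse = AcousticPulse(650, F0, 15000, 2.0)
        sim = simulate_sonication(
            SonicationPattern(), pulse, m, focal(8.8e7), GridSpec((17, 17, 17), 0.6),
            repeats=2,
        )
        for a, b in zip(sim.fractionated, sim.fractionated[1:]):
            assert (b | a == b).all()

    def test_unstable_substep_names_limit(self):
        m = small_medium()
        grid = GridSpec((9, 9, 9), 0.5)
        limit = max_stable_step(grid, m.thermal_diffusivity)
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        with pytest.raises(InvalidInputError, match=f"{limit:.4g}"):
            simulate_sonication(
                SINGLE, pulse, m, focal(1e6), grid, repeats=1,
                dt_substep_s=2 * limit,
            )

    def test_coarse_grid_rejected(self):
        m = small_medium()
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        with pytest.raises(InvalidInputError, match="resolve"):
            simulate_sonication(
                SINGLE, pulse, m, focal(1e6), GridSpec((5, 5, 5), 2.0), repeats=1
            )


class TestRenderThermometry:
    @staticmethod
    def _small_sim(a_s0=3.0e7, prf=2.0, repeats=4):
        m = small_medium()
        pulse = AcousticPulse(600, F0, 15000, prf)
        return m, simulate_sonication(
            SINGLE, pulse, m, focal(a_s0), GridSpec((25, 25, 33), 0.6),
            repeats=repeats,
        )

    def test_zero_elevation_gives_zero_phase_difference(self):
        m = small_medium()
        pulse = AcousticPulse(600, F0, 15000, 1.0)
        sim = simulate_sonication(
            SINGLE, pulse, m, FocalField(0.0, 0.68, 4.25), GridSpec((25, 25, 33), 0.6),
            repeats=2,
        )
        dyn = render_thermometry(sim, ThermometryGeometry(), 0.0, seed=0)
        for img in dyn.slices.values():
            dphi = np.angle(img * np.conj(img[0]))
            assert np.allclose(dphi, 0.0, atol=1e-12)

    def test_phase_magnitude_for_10_degrees(self):
        # |dphi| = 2 pi * 42.58e6 * 1.5 * 1e-7 * 0.019 for a 10 degC rise
        geom = ThermometryGeometry()
        assert abs(geom.phase_per_degc * 10.0) == pytest.approx(0.7626, abs=2e-4)
        assert geom.phase_per_degc < 0

    def test_noiseless_render_matches_voxel_average(self):
        m, sim = self._small_sim()
        geom = ThermometryGeometry()
        truth, _ = voxel_average_temperature(sim, geom)
        dyn = render_thermometry(sim, geom, 0.0, seed=0)
        for name, img in dyn.slices.items():
            dphi = np.unwrap(np.angle(img * np.conj(img[0])), axis=0)
            recon = m.baseline_temp + dphi / geom.phase_per_degc
            assert np.allclose(recon, truth[name], atol=1e-9)

    def test_fixed_seed_bit_identical(self):
        m, sim = self._small_sim()
        geom = ThermometryGeometry()
        d1 = render_thermometry(sim, geom, 1.0, seed=42)
        d2 = render_thermometry(sim, geom, 1.0, seed=42)
        for name in d1.slices:
            assert (d1.slices[name] == d2.slices[name]).all()

    def test_geometry_outside_grid_rejected(self):
        m, sim = self._small_sim()
        geom = ThermometryGeometry(coronal_offsets_mm=(0.0, 50.0))
        with pytest.raises(InvalidInputError, match="outside"):
            render_thermometry(sim, geom, 0.0, seed=0)

    def test_offset_slice_cooler_than_focal_slice(self):
        m, sim = self._small_sim(a_s0=6.0e7, prf=4.0, repeats=20)
        truth, _ = voxel_average_temperature(sim, ThermometryGeometry())
        assert truth["coronal_+7mm"].max() < truth["coronal_+0mm"].max()


class TestLesionPhantom:
    def test_head_only_analytic_volume(self):
        spec = LesionPhantomSpec(
            head_semiaxes_mm=(5, 5, 10), tail_radius_mm=0, tail_length_mm=0
        )
        assert spec.analytic_volume_mm3 == pytest.approx(4 / 3 * math.pi * 250, rel=1e-12)

    def test_head_plus_cone_tail_volume(self):
        spec = LesionPhantomSpec(
            head_semiaxes_mm=(4, 4, 6), tail_radius_mm=1.5, tail_length_mm=10
        )
        assert spec.analytic_volume_mm3 == pytest.approx(402.1 + 23.6, abs=0.15)

    def test_mask_volume_converges_to_analytic(self):
        spec = LesionPhantomSpec()
        coarse = make_lesion_volume(spec, 1.0, seed=0)
        fine = make_lesion_volume(spec, 0.4, seed=0)
        err_coarse = abs(coarse.mask_volume_mm3 - spec.analytic_volume_mm3)
        err_fine = abs(fine.mask_volume_mm3 - spec.analytic_volume_mm3)
        assert err_fine < err_coarse
        assert err_fine / spec.analytic_volume_mm3 < 0.01

    def test_mask_connected(self):
        from scipy import ndimage

        ph = make_lesion_volume(LesionPhantomSpec(), 0.5, seed=0)
        _, n = ndimage.label(ph.mask)
        assert n == 1

    def test_fixed_seed_bit_identical(self):
        a = make_lesion_volume(LesionPhantomSpec(), 0.5, seed=9)
        b = make_lesion_volume(LesionPhantomSpec(), 0.5, seed=9)
        assert (a.image == b.image).all()

    def test_unresolved_tail_warns_and_flags(self):
        spec = LesionPhantomSpec(tail_radius_mm=0.4)
        with pytest.warns(UserWarning, match="tail"):
            ph = make_lesion_volume(spec, 1.0, seed=0)
        assert ph.degenerate_tail
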