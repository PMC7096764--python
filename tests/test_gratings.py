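import numpy as np
import pytest

from mpgsim import GratingSpec, Grid1D, combined_two_level, sinusoidal_mpg, transmission_profile
from mpgsim.errors import ConfigError, SamplingError
from mpgsim.gratings import bar_mask, phase_scale


def phases(field):
    return np.angle(field.amplitude)


def test_binary_pi_grating_profile():
    spec = GratingSpec(pitch_um=4.0, phase_low=np.pi, phase_high=np.pi, modulation="none")
    grid = Grid1D(start=0.0, step=0.1, n=80)  # two pitches
    t = transmission_profile(spec, grid)
    ph = phases(t)
    assert np.allclose(np.abs(t.amplitude), 1.0)  # phase-only
    assert set(np.round(np.unique(ph), 9)) == {0.0, np.round(np.pi, 9)}
    # period 4 um: left-closed bar on [0, 2), opening on [2, 4)
    assert np.allclose(ph[:20], np.pi) and np.allclose(ph[20:40], 0.0)
    assert np.allclose(ph[:40], ph[40:])


def test_aperture_blocks_outside_window():
    spec = GratingSpec(pitch_um=1.0, phase_high=np.pi, aperture_um=10.0)
    grid = Grid1D.centered(30.0, 0.05)
    t = transmission_profile(spec, grid)
    outside = np.abs(grid.positions) > 5.0
    assert np.allclose(np.abs(t.amplitude[outside]), 0.0)
    assert np.allclose(np.abs(t.amplitude[~outside]), 1.0)


def test_zero_phase_grating_is_free_space():
    spec = GratingSpec(pitch_um=2.0, phase_low=0.0, phase_high=0.0)
    grid = Grid1D.centered(20.0, 0.1)
    t = transmission_profile(spec, grid)
    assert np.allclose(t.amplitude, 1.0)


def test_undersampled_grid_rejected():
    spec = GratingSpec(pitch_um=1.0)
    with pytest.raises(SamplingError):
        transmission_profile(spec, Grid1D.centered(10.0, 0.2))


def test_missing_mod_period_rejected():
    with pytest.raises(ConfigError):
        GratingSpec(pitch_um=1.0, modulation="sinusoidal")
    with pytest.raises(ConfigError):
        GratingSpec(pitch_um=1.0, modulation="sinusoidal", mod_period_um=0.5)


def test_combined_two_level_histogram_and_period():
    mk = lambda ph: GratingSpec(pitch_um=1.0, phase_low=ph, phase_high=ph)
    grid = Grid1D.centered(400.0, 0.01)
    t = combined_two_level(mk(np.pi / 2), mk(np.pi), 50.0, grid)
    ph = np.round(phases(t), 9)
    assert set(np.unique(ph)) == {0.0, np.round(np.pi / 2, 9), np.round(np.pi, 9)}
    # high-low pattern repeats at W = 2 * unit_width = 100 um
    n_period = int(round(100.0 / grid.step))
    assert np.allclose(t.amplitude[:n_period], t.amplitude[n_period : 2 * n_period])


def test_combined_two_level_rejects_mismatched_pitch():
    a = GratingSpec(pitch_um=1.0, phase_high=np.pi / 2)
    b = GratingSpec(pitch_um=2.0, phase_high=np.pi)
    with pytest.raises(ConfigError):
        combined_two_level(a, b, 50.0, Grid1D.centered(100.0, 0.05))


class TestSinusoidalEnvelope:
    spec = GratingSpec(
        pitch_um=0.6, phase_low=np.pi / 4, phase_high=np.pi,
        modulation="sinusoidal", mod_period_um=45.0, design_energy_kev=40.0,
    )

    def grid(self):
        # commensurate with both pitch and envelope period
        return Grid1D(start=0.0, step=0.003, n=30000)  # two W periods

    def test_extremes_and_crest_at_axis(self):
        t = sinusoidal_mpg(self.spec, self.grid())
        ph = phases(t)
        bars = bar_mask(self.spec, self.grid().positions)
        assert ph[bars].max() == pytest.approx(np.pi, abs=1e-6)
        assert ph[bars].min() == pytest.approx(np.pi / 4, abs=1e-6)
        assert ph[0] == pytest.approx(np.pi)  # crest centered at x = 0

    def test_envelope_mean_over_one_period(self):
        from mpgsim.gratings import _envelope

        x = np.linspace(0.0, 45.0, 90001)[:-1]
        env = _envelope(self.spec, x, 40.0)
        assert env.mean() == pytest.approx((np.pi / 4 + np.pi) / 2, rel=1e-6)

    def test_periodicity_over_w(self):
        t = sinusoidal_mpg(self.spec, self.grid())
        n_w = 15000  # 45 um / 0.003 um
        assert np.allclose(t.amplitude[:n_w], t.amplitude[n_w:], atol=1e-12)

    def test_reduces_to_unmodulated_when_phases_equal(self):
        import dataclasses

        flat = dataclasses.replace(self.spec, phase_low=np.pi, phase_high=np.pi)
        t = transmission_profile(flat, self.grid())
        ph = phases(t)
        bars = bar_mask(flat, self.grid().positions)
        assert np.allclose(ph[bars], np.pi)


def test_triangular_envelope_extremes_and_mean():
    spec = GratingSpec(
        pitch_um=0.6, phase_low=np.pi / 4, phase_high=np.pi,
        modulation="triangular", mod_period_um=45.0,
    )
    from mpgsim.gratings import _envelope

    x = np.linspace(0.0, 45.0, 90001)[:-1]
    env = _envelope(spec, x, spec.design_energy_kev)
    assert env.max() == pytest.approx(np.pi, abs=1e-6)
    assert env.min() == pytest.approx(np.pi / 4, abs=1e-4)
    assert env.mean() == pytest.approx((np.pi / 4 + np.pi) / 2, rel=1e-4)
    assert env[0] == pytest.approx(np.pi)


def test_phase_energy_scaling_half_at_double_energy():
    spec = GratingSpec(pitch_um=2.0, phase_high=np.pi, design_energy_kev=40.0)
    grid = Grid1D.centered(20.0, 0.05)
    t40 = transmission_profile(spec, grid, 40.0)
    t80 = transmission_profile(spec, grid, 80.0)
    assert np.allclose(np.angle(t80.amplitude), np.angle(t40.amplitude) / 2.0)
    assert phase_scale(spec, 80.0) == pytest.approx(0.5)


def test_energy_conservation_phase_only():
    spec = GratingSpec(
        pitch_um=0.6, phase_low=np.pi / 4, phase_high=np.pi,
        modulation="sinusoidal", mod_period_um=45.0,
    )
    grid = Grid1D.centered(90.0, 0.003)
    t = transmission_profile(spec, grid)
    power = np.sum(np.abs(t.amplitude) ** 2) * grid.step
    assert power == pytest.approx(grid.n * grid.step, rel=1e-12)  # = open screen
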