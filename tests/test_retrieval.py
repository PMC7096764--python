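import numpy as np
import pytest

from mpgsim import (
    Grid1D,
    IntensityProfile,
    PhaseObject,
    bct_system,
    fringe_shift,
    phase_sensitivity,
    pmma_polyimide_phantom,
    refraction_angle,
    simulate_with_object,
    single_shot_retrieve,
)
from mpgsim.errors import ConfigError, CoverageError, DemodulationError

M_OBJ = 850.0 / 400.0  # G0-plane to detector over G0-plane to object (Dod=450)


def test_refraction_angle_values():
    # dPhi/dy = 2*pi rad/mm at 40 keV -> alpha = lambda / 1 mm
    assert refraction_angle(2 * np.pi, 40.0) == pytest.approx(3.0996e-8, rel=1e-4)
    assert refraction_angle(0.0, 40.0) == 0.0
    assert refraction_angle(4 * np.pi, 40.0) == pytest.approx(
        2 * refraction_angle(2 * np.pi, 40.0)
    )


def test_phase_sensitivity_values():
    assert phase_sensitivity(450.0, 150.0) == pytest.approx(3.0e3)
    assert phase_sensitivity(0.0, 150.0) == 0.0
    assert phase_sensitivity(900.0, 150.0) == pytest.approx(6.0e3)
    assert phase_sensitivity(450.0, 300.0) == pytest.approx(1.5e3)
    with pytest.raises(ConfigError):
        phase_sensitivity(450.0, -1.0)


def test_fringe_shift_small_angle():
    alpha = 3.0996e-8
    assert fringe_shift(alpha, 600.0) == pytest.approx(0.0186, rel=1e-3)  # um
    assert fringe_shift(0.0, 600.0) == 0.0
    exact = fringe_shift(1e-8, 600.0, exact_tan=True)
    linear = fringe_shift(1e-8, 600.0)
    assert abs(exact - linear) / linear < 1e-14


def synthetic_fringes(shift_um=0.0, period=150.0):
    grid = Grid1D.centered(1800.0, 0.5)
    x = grid.positions
    vals = 1.0 + 0.3 * np.cos(2 * np.pi * (x - shift_um) / period)
    return IntensityProfile(grid, vals)


def test_rigid_shift_recovered_from_synthetic_fringes():
    shift = 0.3  # um
    r = single_shot_retrieve(synthetic_fringes(shift), synthetic_fringes(0.0), 150.0)
    expected = 2 * np.pi * shift / 150.0
    assert np.allclose(r.fringe_phase[r.valid], expected, atol=1e-3)
    assert np.mean(r.fringe_shift_um[r.valid]) == pytest.approx(shift, rel=1e-3)


def test_identical_profiles_retrieve_zero():
    prof = synthetic_fringes(0.0)
    r = single_shot_retrieve(prof, prof, 150.0, dod_mm=450.0, energy_kev=40.0)
    assert np.allclose(r.fringe_phase[r.valid], 0.0, atol=1e-12)
    assert np.allclose(r.integrated_phase[r.valid], 0.0, atol=1e-12)


def test_no_carrier_raises_demodulation_error():
    grid = Grid1D.centered(1800.0, 0.5)
    flat = IntensityProfile(grid, np.ones(grid.n) + 1e-6 * grid.positions**2 / 1e6)
    with pytest.raises(DemodulationError):
        single_shot_retrieve(flat, flat, 150.0)


def test_mismatched_grids_rejected():
    a = synthetic_fringes(0.0)
    grid = Grid1D.centered(1800.0, 0.6)
    b = IntensityProfile(grid, np.ones(grid.n))
    with pytest.raises(CoverageError):
        single_shot_retrieve(a, b, 150.0)


def test_object_behind_detector_rejected(bct):
    obj = PhaseObject.ramp(2 * np.pi, 0.4, dod_mm=700.0)
    with pytest.raises(ConfigError):
        simulate_with_object(bct, obj)


@pytest.fixture(scope="module")
def ramp_system():
    return bct_system(span_fringe_periods=14.0)


def measure_ramp_dphi(system, wp, dod, gradient=2 * np.pi, ramp_mm=0.8):
    obj = PhaseObject.ramp(gradient, ramp_mm, dod_mm=dod)
    fr = simulate_with_object(system, obj)
    ref = simulate_with_object(system, obj, reference=True)
    r = single_shot_retrieve(fr, ref, wp)
    x = r.grid.positions
    m_obj = 850.0 / (850.0 - dod)
    inner = (np.abs(x) < ramp_mm / 2 * 1e3 * m_obj - 2.5 * wp) & r.valid
    return float(np.mean(r.fringe_phase[inner]))


def test_ramp_chain_closes_against_refraction_model(ramp_system):
    """simulate -> retrieve -> analytic chain: measured shift = alpha*Dod."""
    alpha = refraction_angle(2 * np.pi, 40.0)
    dphi = measure_ramp_dphi(ramp_system, 150.0, 450.0)
    expected = 2 * np.pi * alpha * 450.0e3 / 150.0
    assert dphi == pytest.approx(expected, rel=0.05)


def test_retrieved_phase_proportional_to_dod(ramp_system):
    d = {dod: measure_ramp_dphi(ramp_system, 150.0, dod) for dod in (400.0, 500.0, 600.0)}
    assert d[500.0] / d[400.0] == pytest.approx(5.0 / 4.0, rel=0.02)
    assert d[600.0] / d[400.0] == pytest.approx(6.0 / 4.0, rel=0.02)


def test_retrieval_linear_in_object_amplitude(ramp_system):
    d1 = measure_ramp_dphi(ramp_system, 150.0, 450.0, gradient=2 * np.pi)
    d2 = measure_ramp_dphi(ramp_system, 150.0, 450.0, gradient=4 * np.pi)
    assert d2 / d1 == pytest.approx(2.0, rel=0.02)


def test_sensitivity_invariant_when_grating_moves():
    """Inverse-geometry property: retrieved fringe phase at fixed Dod and W'
    does not depend on where the MPG sits."""
    a = bct_system(dsg_mm=250.0, dgd_mm=600.0, span_fringe_periods=14.0)
    b = bct_system(dsg_mm=300.0, dgd_mm=550.0, span_fringe_periods=14.0)
    da = measure_ramp_dphi(a, 150.0, 450.0)
    db = measure_ramp_dphi(b, 150.0, 450.0)
    assert db / da == pytest.approx(1.0, rel=0.02)


def test_phantom_projected_phase_recovered():
    """PMMA block with embedded polyimide: retrieved projected phase matches
    the input away from the block edges."""
    system = bct_system(span_fringe_periods=26.0, grating_step_um=0.002)
    obj = pmma_polyimide_phantom(dod_mm=450.0)
    fr = simulate_with_object(system, obj)
    ref = simulate_with_object(system, obj, reference=True)
    r = single_shot_retrieve(
        fr, ref, 150.0, dod_mm=450.0, energy_kev=40.0, object_magnification=M_OBJ
    )
    x = r.grid.positions
    projected = obj.phase(x / M_OBJ)
    left = r.valid & (x < -1700.0)
    retrieved = r.integrated_phase - np.mean(r.integrated_phase[left]) + np.mean(projected[left])
    away = r.valid.copy()
    for e in np.array([-0.7, -0.2, 0.2, 0.7]) * 1e3 * M_OBJ:
        away &= np.abs(x - e) >= 300.0
    assert np.max(np.abs(retrieved - projected)[away]) < 0.1 * np.pi
    # the two plateau levels are recovered
    pmma = (x > -1150.0) & (x < -800.0)
    center = np.abs(x) < 120.0
    assert np.mean(retrieved[pmma]) == pytest.approx(0.79 * np.pi, abs=0.05 * np.pi)
    assert np.mean(retrieved[center]) == pytest.approx(
        np.mean(projected[center]), abs=0.05 * np.pi
    )


def test_result_invariant_fringe_phase_vs_shift():
    r = single_shot_retrieve(synthetic_fringes(0.2), synthetic_fringes(0.0), 150.0)
    assert np.allclose(r.fringe_phase, 2 * np.pi * r.fringe_shift_um / 150.0, atol=1e-9)
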