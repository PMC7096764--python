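"""Pre-baked reproduction drivers for the published simulation studies.

Each driver binds the stated parameters of one figure or table of the study
(Talbot verification, parallel/point-source carpets, visibility sweeps,
spectrum degradation, line-source comparison, sensitivity and phantom
retrieval) and returns a dict of headline numbers plus the arrays behind
them.  ``fast=True`` coarsens sampling (5-nm grating grid, 2-keV spectral
bins, wider z steps) with a sub-half-percentage-point effect on the
visibilities, so the whole set runs in minutes.
"""

from __future__ import annotations

from typing import Any, Callable

import numpy as np

from .core import Geometry, Grid1D, energy_to_wavelength
from .errors import ConfigError
from .fringes import fringe_harmonic, locate_peaks, smooth_box, visibility
from .gratings import GratingSpec, combined_two_level, transmission_profile
from .propagate import IntensityProfile, angular_spectrum, carpet_scan
from .retrieval import (
    PhaseObject,
    pmma_polyimide_phantom,
    refraction_angle,
    simulate_with_object,
    single_shot_retrieve,
)
from .design import design_g0
from .simulate import MPGSystem, bct_system, raised_cosine_window
from .sources import (
    SourceSpec,
    generate_spectrum,
    line_source_intensity,
    polychromatic_intensity,
    temporal_coherence_sweep,
)

Artifacts = dict[str, np.ndarray]
Result = tuple[dict[str, Any], Artifacts]


def _talbot_field(fast: bool):
    spec = GratingSpec(
        pitch_um=4.0, duty=0.5, phase_low=np.pi, phase_high=np.pi,
        modulation="none", design_energy_kev=25.0,
    )
    step = 0.02 if fast else 0.01
    grid = Grid1D.centered(512.0, step)
    return spec, transmission_profile(spec, grid, 25.0)


def fig2(fast: bool = False) -> Result:
    """Talbot carpet of a 4-um binary pi grating at 25 keV, 0-200 mm."""
    _, field = _talbot_field(fast)
    z = np.arange(1.0, 200.0 + 0.5, 1.0)
    geom = Geometry(parallel=True, d_gd=1.0)
    harm = []
    rows = []
    for zi in z:
        out = angular_spectrum(field, float(zi), 25.0)
        prof = IntensityProfile.from_field(out)
        harm.append(fringe_harmonic(prof, 2.0))
        keep = np.abs(prof.grid.positions) <= 8.0
        rows.append(prof.normalized().values[keep])
    harm = np.asarray(harm)
    peaks = locate_peaks(z, harm)
    lam_nm = energy_to_wavelength(25.0)
    zt1 = 4.0**2 / (8.0 * lam_nm * 1e-3) * 1e-3  # um^2 / um -> um -> mm
    results = {
        "first_talbot_mm": float(peaks[0]),
        "third_talbot_mm": float(peaks[1]),
        "closed_form_first_mm": zt1,
        "closed_form_third_mm": 3 * zt1,
    }
    return results, {"z_mm": z, "harmonic": harm, "carpet": np.vstack(rows)}


def fig5(fast: bool = False) -> Result:
    """Rectangular MPG from pi/2 and pi units of 1-um pitch, W = 100 um,
    25 keV parallel beam at 300 mm."""
    step = 0.005 if fast else 0.001
    mk = lambda ph: GratingSpec(
        pitch_um=1.0, phase_low=ph, phase_high=ph, design_energy_kev=25.0
    )
    grid = Grid1D.centered(4 * 100.0 * 1.4, step)
    field = combined_two_level(mk(np.pi / 2), mk(np.pi), 50.0, grid, 25.0)
    window = raised_cosine_window(grid, 2 * 100.0, grid.width / 2)
    field.amplitude *= window
    out = angular_spectrum(field, 300.0, 25.0)
    prof = IntensityProfile.from_field(out)
    vis = visibility(prof, 100.0, smooth_um=1.0)
    sm = smooth_box(prof, 1.0)
    results = {"fringe_period_um": 100.0, "visibility_pct": vis}
    return results, {"x_um": prof.grid.positions, "intensity": sm.values}


def _parallel_system(pitch: float, w: float, fast: bool, energy: float = 40.0) -> MPGSystem:
    geom = Geometry(parallel=True, d_gd=600.0)
    grating = GratingSpec(
        pitch_um=pitch, phase_low=np.pi / 4, phase_high=np.pi,
        modulation="triangular", mod_period_um=w, design_energy_kev=energy,
    )
    return MPGSystem(
        grating=grating, geometry=geom, source=SourceSpec("parallel"),
        energy_kev=energy, grating_step_um=0.005 if fast else 0.001,
    )


def fig8(fast: bool = False) -> Result:
    """Parallel-beam fringe carpets, 40 keV, W = 100 um, z = 450-750 mm."""
    z_step = 25.0 if fast else 5.0
    arts: Artifacts = {}
    results: dict[str, Any] = {}
    for pitch in (1.0, 0.6):
        system = _parallel_system(pitch, 100.0, fast)
        carpet = system.carpet(450.0, 750.0, z_step)
        arts[f"carpet_p{pitch}"] = carpet.as_array()[:, :: 200 if fast else 1000]
        arts[f"z_mm_p{pitch}"] = carpet.z_values_mm
        results[f"visibility_600mm_pitch_{pitch}"] = system.with_(
            geometry=system.geometry.with_dgd(600.0)
        ).visibility()
    return results, arts


def fig9(fast: bool = False) -> Result:
    """Parallel-beam visibility sweeps vs distance, energy, pitch and W."""
    z_values = np.arange(450.0, 751.0, 50.0 if fast else 25.0)
    results: dict[str, Any] = {}
    arts: Artifacts = {"z_mm": z_values}
    for e in (20.0, 30.0, 40.0, 50.0):
        sys_e = _parallel_system(0.6, 100.0, fast, energy=40.0)
        vis = [
            sys_e.with_(geometry=sys_e.geometry.with_dgd(float(z))).visibility(energy_kev=e)
            for z in z_values
        ]
        arts[f"visibility_{int(e)}kev"] = np.asarray(vis)
    for pitch in (0.6, 0.8, 1.0, 1.2):
        v = _parallel_system(pitch, 100.0, fast).visibility()
        results[f"visibility_pitch_{pitch}"] = v
    for w in (100.0, 150.0, 200.0):
        v = _parallel_system(0.6, w, fast).visibility()
        results[f"visibility_W_{int(w)}"] = v
    return results, arts


def fig10(fast: bool = False) -> Result:
    """Point-source carpet, 40 keV, Dsg = 250 mm, 0.6-um pitch, W = 44.1 um."""
    system = bct_system(grating_step_um=0.005 if fast else 0.001)
    z_step = 25.0 if fast else 5.0
    carpet = system.carpet(450.0, 750.0, z_step)
    # measured fringe period at 600 mm: spacing of smoothed envelope peaks
    prof = system.point_intensity()
    sm = smooth_box(prof, system.micro_period_um)
    x = sm.grid.positions
    core = np.abs(x) < 2.0 * system.fringe_period_um
    from scipy.signal import find_peaks

    idx, _ = find_peaks(sm.values[core], distance=int(100.0 / sm.grid.step))
    spacing = float(np.mean(np.diff(x[core][idx]))) if idx.size > 1 else np.nan
    results = {
        "fringe_period_600mm_um": spacing,
        "visibility_600mm_pct": system.visibility(),
    }
    return results, {"z_mm": carpet.z_values_mm}


def fig11(fast: bool = False) -> Result:
    """Visibility vs energy, 26-60 keV point source, heights fixed at 40 keV."""
    system = bct_system(grating_step_um=0.005 if fast else 0.001)
    energies = np.arange(26.0, 61.0, 2.0)
    curve = temporal_coherence_sweep(system, energies)
    sel = (energies >= 34.0) & (energies <= 46.0)
    band = curve.visibility_pct[sel]
    results = {
        "visibility_40kev_pct": float(curve.visibility_pct[energies == 40.0][0]),
        "variation_40pm6_pp": float(band.max() - band.min()),
    }
    return results, {"energy_kev": energies, "visibility_pct": curve.visibility_pct}


def fig12(fast: bool = False) -> Result:
    """Polychromatic degradation: 60 kV + 0.2 mm Cu spectrum vs mono 40 keV."""
    spectrum = generate_spectrum(60.0, "Cu", 0.2, 2.0 if fast else 1.0).pruned()
    system = bct_system(grating_step_um=0.005 if fast else 0.001)
    poly = polychromatic_intensity(system, spectrum)
    results = {
        "mean_energy_kev": spectrum.mean_energy_kev,
        "visibility_mono_pct": system.visibility(),
        "visibility_poly_pct": visibility(
            poly, system.fringe_period_um, smooth_um=system.micro_period_um
        ),
    }
    arts = {"energy_kev": spectrum.energies_kev, "weight": spectrum.weights}
    return results, arts


def fig13(fast: bool = False) -> Result:
    """Point source vs 12.9-um line source, 0.6-um MPG, W' = 150 um."""
    system = bct_system(grating_step_um=0.005 if fast else 0.001)
    pt = system.point_intensity()
    ln = line_source_intensity(pt, 12.9, system.geometry)
    wp, mp = system.fringe_period_um, system.micro_period_um
    results = {
        "visibility_point_pct": visibility(pt, wp, smooth_um=mp),
        "visibility_line_pct": visibility(ln, wp, smooth_um=mp),
    }
    arts = {
        "x_um": pt.grid.positions,
        "point": smooth_box(pt, mp).values,
        "line": smooth_box(ln, mp).values,
    }
    return results, arts


def fig14(fast: bool = False) -> Result:
    """Pitch comparison with spectrum + line source, W' = 150 um."""
    spectrum = generate_spectrum(60.0, "Cu", 0.2, 2.0).pruned()
    results: dict[str, Any] = {}
    for pitch, ls in ((0.6, 12.9), (1.0, 7.7)):
        system = bct_system(
            pitch_um=pitch,
            source=SourceSpec("line", line_width_um=ls),
            grating_step_um=0.005 if fast else 0.001,
        )
        poly = polychromatic_intensity(system, spectrum)
        results[f"visibility_pitch_{pitch}_pct"] = visibility(
            poly, system.fringe_period_um, smooth_um=system.micro_period_um
        )
    return results, {}


def fig15(fast: bool = False) -> Result:
    """Sensitivity proportionality: ramp object, 2*pi rad/mm differential."""
    alpha = refraction_angle(2 * np.pi, 40.0)
    step = 0.004 if fast else 0.002

    def mean_dphi(wp: float, dod: float) -> float:
        system = bct_system(
            w_prime_um=wp, span_fringe_periods=20.0, grating_step_um=step
        )
        obj = PhaseObject.ramp(2 * np.pi, 1.2, dod_mm=dod)
        fr = simulate_with_object(system, obj)
        ref = simulate_with_object(system, obj, reference=True)
        r = single_shot_retrieve(fr, ref, wp)
        m_obj = 850.0 / (850.0 - dod)
        x = r.grid.positions
        inner = (np.abs(x) < 600.0 * m_obj - 3.5 * wp) & r.valid
        return float(np.mean(r.fringe_phase[inner]))

    results: dict[str, Any] = {}
    for dod in (400.0, 500.0, 600.0):
        d = mean_dphi(150.0, dod)
        results[f"dphi_dod_{int(dod)}_rad"] = d
        results[f"model_ratio_dod_{int(dod)}"] = d / (
            2 * np.pi * alpha * dod * 1e3 / 150.0
        )
    for wp in (100.0, 150.0, 200.0):
        d = mean_dphi(wp, 450.0)
        results[f"dphi_W_{int(wp)}_rad"] = d
        results[f"model_ratio_W_{int(wp)}"] = d / (2 * np.pi * alpha * 450.0e3 / wp)
    return results, {}


def fig16(fast: bool = False) -> Result:
    """PMMA/polyimide phantom retrieval in the BCT geometry."""
    system = bct_system(
        span_fringe_periods=26.0, grating_step_um=0.004 if fast else 0.002
    )
    obj = pmma_polyimide_phantom(dod_mm=450.0)
    fr = simulate_with_object(system, obj)
    ref = simulate_with_object(system, obj, reference=True)
    m_obj = 850.0 / 400.0
    r = single_shot_retrieve(
        fr, ref, 150.0, dod_mm=450.0, energy_kev=40.0, object_magnification=m_obj
    )
    x = r.grid.positions
    projected = obj.phase(x / m_obj)
    left = r.valid & (x < -1700.0)
    retrieved = (
        r.integrated_phase
        - np.mean(r.integrated_phase[left])
        + np.mean(projected[left])
    )
    edge_positions = np.array([-0.7, -0.2, 0.2, 0.7]) * 1e3 * m_obj
    away = r.valid.copy()
    for e in edge_positions:
        away &= np.abs(x - e) >= 300.0
    max_err = float(np.max(np.abs(retrieved - projected)[away]))
    results = {"max_abs_error_pi": max_err / np.pi}
    arts = {"x_um": x, "retrieved_rad": retrieved, "projected_rad": projected}
    return results, arts


def table1(fast: bool = False) -> Result:
    """Source-grating design sheet for 0.6- and 1.0-um MPG pitches."""
    geom = Geometry(d_sg=250.0, d_gd=600.0)
    results: dict[str, Any] = {}
    for pitch in (0.6, 1.0):
        spec = GratingSpec(pitch_um=pitch, modulation="none")
        d = design_g0(spec, geom, 40.0, 150.0)
        results[f"ls_um_pitch_{pitch}"] = round(d.ls_um, 1)
        results[f"p0_um_pitch_{pitch}"] = d.p0_um
        results[f"open_ratio_pct_pitch_{pitch}"] = round(d.open_ratio_pct, 2)
    return results, {}


def table2(fast: bool = False) -> Result:
    """Summary visibilities: point/line/polychromatic, 0.6 and 1.0 um pitch."""
    r13, _ = fig13(fast)
    r12, _ = fig12(fast)
    r14, _ = fig14(fast)
    results = {
        "point_40kev_pct": r13["visibility_point_pct"],
        "line_40kev_pct": r13["visibility_line_pct"],
        "point_spectrum_pct": r12["visibility_poly_pct"],
        "line_spectrum_p06_pct": r14["visibility_pitch_0.6_pct"],
        "line_spectrum_p10_pct": r14["visibility_pitch_1.0_pct"],
    }
    return results, {}


FIGURES: dict[str, Callable[[bool], Result]] = {
    "fig2": fig2,
    "fig5": fig5,
    "fig8": fig8,
    "fig9": fig9,
    "fig10": fig10,
    "fig11": fig11,
    "fig12": fig12,
    "fig13": fig13,
    "fig14": fig14,
    "fig15": fig15,
    "fig16": fig16,
    "table1": table1,
    "table2": table2,
}


def run_figure(figure_id: str, fast: bool = False) -> Result:
    """Execute one pre-baked reproduction by id (fig2...fig16, table1/2)."""
    try:
        fn = FIGURES[figure_id]
    except KeyError:
        raise ConfigError(
            f"unknown figure id {figure_id!r}; choose from {sorted(FIGURES)}"
        ) from None
    return fn(fast)
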