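"""Free-space propagation from grating plane to detector plane.

Two routes are provided:

* direct numerical quadrature of the Rayleigh--Sommerfeld diffraction
  integral (``srdi_parallel`` / ``srdi_point_source``) -- the reference
  implementation and cross-check oracle, O(N_grating * N_detector);
* a fast band-limited angular-spectrum path (``angular_spectrum`` /
  ``propagate_spherical``) used for all production-size simulations.

The simulated gratings are line gratings, invariant along y, so the 2D
diffraction kernel is reduced to 1D by stationary phase in y: the effective
kernel is proportional to exp(j(k r + pi/4)) / sqrt(lambda r) with
r = sqrt(z^2 + (x2-x1)^2), times the obliquity factor cos(theta) = z/r.
Constant phase offsets cancel in intensity.  Point-source (cone-beam)
geometry is handled on the fast path by the Fresnel scaling theorem: a
spherical wave from distance R propagating a further d maps to a plane-wave
propagation over the reduced distance R*d/(R+d) with detector coordinates
magnified by (R+d)/R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, fftfreq, ifft, next_fast_len

from .core import ComplexField, Geometry, Grid1D, NM_PER_UM, UM_PER_MM, energy_to_wavelength
from .errors import CoverageError, SamplingError, UnitsError


@dataclass
class IntensityProfile:
    """Non-negative detector-plane intensity sampled on a :class:`Grid1D`."""

    grid: Grid1D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n,):
            raise UnitsError("intensity length does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise UnitsError("intensity must be finite")
        if np.any(self.values < -1e-12 * max(1.0, np.max(np.abs(self.values)))):
            raise UnitsError("intensity must be non-negative")
        self.values = np.maximum(self.values, 0.0)

    @classmethod
    def from_field(cls, field: ComplexField) -> "IntensityProfile":
        return cls(grid=field.grid, values=field.intensity)

    def normalized(self) -> "IntensityProfile":
        m = float(np.max(self.values))
        if m == 0.0:
            return IntensityProfile(self.grid, self.values.copy())
        return IntensityProfile(self.grid, self.values / m)


@dataclass
class Carpet:
    """Stack of intensity profiles over a range of grating-to-detector
    distances (a Talbot/fringe carpet)."""

    z_values_mm: np.ndarray
    profiles: list[IntensityProfile]
    normalized_per_plane: bool = True

    def __post_init__(self) -> None:
        self.z_values_mm = np.asarray(self.z_values_mm, dtype=np.float64)
        if len(self.profiles) != self.z_values_mm.size:
            raise UnitsError("carpet needs one profile per z")
        if self.z_values_mm.size > 1 and np.any(np.diff(self.z_values_mm) <= 0):
            raise UnitsError("carpet z values must be strictly increasing")

    def as_array(self) -> np.ndarray:
        """(n_z, n_x) intensity array; requires a common detector grid."""
        g0 = self.profiles[0].grid
        for p in self.profiles:
            if (p.grid.n, p.grid.step, p.grid.start) != (g0.n, g0.step, g0.start):
                raise CoverageError("carpet profiles are not on a common grid")
        return np.vstack([p.values for p in self.profiles])


def _wavelength_um(energy_kev: float) -> float:
    return energy_to_wavelength(energy_kev) / NM_PER_UM


def angular_spectrum(
    field: ComplexField,
    distance_mm: float,
    energy_kev: float,
    pad_factor: float = 2.0,
) -> ComplexField:
    """Band-limited angular-spectrum propagation over ``distance_mm``.

    The transfer function exp(j*k*z*sqrt(1-(lambda f)^2)) is applied in the
    spatial-frequency domain with zero padding against wrap-around and the
    standard band limit that keeps the sampled transfer-function phase below
    pi per frequency bin (suppressing aliased replicas).
    """
    if distance_mm == 0.0:
        return ComplexField(field.grid, field.amplitude.copy())
    if distance_mm < 0:
        raise UnitsError("propagation distance must be non-negative")
    lam = _wavelength_um(energy_kev)
    z = distance_mm * UM_PER_MM
    dx = field.grid.step
    n = field.grid.n
    nfft = next_fast_len(int(np.ceil(n * max(1.0, pad_factor))))
    f = fftfreq(nfft, d=dx)
    arg = 1.0 - (lam * f) ** 2
    kz = (2.0 * np.pi / lam) * z * np.sqrt(np.maximum(arg, 0.0))
    h = np.where(arg > 0.0, np.exp(1j * kz), 0.0)
    # band limit (Matsushima & Shimobaba): |f| below the frequency at which
    # the discretized transfer-function phase aliases
    df = 1.0 / (nfft * dx)
    f_limit = 1.0 / (lam * np.sqrt((2.0 * df * z) ** 2 + 1.0))
    h[np.abs(f) > f_limit] = 0.0
    spec = fft(field.amplitude, nfft)
    out = ifft(spec * h)[:n]
    return ComplexField(field.grid, out)


def propagate_spherical(
    field: ComplexField,
    distance_mm: float,
    r_source_mm: float,
    energy_kev: float,
    pad_factor: float = 2.0,
) -> tuple[ComplexField, float]:
    """Propagate a field carried on a diverging spherical wave.

    ``field`` is the complex envelope relative to the spherical reference
    wave from a point source ``r_source_mm`` upstream of the current plane.
    Returns the envelope at ``distance_mm`` downstream (on the geometrically
    magnified grid) and the new source distance ``r_source_mm+distance_mm``.
    Multi-stage propagation chains by passing the returned distance back in.
    """
    if r_source_mm <= 0:
        raise UnitsError("source distance must be positive")
    m = (r_source_mm + distance_mm) / r_source_mm
    d_eff = r_source_mm * distance_mm / (r_source_mm + distance_mm)
    out = angular_spectrum(field, d_eff, energy_kev, pad_factor=pad_factor)
    scaled = ComplexField(out.grid.scaled(m), out.amplitude / np.sqrt(m))
    return scaled, r_source_mm + distance_mm


def _direct_quadrature(
    amplitude: np.ndarray,
    x1_um: np.ndarray,
    x2_um: np.ndarray,
    z_um: float,
    lam_um: float,
    dx_um: float,
) -> np.ndarray:
    """Direct 1D-reduced Rayleigh-Sommerfeld sum (the brute-force oracle).

    Phases are evaluated as k*(r - z), dropping the constant k*z plane phase,
    with r - z computed in the cancellation-free form dx^2/(r + z).
    """
    k = 2.0 * np.pi / lam_um
    # aliasing guard: kernel phase change per grating sample must stay < pi
    max_dx = max(
        abs(x2_um[0] - x1_um[-1]), abs(x2_um[-1] - x1_um[0]),
        abs(x2_um[0] - x1_um[0]), abs(x2_um[-1] - x1_um[-1]),
    )
    max_slope = k * max_dx / np.hypot(z_um, max_dx)
    if max_slope * dx_um > np.pi:
        raise SamplingError(
            "grating sampling too coarse for the requested detector span "
            f"(kernel phase advances {max_slope * dx_um:.2f} rad per sample)"
        )
    out = np.empty(x2_um.size, dtype=np.complex128)
    # chunk the detector loop to keep the (n2, n1) work array bounded
    chunk = max(1, int(4e6 // max(1, x1_um.size)))
    for i0 in range(0, x2_um.size, chunk):
        dxs = x2_um[i0 : i0 + chunk, None] - x1_um[None, :]
        r = np.hypot(z_um, dxs)
        dr = dxs * dxs / (r + z_um)  # r - z without cancellation
        kern = np.exp(1j * k * dr) * (z_um / r) / np.sqrt(lam_um * r)
        out[i0 : i0 + chunk] = kern @ amplitude
    return out * dx_um * np.exp(1j * np.pi / 4.0)


def srdi_parallel(
    field_at_grating: ComplexField,
    dgd_mm: float,
    energy_kev: float,
    detector_grid: Grid1D,
) -> ComplexField:
    """Rayleigh-Sommerfeld quadrature for plane-wave incidence (unit field on
    the grating; the source terms drop out)."""
    lam = _wavelength_um(energy_kev)
    z = dgd_mm * UM_PER_MM
    a = _direct_quadrature(
        field_at_grating.amplitude,
        field_at_grating.grid.positions,
        detector_grid.positions,
        z,
        lam,
        field_at_grating.grid.step,
    )
    return ComplexField(detector_grid, a)


def srdi_point_source(
    field_at_grating: ComplexField,
    geom: Geometry,
    energy_kev: float,
    detector_grid: Grid1D,
    include_source: bool = True,
) -> ComplexField:
    """Rayleigh-Sommerfeld quadrature for a point source on the axis.

    With ``include_source`` the incident spherical-wave factor
    exp(j k r0)/sqrt(r0) (1D-reduced) is composed onto the grating
    transmission before the quadrature to the detector; otherwise
    ``field_at_grating`` is assumed to already contain it.
    """
    if geom.parallel:
        return srdi_parallel(field_at_grating, geom.d_gd, energy_kev, detector_grid)
    lam = _wavelength_um(energy_kev)
    x1 = field_at_grating.grid.positions
    amp = field_at_grating.amplitude
    if include_source:
        dsg = geom.d_sg * UM_PER_MM
        r0 = np.hypot(dsg, x1)
        dr0 = x1 * x1 / (r0 + dsg)  # r0 - Dsg
        k = 2.0 * np.pi / lam
        amp = amp * np.exp(1j * k * dr0) / np.sqrt(r0)
    z = geom.d_gd * UM_PER_MM
    a = _direct_quadrature(amp, x1, detector_grid.positions, z, lam, field_at_grating.grid.step)
    return ComplexField(detector_grid, a)


def propagate_to_detector(
    field_at_grating: ComplexField,
    geom: Geometry,
    energy_kev: float,
    pad_factor: float = 2.0,
) -> ComplexField:
    """Fast-path propagation grating -> detector for either source kind.

    Parallel geometry keeps the grating grid; point-source geometry returns
    the field on the grid magnified by M = Dsd/Dsg.
    """
    if geom.parallel:
        return angular_spectrum(field_at_grating, geom.d_gd, energy_kev, pad_factor)
    out, _ = propagate_spherical(field_at_grating, geom.d_gd, geom.d_sg, energy_kev, pad_factor)
    return out


def carpet_scan(
    field_at_grating: ComplexField,
    geom: Geometry,
    energy_kev: float,
    z_min_mm: float,
    z_max_mm: float,
    z_step_mm: float,
    normalize: bool = True,
    pad_factor: float = 2.0,
) -> Carpet:
    """Propagate one grating field to a range of detector distances.

    For point sources the detector grid of each plane is rescaled by that
    plane's geometric magnification.  With ``normalize`` each plane is
    max-normalized, the convention used for displaying fringe carpets.
    """
    if z_step_mm <= 0:
        raise UnitsError("z step must be positive")
    z_values = np.arange(z_min_mm, z_max_mm + 0.5 * z_step_mm, z_step_mm)
    profiles: list[IntensityProfile] = []
    for z in z_values:
        g = geom.with_dgd(float(z)) if z > 0 else None
        if z <= 0:
            out = ComplexField(field_at_grating.grid, field_at_grating.amplitude.copy())
        elif geom.parallel:
            out = angular_spectrum(field_at_grating, float(z), energy_kev, pad_factor)
        else:
            out = propagate_to_detector(field_at_grating, g, energy_kev, pad_factor)
        prof = IntensityProfile.from_field(out)
        profiles.append(prof.normalized() if normalize else prof)
    return Carpet(z_values_mm=z_values, profiles=profiles, normalized_per_plane=normalize)
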