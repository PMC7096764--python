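"""Phase sensitivity, refraction and single-shot Fourier phase retrieval.

A thin phase object at Dod upstream of the detector deflects the beam by the
refraction angle alpha = (lambda/2pi) dPhi/dy, which rigidly shifts the
broad fringes by Delta_y = alpha*Dod, i.e. a fringe-phase shift
Delta_phi = 2*pi*Delta_y/W'.  The dimensionless phase sensitivity of the
interferometer is S = Dod/W' (in one length unit); it depends on the
object-to-detector distance and the fringe period only, not on where the
grating sits (inverse-geometry property with a point source).

Single-shot retrieval demodulates one fringe image at the carrier 1/W':
isolate the first-harmonic sideband in frequency space, inverse transform,
and read the per-position phase as the argument of the analytic signal; the
object's projected phase follows by integrating the differential measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.fft import fft, fftfreq, ifft
from scipy.integrate import cumulative_trapezoid
from scipy.special import erf

from .core import (
    ComplexField,
    NM_PER_UM,
    UM_PER_MM,
    energy_to_wavelength,
)
from .errors import ConfigError, CoverageError, DemodulationError
from .propagate import IntensityProfile
from .simulate import MPGSystem
from .propagate import propagate_spherical, angular_spectrum
from .sources import line_source_intensity


def refraction_angle(dphi_dy_rad_per_mm: float, energy_kev: float) -> float:
    """Refraction angle alpha = (lambda/2pi) * dPhi/dy in rad."""
    lam_mm = energy_to_wavelength(energy_kev) * 1e-6  # nm -> mm
    return lam_mm / (2.0 * np.pi) * dphi_dy_rad_per_mm


def phase_sensitivity(dod_mm: float, w_prime_um: float) -> float:
    """Dimensionless phase sensitivity S = Dod/W'."""
    if dod_mm < 0 or w_prime_um <= 0:
        raise ConfigError("need Dod >= 0 and W' > 0")
    return dod_mm * UM_PER_MM / w_prime_um


def fringe_shift(alpha_rad: float, dod_mm: float, exact_tan: bool = False) -> float:
    """Fringe shift Delta_y = Dod*tan(alpha) ~ alpha*Dod, in um."""
    import warnings

    if abs(alpha_rad) > 0.1:
        warnings.warn("refraction angle beyond the small-angle regime", stacklevel=2)
    factor = np.tan(alpha_rad) if exact_tan else alpha_rad
    return float(factor * dod_mm * UM_PER_MM)


@dataclass
class PhaseObject:
    """Thin (projected) phase screen at ``dod_mm`` upstream of the detector.

    ``phase_fn`` maps object-plane transverse positions (um) to the
    projected phase Phi in rad at ``energy_kev``; at other energies the
    phase scales as 1/E like any refractive phase.
    """

    phase_fn: Callable[[np.ndarray], np.ndarray]
    dod_mm: float
    support_mm: float
    energy_kev: float = 40.0

    def phase(self, y_um: np.ndarray, energy_kev: float | None = None) -> np.ndarray:
        phi = np.asarray(self.phase_fn(np.asarray(y_um, dtype=np.float64)))
        if energy_kev is not None and energy_kev != self.energy_kev:
            phi = phi * (self.energy_kev / energy_kev)
        return phi

    @classmethod
    def ramp(
        cls,
        gradient_rad_per_mm: float,
        width_mm: float,
        dod_mm: float,
        energy_kev: float = 40.0,
    ) -> "PhaseObject":
        """Linear phase ramp of constant gradient across a centered window,
        with flat plateaus outside (so the refraction is constant inside)."""
        half_um = width_mm * UM_PER_MM / 2.0
        g_per_um = gradient_rad_per_mm / UM_PER_MM

        def fn(y):
            return g_per_um * np.clip(y, -half_um, half_um)

        return cls(phase_fn=fn, dod_mm=dod_mm, support_mm=width_mm, energy_kev=energy_kev)

    @classmethod
    def slabs(
        cls,
        slabs: Sequence[tuple[float, float, float]],
        dod_mm: float,
        edge_um: float = 40.0,
        energy_kev: float = 40.0,
    ) -> "PhaseObject":
        """Additive stack of slabs ``(width_mm, phase_rad, center_mm)`` with
        erf-smoothed edges of scale ``edge_um`` (manufactured edges are not
        mathematically sharp, and a finite edge keeps the refraction angle
        bounded)."""
        slabs = [tuple(map(float, s)) for s in slabs]

        def fn(y):
            total = np.zeros_like(y)
            for width_mm, phase_rad, center_mm in slabs:
                half = width_mm * UM_PER_MM / 2.0
                c = center_mm * UM_PER_MM
                left = (y - (c - half)) / (np.sqrt(2.0) * edge_um)
                right = (y - (c + half)) / (np.sqrt(2.0) * edge_um)
                total = total + phase_rad * 0.5 * (erf(left) - erf(right))
            return total

        # 4-sigma edge tails on each side bound the support
        support = max(w + 8.0 * edge_um / UM_PER_MM + 2 * abs(c) for w, _, c in slabs)
        return cls(phase_fn=fn, dod_mm=dod_mm, support_mm=support, energy_kev=energy_kev)


def pmma_polyimide_phantom(
    dod_mm: float = 450.0, edge_um: float = 40.0, energy_kev: float = 40.0
) -> PhaseObject:
    """Slab phantom: a 1.4-mm-wide, 260-um-thick PMMA block (projected phase
    0.79 pi at 40 keV) with a 0.4-mm-wide, 130-um-thick polyimide block
    (1.6 pi) embedded at its center.  The polyimide displaces half the PMMA
    thickness, so the central extra phase is 1.6 pi - 0.395 pi on top of the
    PMMA base.

    ``edge_um`` sets the erf edge scale.  Edges much below ~35 um are
    sub-resolution for the 150-um fringe carrier: they act as diffractive
    phase steps rather than refracting prisms, outside the validity of the
    single-shot retrieval model, so the default keeps the phantom's
    gradients in the refractive regime."""
    return PhaseObject.slabs(
        [
            (1.4, 0.79 * np.pi, 0.0),
            (0.4, (1.6 - 0.79 / 2.0) * np.pi, 0.0),
        ],
        dod_mm=dod_mm,
        edge_um=edge_um,
        energy_kev=energy_kev,
    )


def simulate_with_object(
    system: MPGSystem,
    obj: PhaseObject | None,
    energy_kev: float | None = None,
    reference: bool = False,
) -> IntensityProfile:
    """Detector intensity with a thin phase screen at Dod upstream.

    The field is propagated grating -> object plane, multiplied by
    exp(j*Phi(y)) (projection approximation, phase only), and propagated the
    remaining Dod.  ``obj=None`` gives the no-object fringes via a single
    propagation; ``reference=True`` keeps the object's two-stage propagation
    route but zeroes its phase, which produces reference fringes on the
    numerically identical grid as the object fringes (the right input for
    differential retrieval).
    """
    e = system.energy_kev if energy_kev is None else energy_kev
    geom = system.geometry
    field = system.grating_field(e)
    if obj is None:
        out = system.detector_field(e)
    else:
        if obj.dod_mm > geom.d_gd:
            raise ConfigError(
                f"object must sit between MPG and detector (Dod={obj.dod_mm} mm "
                f"> Dgd={geom.d_gd} mm)"
            )
        d1 = geom.d_gd - obj.dod_mm
        if geom.parallel:
            at_obj = angular_spectrum(field, d1, e, system.pad_factor) if d1 > 0 else field
            y = at_obj.grid.positions
            phi = np.zeros_like(y) if reference else obj.phase(y, e)
            screened = ComplexField(at_obj.grid, at_obj.amplitude * np.exp(1j * phi))
            out = angular_spectrum(screened, obj.dod_mm, e, system.pad_factor)
        else:
            r = geom.d_sg
            at_obj = field
            if d1 > 0:
                at_obj, r = propagate_spherical(field, d1, r, e, system.pad_factor)
            y = at_obj.grid.positions  # physical object-plane coordinates
            if not reference and obj.support_mm * UM_PER_MM > at_obj.grid.width:
                raise CoverageError("object wider than the illuminated aperture")
            phi = np.zeros_like(y) if reference else obj.phase(y, e)
            screened = ComplexField(at_obj.grid, at_obj.amplitude * np.exp(1j * phi))
            out, _ = propagate_spherical(screened, obj.dod_mm, r, e, system.pad_factor)
    prof = IntensityProfile.from_field(out)
    if system.source.kind == "line":
        prof = line_source_intensity(prof, system.source.line_width_um, geom)
    return prof


@dataclass
class RetrievalResult:
    """Demodulated fringe phase and derived object-phase measures.

    ``fringe_phase`` is Delta_phi(y) in rad with the sign convention
    Delta_phi = 2*pi*Delta_y/W' (positive shift toward +y gives positive
    phase); ``fringe_shift_um`` = Delta_y.  ``differential_phase`` is the
    projected object-phase gradient dPhi/dy on the detector (rad/um) and
    ``integrated_phase`` its cumulative trapezoid integral (rad), both only
    when geometry and energy were supplied.  ``valid`` masks the region away
    from the Hann-window edges.
    """

    grid: object
    w_prime_um: float
    fringe_phase: np.ndarray
    fringe_shift_um: np.ndarray
    valid: np.ndarray
    differential_phase: np.ndarray | None = None
    integrated_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        # invariant: Delta_phi = 2*pi*Delta_y/W' by construction
        assert np.allclose(
            self.fringe_phase,
            2.0 * np.pi * self.fringe_shift_um / self.w_prime_um,
            atol=1e-9,
        )


def _demodulate(values: np.ndarray, x_um: np.ndarray, w_prime_um: float,
                band_halfwidth_frac: float) -> np.ndarray:
    """Analytic signal of the first-harmonic fringe component.

    The sideband around the carrier 1/W' is isolated with a raised-cosine
    (Tukey) edge taper over its outer half, which suppresses the spatial
    ringing a hard band edge would imprint on the demodulated phase.
    """
    n = values.size
    window = np.hanning(n)
    spec = fft(values * window)
    dx = x_um[1] - x_um[0]
    f = fftfreq(n, d=dx)
    fc = 1.0 / w_prime_um
    half = band_halfwidth_frac / w_prime_um
    band = np.abs(f - fc) <= half
    if not np.any(band):
        raise DemodulationError("carrier band contains no frequency samples")
    power = np.abs(spec) ** 2
    peak = float(np.max(power[band]))
    outside = (f > 0) & ~band & (f < 3.0 * fc)
    background = float(np.median(power[outside])) if np.any(outside) else 0.0
    # the carrier must also stand clear of the DC term, not just of the
    # (possibly numerically empty) background floor
    background = max(background, 1e-8 * float(power[0]) / 3.0)
    if peak < 3.0 * background:
        raise DemodulationError(
            f"no detectable fringe carrier at 1/W' = {fc:.4g} /um "
            f"(peak {peak:.3g} < 3x background {background:.3g})"
        )
    u = np.abs(f - fc) / half  # 0 at carrier, 1 at band edge
    taper = np.where(u <= 0.5, 1.0, 0.5 * (1.0 + np.cos(np.pi * np.clip(2.0 * u - 1.0, 0, 1))))
    return ifft(spec * band * taper)


def _unwrap_from_center(wrapped: np.ndarray, i0: int) -> np.ndarray:
    """Unwrap a phase profile outward from index ``i0`` (adds 2*pi multiples
    at jumps > pi), so noise at the profile edges cannot corrupt the
    well-conditioned central region."""
    out = np.empty_like(wrapped)
    out[i0:] = np.unwrap(wrapped[i0:])
    out[: i0 + 1] = np.unwrap(wrapped[: i0 + 1][::-1])[::-1]
    return out


def single_shot_retrieve(
    object_fringes: IntensityProfile,
    reference_fringes: IntensityProfile,
    w_prime_um: float,
    dod_mm: float | None = None,
    energy_kev: float | None = None,
    object_magnification: float = 1.0,
    band_halfwidth_frac: float = 0.5,
) -> RetrievalResult:
    """Single-shot Fourier retrieval of the fringe-phase map.

    Both profiles must share one grid spanning at least four fringe periods.
    ``object_magnification`` is the geometric magnification of the object
    plane onto the detector (Dsd/Dso); with it, ``dod_mm`` and
    ``energy_kev``, the physical projected phase (in detector coordinates)
    is integrated from the differential measure via
    dPhi/dy = 2*pi*Delta_y / (lambda * Dod * M_obj).
    """
    go, gr = object_fringes.grid, reference_fringes.grid
    if go.n != gr.n or not (
        np.isclose(go.step, gr.step, rtol=1e-9) and np.isclose(go.start, gr.start, rtol=1e-9)
    ):
        raise CoverageError("object and reference fringes must share one grid")
    x = go.positions
    if x[-1] - x[0] < 4.0 * w_prime_um:
        raise CoverageError("retrieval needs at least 4 fringe periods of coverage")
    c_obj = _demodulate(object_fringes.values, x, w_prime_um, band_halfwidth_frac)
    c_ref = _demodulate(reference_fringes.values, x, w_prime_um, band_halfwidth_frac)
    # usable region: where the reference fringe carrier actually has power
    # (the aperture guard bands and Hann-window edges carry none)
    amp = np.abs(c_ref)
    strong = amp > 0.2 * float(np.max(amp))
    i0 = int(np.argmin(np.abs(x)))
    # contiguous strong region containing the axis, shrunk by one period
    lo = i0
    while lo > 0 and strong[lo - 1]:
        lo -= 1
    hi = i0
    while hi < x.size - 1 and strong[hi + 1]:
        hi += 1
    per = int(np.ceil(w_prime_um / go.step))
    valid = np.zeros(x.size, dtype=bool)
    valid[min(lo + per, i0) : max(hi - per, i0) + 1] = True
    # wrapped per-sample phase difference, unwrapped outward from the axis
    dphi_carrier = _unwrap_from_center(np.angle(c_obj * np.conj(c_ref)), i0)
    # carrier phase advance of a +y fringe shift is negative: I(y - dy)
    fringe_phase = -dphi_carrier
    shift_um = fringe_phase * w_prime_um / (2.0 * np.pi)
    differential = None
    integrated = None
    if dod_mm is not None and energy_kev is not None:
        lam_um = energy_to_wavelength(energy_kev) / NM_PER_UM
        dod_um = dod_mm * UM_PER_MM
        differential = 2.0 * np.pi * shift_um / (lam_um * dod_um * object_magnification)
        # integrate the differential measure over the usable region only;
        # outside it the integral is frozen (no spurious drift)
        integrated = cumulative_trapezoid(np.where(valid, differential, 0.0), x, initial=0.0)
        integrated = integrated - integrated[valid][0]
    return RetrievalResult(
        grid=go,
        w_prime_um=w_prime_um,
        fringe_phase=fringe_phase,
        fringe_shift_um=shift_um,
        valid=valid,
        differential_phase=differential,
        integrated_phase=integrated,
    )
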