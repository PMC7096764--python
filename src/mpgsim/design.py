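"""Closed-form spatial-coherence and source-grating (G0) design.

An incoherent tube focal spot is partitioned by the absorption grating G0
into mutually incoherent line sources of width Ls (the opening of one G0
pitch, Ls = P0 * Y0 with open ratio Y0).  Each opening must be spatially
coherent over the MPG pitch at the grating plane, lc = lambda*Dsg/Ls >= P,
which caps the opening at Ls = lambda*Dsg/lc_required.  For the fringes of
all openings to superpose in registry on the detector, the G0 pitch must
equal the detector fringe period scaled back to the source plane,
P0 = W' * Dsg / Dgd.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Geometry, NM_PER_UM, UM_PER_MM, energy_to_wavelength
from .errors import InfeasibleDesignError, UnitsError
from .gratings import GratingSpec
from .sources import projected_source_width_um


def coherence_length(energy_kev: float, dsg_mm: float, ls_um: float) -> float:
    """Transverse coherence length lc = lambda*Dsg/Ls at the grating, in um."""
    if dsg_mm <= 0 or ls_um <= 0:
        raise UnitsError("coherence length needs positive Dsg and Ls")
    lam_um = energy_to_wavelength(energy_kev) / NM_PER_UM
    return lam_um * (dsg_mm * UM_PER_MM) / ls_um


def max_line_source(lc_required_um: float, dsg_mm: float, energy_kev: float) -> float:
    """Largest G0 opening Ls = lambda*Dsg/lc (um) meeting the coherence
    requirement ``lc >= lc_required`` (normally the MPG pitch)."""
    if lc_required_um <= 0 or dsg_mm <= 0:
        raise UnitsError("need positive coherence length and Dsg")
    lam_um = energy_to_wavelength(energy_kev) / NM_PER_UM
    return lam_um * (dsg_mm * UM_PER_MM) / lc_required_um


def g0_pitch(w_prime_um: float, geom: Geometry) -> float:
    """G0 pitch P0 = W'*Dsg/Dgd (um): fringes from adjacent openings land in
    registry on the detector."""
    if w_prime_um <= 0:
        raise UnitsError("fringe period must be positive")
    if geom.parallel:
        raise UnitsError("G0 design requires a finite source distance")
    return w_prime_um * geom.d_sg / geom.d_gd


@dataclass(frozen=True)
class CoherenceDesign:
    """Design sheet for one MPG pitch at a given geometry and energy."""

    ls_um: float  # line-source opening Ls
    lc_um: float  # coherence length at the MPG
    p0_um: float  # G0 pitch
    open_ratio: float  # Y0 = Ls/P0, as a fraction
    projected_source_um: float  # Ls*Dgd/Dsg at the detector
    fringe_period_um: float  # W'

    @property
    def open_ratio_pct(self) -> float:
        return 100.0 * self.open_ratio

    def fits_pixel(self, pixel_um: float) -> bool:
        """Whether the projected source blur stays within one detector pixel."""
        return self.projected_source_um <= pixel_um


def design_g0(
    mpg: GratingSpec,
    geom: Geometry,
    energy_kev: float,
    w_prime_um: float,
) -> CoherenceDesign:
    """Compose the coherence and registry constraints into a G0 design.

    Raises :class:`InfeasibleDesignError` when the required opening is not
    smaller than the G0 pitch (open ratio >= 1).
    """
    ls = max_line_source(mpg.pitch_um, geom.d_sg, energy_kev)
    p0 = g0_pitch(w_prime_um, geom)
    ratio = ls / p0
    if ratio >= 1.0:
        raise InfeasibleDesignError(
            f"open ratio {ratio:.3f} >= 1: opening {ls:.2f} um does not fit "
            f"in the G0 pitch {p0:.2f} um"
        )
    return CoherenceDesign(
        ls_um=ls,
        lc_um=coherence_length(energy_kev, geom.d_sg, ls),
        p0_um=p0,
        open_ratio=ratio,
        projected_source_um=projected_source_width_um(ls, geom),
        fringe_period_um=w_prime_um,
    )
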