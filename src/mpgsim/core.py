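"""Units, grids, fields and geometry shared by every other module.

Unit conventions (matching the quantities as they are usually printed for
grating interferometers): photon energy in keV, wavelength in nm, transverse
coordinates / pitches / periods / source sizes in um, axial distances in mm.
Conversions happen inside the numerical kernels, never at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UnitsError

#: hc in keV*nm (CODATA): E [keV] * lambda [nm] = hc.
HC_KEV_NM = 1.23984

#: Unit conversions used by the numerical kernels.
NM_PER_UM = 1.0e3
UM_PER_MM = 1.0e3


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV.

    lambda = hc / E; a strict bijection on (0, inf).
    """
    if energy_kev <= 0:
        raise UnitsError(f"photon energy must be positive, got {energy_kev} keV")
    return HC_KEV_NM / energy_kev


def wavelength_to_energy(wavelength_nm: float) -> float:
    """Photon energy in keV for a wavelength in nm (inverse of the above)."""
    if wavelength_nm <= 0:
        raise UnitsError(f"wavelength must be positive, got {wavelength_nm} nm")
    return HC_KEV_NM / wavelength_nm


def wavenumber_per_um(energy_kev: float) -> float:
    """k = 2*pi/lambda in rad/um."""
    return 2.0 * np.pi / (energy_to_wavelength(energy_kev) / NM_PER_UM)


@dataclass(frozen=True)
class Grid1D:
    """Uniform, node-centered 1D sampling grid along the transverse axis.

    Positions are ``start + i*step`` (um) for ``i = 0..n-1``.
    """

    start: float  # um
    step: float  # um
    n: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise UnitsError(f"grid step must be positive, got {self.step}")
        if self.n < 2:
            raise UnitsError(f"grid needs at least 2 samples, got {self.n}")

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n)

    @property
    def width(self) -> float:
        """Extent from first to last node in um."""
        return self.step * (self.n - 1)

    @classmethod
    def centered(cls, width_um: float, step_um: float) -> "Grid1D":
        """Symmetric grid around x = 0 spanning at least ``width_um``."""
        n = int(np.ceil(width_um / step_um)) + 1
        if n % 2 == 0:
            n += 1  # odd count puts a node exactly on the optical axis
        half = step_um * (n - 1) / 2.0
        return cls(start=-half, step=step_um, n=n)

    def scaled(self, factor: float) -> "Grid1D":
        """Grid with all positions multiplied by ``factor`` (magnification)."""
        return Grid1D(start=self.start * factor, step=self.step * factor, n=self.n)


@dataclass
class ComplexField:
    """Sampled complex wave amplitude on a :class:`Grid1D`."""

    grid: Grid1D
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.amplitude.shape != (self.grid.n,):
            raise UnitsError(
                f"amplitude length {self.amplitude.shape} does not match grid n={self.grid.n}"
            )

    @property
    def intensity(self) -> np.ndarray:
        """I = |A|^2."""
        return np.abs(self.amplitude) ** 2


@dataclass(frozen=True)
class Geometry:
    """Axial distances of the interferometer (all in mm).

    ``d_sg`` is the source(-grating)-to-MPG distance Dsg, ``d_gd`` the
    MPG-to-detector distance Dgd and ``d_od`` the optional object-to-detector
    distance Dod.  ``parallel=True`` marks the plane-wave convention
    (Dsg -> infinity, no geometric magnification).  ``d_focal_g0`` is the
    focal-spot-to-G0 distance when a source grating is modelled.
    """

    d_sg: float | None = None  # mm; None only when parallel
    d_gd: float = 600.0  # mm
    d_od: float | None = None  # mm
    d_focal_g0: float | None = None  # mm
    parallel: bool = False

    def __post_init__(self) -> None:
        if self.d_gd <= 0:
            raise UnitsError(f"Dgd must be positive, got {self.d_gd} mm")
        if not self.parallel:
            if self.d_sg is None:
                raise UnitsError("point/line geometry requires d_sg")
            if self.d_sg <= 0:
                raise UnitsError(f"Dsg must be positive, got {self.d_sg} mm")
        if self.d_od is not None:
            if self.d_od <= 0:
                raise UnitsError(f"Dod must be positive, got {self.d_od} mm")
            if self.d_od > self.d_gd:
                raise UnitsError(
                    "inverse geometry requires the object downstream of the MPG "
                    f"(Dod={self.d_od} mm > Dgd={self.d_gd} mm)"
                )
        if self.d_focal_g0 is not None and self.d_focal_g0 <= 0:
            raise UnitsError("focal-spot-to-G0 distance must be positive")

    @property
    def d_sd(self) -> float | None:
        """Source-to-detector distance Dsd = Dsg + Dgd (None for parallel)."""
        if self.parallel:
            return None
        return self.d_sg + self.d_gd

    def with_dgd(self, d_gd: float) -> "Geometry":
        return replace(self, d_gd=d_gd)


def magnification(geom: Geometry) -> float:
    """Geometric fringe magnification M = Dsd/Dsg (1 for a parallel beam)."""
    if geom.parallel:
        return 1.0
    return (geom.d_sg + geom.d_gd) / geom.d_sg


def object_magnification(d_source_object_mm: float, d_od_mm: float) -> float:
    """Magnification of an object at ``d_source_object`` from the source with
    the detector ``d_od`` further downstream."""
    if d_source_object_mm <= 0 or d_od_mm < 0:
        raise UnitsError("object magnification needs positive distances")
    return (d_source_object_mm + d_od_mm) / d_source_object_mm
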