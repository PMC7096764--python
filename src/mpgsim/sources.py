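"""Source models and the synthetic polychromatic tube spectrum.

A parallel beam and an ideal point source are handled directly by the
propagation module.  A finite line source (one opening of the source grating
G0, width Ls) is modelled by convolving the point-source detector intensity
with the geometrically projected source window of width Ls*Dgd/Dsg -- the
mutually incoherent sub-points of the opening superpose in intensity, and
Ls << Dsg by several orders of magnitude, so the projection is an ideal box.

The polychromatic tube beam is an incoherent sum over energies: each
spectral line is propagated fully coherently (with the grating bar phase
rescaled as 1/E from the design energy) and the intensities are added with
the spectral photon weights.  The built-in spectrum generator is a
filtered-bremsstrahlung model: Kramers' law N(E) ~ (kVp - E)/E attenuated by
exp(-mu(E) t) with tabulated Cu/Al attenuation (no characteristic lines;
tungsten K-lines below 60 kVp carry negligible weight after 0.2 mm Cu).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import Geometry
from .errors import ConfigError, UnitsError
from .fringes import VisibilityCurve
from .propagate import IntensityProfile

SourceKind = Literal["parallel", "point", "line"]


@dataclass(frozen=True)
class SourceSpec:
    """Parallel / point / finite-line source on the axis at z = -Dsg."""

    kind: SourceKind = "point"
    line_width_um: float | None = None  # Ls, line sources only

    def __post_init__(self) -> None:
        if self.kind == "line":
            if self.line_width_um is None or self.line_width_um <= 0:
                raise ConfigError("line source requires line_width_um > 0")


@dataclass
class Spectrum:
    """Discrete polychromatic weighting: energies (keV, ascending) and
    relative photon counts."""

    energies_kev: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.energies_kev.shape != self.weights.shape or self.energies_kev.ndim != 1:
            raise ConfigError("spectrum needs matching 1D energy and weight arrays")
        if self.energies_kev.size and np.any(np.diff(self.energies_kev) <= 0):
            raise ConfigError("spectrum energies must be strictly ascending")
        if np.any(self.energies_kev <= 0):
            raise UnitsError("spectrum energies must be positive")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ConfigError("spectrum weights must be finite and non-negative")
        if not np.any(self.weights > 0):
            raise ConfigError("spectrum needs at least one positive weight")

    @property
    def mean_energy_kev(self) -> float:
        return float(np.sum(self.energies_kev * self.weights) / np.sum(self.weights))

    def normalized(self) -> "Spectrum":
        return Spectrum(self.energies_kev.copy(), self.weights / np.sum(self.weights))

    def pruned(self, rel_threshold: float = 1e-4) -> "Spectrum":
        """Drop bins whose weight is below ``rel_threshold`` of the maximum."""
        keep = self.weights >= rel_threshold * np.max(self.weights)
        return Spectrum(self.energies_kev[keep], self.weights[keep]).normalized()

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["energy_kev", "weight"])
            for e, wt in zip(self.energies_kev, self.weights):
                w.writerow([f"{e:.6g}", f"{wt:.8g}"])

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        e, w = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                e.append(float(row["energy_kev"]))
                w.append(float(row["weight"]))
        return cls(np.asarray(e), np.asarray(w))


# NIST mass attenuation coefficients mu/rho in cm^2/g (photoelectric +
# scattering, no coherent removal), log-log interpolated between nodes.
_MU_RHO_TABLES: dict[str, tuple[np.ndarray, np.ndarray, float]] = {
    "Cu": (
        np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0]),
        np.array([215.9, 74.05, 33.79, 10.92, 4.862, 2.613, 1.593, 0.763, 0.4584]),
        8.96,  # g/cm^3
    ),
    "Al": (
        np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0]),
        np.array([26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704]),
        2.699,
    ),
}


def attenuation_factor(material: str, energies_kev: np.ndarray, thickness_mm: float) -> np.ndarray:
    """exp(-mu(E) * t) for a filter of ``thickness_mm``."""
    if material not in _MU_RHO_TABLES:
        raise ConfigError(f"unsupported filter material {material!r} (have Cu, Al)")
    e_nodes, mu_rho, rho = _MU_RHO_TABLES[material]
    log_mu = np.interp(np.log(energies_kev), np.log(e_nodes), np.log(mu_rho))
    mu = np.exp(log_mu) * rho  # 1/cm
    return np.exp(-mu * thickness_mm / 10.0)


def generate_spectrum(
    kvp: float,
    filter_material: str = "Cu",
    filter_thickness_mm: float = 0.2,
    bin_width_kev: float = 1.0,
    low_energy_cutoff_kev: float = 10.0,
) -> Spectrum:
    """Synthetic filtered-bremsstrahlung spectrum, normalized to unit weight.

    Kramers' law N(E) ~ (kVp - E)/E on [bin_width, kVp), times the filter
    transmission.  With a filter present, bins below the 10 keV cutoff are
    zeroed (their transmission is negligible anyway).
    """
    if kvp <= 0 or bin_width_kev <= 0:
        raise UnitsError("kvp and bin width must be positive")
    if filter_thickness_mm < 0:
        raise UnitsError("filter thickness must be non-negative")
    e = np.arange(bin_width_kev, kvp, bin_width_kev, dtype=np.float64)
    if e.size == 0:
        raise ConfigError("no spectral bins below the tube potential")
    w = (kvp - e) / e
    if filter_thickness_mm > 0:
        w = w * attenuation_factor(filter_material, e, filter_thickness_mm)
        w[e < low_energy_cutoff_kev] = 0.0
    if not np.any(w > 0):
        raise ConfigError("filtration removed the entire spectrum")
    return Spectrum(e, w / np.sum(w))


def projected_source_width_um(ls_um: float, geom: Geometry) -> float:
    """Width Ls*Dgd/Dsg of the source opening projected onto the detector."""
    if geom.parallel:
        raise ConfigError("projected source width is undefined for a parallel beam")
    return ls_um * geom.d_gd / geom.d_sg


def line_source_intensity(
    point_intensity: IntensityProfile, ls_um: float, geom: Geometry
) -> IntensityProfile:
    """Detector intensity for a finite line source of width Ls.

    Convolves the point-source intensity with a unit-area box of the
    projected width Ls*Dgd/Dsg.  If the projected width falls below two grid
    steps the profile is returned unchanged with a resolution warning.
    """
    if ls_um <= 0:
        raise UnitsError("line source width must be positive")
    w_proj = projected_source_width_um(ls_um, geom)
    step = point_intensity.grid.step
    n = int(round(w_proj / step))
    if n >= 2 and n % 2 == 0:
        n += 1  # symmetric (zero-phase) window
    if n < 2:
        warnings.warn(
            f"projected source width {w_proj:.3g} um < 2 grid steps; returning "
            "the point-source profile unchanged",
            stacklevel=2,
        )
        return IntensityProfile(point_intensity.grid, point_intensity.values.copy())
    kernel = np.full(n, 1.0 / n)
    vals = np.convolve(point_intensity.values, kernel, mode="same")
    return IntensityProfile(point_intensity.grid, vals)


def polychromatic_intensity(system, spectrum: Spectrum) -> IntensityProfile:
    """Incoherent spectral sum I(x) = sum_i w_i I(x; E_i) / sum_i w_i.

    ``system`` is an :class:`~mpgsim.simulate.MPGSystem`; each energy is
    propagated fully coherently with the grating bar phase rescaled as 1/E
    from the design energy (fixed physical heights).  A line source on the
    system is applied to the summed intensity (the convolution is linear).
    """
    spec = spectrum.normalized()
    total = None
    for e, w in zip(spec.energies_kev, spec.weights):
        if w == 0.0:
            continue
        prof = system.point_intensity(float(e))
        total = w * prof.values if total is None else total + w * prof.values
        grid = prof.grid
    out = IntensityProfile(grid, total)
    if system.source.kind == "line":
        out = line_source_intensity(out, system.source.line_width_um, system.geometry)
    return out


def temporal_coherence_sweep(system, energies_kev: Sequence[float]) -> VisibilityCurve:
    """Monochromatic fringe visibility per energy for fixed grating heights.

    The bar phase is rescaled as 1/E from the design energy; visibility is
    read at the system's detector fringe period W'.
    """
    vis = [system.visibility(energy_kev=float(e)) for e in energies_kev]
    return VisibilityCurve(
        parameter="energy_kev",
        values=np.asarray(list(energies_kev), dtype=np.float64),
        visibility_pct=np.asarray(vis, dtype=np.float64),
    )
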