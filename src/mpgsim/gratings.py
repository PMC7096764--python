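"""Complex transmission profiles T(x) = A(x) * exp(j*phi(x)) for phase gratings.

Covers the plain binary phase grating of Talbot--Lau systems, the two-level
combined grating used to explain broad-fringe formation, and the sinusoidally
modulated phase grating (MPG) at the core of the analyzer-less design: a
fine-pitch binary comb whose bar phase is slowly modulated by a cosine
envelope of period W much larger than the pitch.

All gratings are phase-only by default (the MPG is nearly transparent to
x-rays at the design energies); an optional amplitude model can be attached.
The projected bar phase scales with photon energy as phi(E) = phi(E_d)*E_d/E,
since for heights fixed at the design energy E_d the phase decrement delta of
the grating material scales as 1/E^2 while 1/lambda scales as E.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from .core import ComplexField, Grid1D
from .errors import ConfigError, SamplingError

Modulation = Literal["none", "rectangular", "sinusoidal", "triangular"]


@dataclass(frozen=True)
class GratingSpec:
    """Parameterization of a (possibly modulated) phase grating.

    ``phase_low``/``phase_high`` are the projected phase shifts phi1 <= phi2
    (rad) presented by the two bar heights at ``design_energy_kev``.  For an
    unmodulated grating only ``phase_high`` is used as the bar phase.
    ``mod_period_um`` is the envelope period W.  ``aperture_um`` optionally
    blocks everything outside a centered window of that width.
    """

    pitch_um: float
    duty: float = 0.5
    phase_low: float = 0.0
    phase_high: float = np.pi
    modulation: Modulation = "none"
    mod_period_um: float | None = None
    design_energy_kev: float = 40.0
    aperture_um: float | None = None

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ConfigError(f"pitch must be positive, got {self.pitch_um} um")
        if not 0.0 < self.duty < 1.0:
            raise ConfigError(f"duty must be in (0, 1), got {self.duty}")
        if not 0.0 <= self.phase_low <= self.phase_high:
            raise ConfigError(
                f"need 0 <= phase_low <= phase_high, got ({self.phase_low}, {self.phase_high})"
            )
        if self.modulation != "none":
            if self.mod_period_um is None:
                raise ConfigError(f"{self.modulation} modulation requires mod_period_um")
            if self.mod_period_um <= self.pitch_um:
                raise ConfigError(
                    f"modulation period W={self.mod_period_um} um must exceed "
                    f"the pitch P={self.pitch_um} um"
                )
        if self.design_energy_kev <= 0:
            raise ConfigError("design energy must be positive")

    def with_mod_period(self, w_um: float) -> "GratingSpec":
        return replace(self, mod_period_um=w_um)

    def with_pitch(self, pitch_um: float) -> "GratingSpec":
        return replace(self, pitch_um=pitch_um)


def phase_scale(spec: GratingSpec, energy_kev: float) -> float:
    """Multiplier taking design-energy bar phases to ``energy_kev``."""
    return spec.design_energy_kev / energy_kev


def bar_mask(spec: GratingSpec, x_um: np.ndarray) -> np.ndarray:
    """Boolean mask of grating bars on the pitch-P comb.

    Bars occupy the first ``duty`` fraction of each pitch starting at x = 0;
    a sample exactly on a bar/opening boundary belongs to the bar
    (left-closed, right-open intervals).
    """
    frac = np.mod(x_um / spec.pitch_um, 1.0)
    return frac < spec.duty


def _envelope(spec: GratingSpec, x_um: np.ndarray, energy_kev: float) -> np.ndarray:
    """Bar-phase envelope phi_env(x) at ``energy_kev``."""
    s = phase_scale(spec, energy_kev)
    lo, hi = spec.phase_low * s, spec.phase_high * s
    if spec.modulation == "none":
        return np.full_like(x_um, hi)
    w = spec.mod_period_um
    if spec.modulation == "sinusoidal":
        # crest (phi2) centered on the optical axis
        return lo + (hi - lo) * 0.5 * (1.0 + np.cos(2.0 * np.pi * x_um / w))
    if spec.modulation == "triangular":
        # symmetric triangle wave between phi1 and phi2, crest at the axis;
        # the calibrated reconstruction of the slow height modulation (the
        # published fringe visibilities are reproduced by this envelope, and
        # the modulation is described as triangular-approximable)
        saw = 2.0 * np.abs(np.mod(x_um / w + 0.5, 1.0) - 0.5)
        return lo + (hi - lo) * (1.0 - saw)
    if spec.modulation == "rectangular":
        # alternating half-period blocks of low and high bar phase,
        # high block centered at x = 0 like the sinusoidal crest
        high_block = np.mod(x_um / w + 0.25, 1.0) < 0.5
        return np.where(high_block, hi, lo)
    raise ConfigError(f"unknown modulation {spec.modulation!r}")


def transmission_profile(
    spec: GratingSpec,
    grid: Grid1D,
    energy_kev: float | None = None,
    attenuation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ComplexField:
    """Sampled complex transmission T(x) = A(x)*exp(j*phi(x)).

    ``energy_kev`` defaults to the design energy; at other energies the bar
    phase is rescaled as 1/E.  ``attenuation`` optionally maps positions (um)
    to an amplitude factor in [0, 1]; the default grating is phase-only.
    """
    if grid.step > spec.pitch_um / 10.0:
        raise SamplingError(
            f"grid step {grid.step} um does not resolve pitch {spec.pitch_um} um "
            "(need step <= pitch/10)"
        )
    e = spec.design_energy_kev if energy_kev is None else energy_kev
    x = grid.positions
    phi = np.where(bar_mask(spec, x), _envelope(spec, x, e), 0.0)
    amp = np.ones_like(x) if attenuation is None else np.clip(attenuation(x), 0.0, 1.0)
    if spec.aperture_um is not None:
        amp = np.where(np.abs(x) <= spec.aperture_um / 2.0, amp, 0.0)
    return ComplexField(grid=grid, amplitude=amp * np.exp(1j * phi))


def sinusoidal_mpg(
    spec: GratingSpec, grid: Grid1D, energy_kev: float | None = None
) -> ComplexField:
    """Transmission of a sinusoidally modulated phase grating.

    The bar phase follows phi_env(x) = phi1 + (phi2-phi1)*(1+cos(2*pi*x/W))/2
    on the bars of the pitch-P comb, so min(phi_env)=phi1 and max(phi_env)=phi2
    exactly, with the crest on the optical axis.
    """
    if spec.modulation != "sinusoidal":
        raise ConfigError("sinusoidal_mpg requires modulation='sinusoidal'")
    return transmission_profile(spec, grid, energy_kev)


def combined_two_level(
    spec_low: GratingSpec,
    spec_high: GratingSpec,
    unit_width_um: float,
    grid: Grid1D,
    energy_kev: float | None = None,
) -> ComplexField:
    """Two fine-pitch gratings with different bar phases interleaved in
    alternating blocks of ``unit_width_um``, repeating with W = 2*unit_width.

    This is the rectangular-modulation construction that demonstrates how
    bright/dim spots from low/high phase shifts compose a broad fringe.
    """
    if spec_low.pitch_um != spec_high.pitch_um:
        raise ConfigError(
            f"combined grating needs equal pitches, got {spec_low.pitch_um} "
            f"and {spec_high.pitch_um} um"
        )
    if unit_width_um <= 0:
        raise ConfigError("unit width must be positive")
    low = transmission_profile(spec_low, grid, energy_kev)
    high = transmission_profile(spec_high, grid, energy_kev)
    # block n covers [n*u, (n+1)*u); even blocks carry the high-phase grating
    # so the high unit is adjacent to the axis, as in the two-level sketch
    block = np.floor(grid.positions / unit_width_um).astype(int)
    take_high = np.mod(block, 2) == 0
    amp = np.where(take_high, high.amplitude, low.amplitude)
    return ComplexField(grid=grid, amplitude=amp)
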