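"""Fringe-visibility extraction, smoothing, pixel binning and sweep drivers.

Visibility is the peak/trough contrast (Ipeak - Itrough)/(Ipeak + Itrough)
of the periodic fringe pattern near the optical axis, in percent.  The broad
MPG fringes are composited from pitch-scale micro-fringes, so the envelope is
optionally smoothed with a small box window before the peak and trough are
read off; the smoothing width is a knob (default 1 um) that removes the
micro-structure while leaving the fringe-period (>= 100 um) envelope intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import Grid1D
from .errors import CoverageError, UndefinedVisibilityError
from .propagate import IntensityProfile


@dataclass
class VisibilityCurve:
    """Visibility (percent) as a function of one swept parameter."""

    parameter: str
    values: np.ndarray
    visibility_pct: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.visibility_pct = np.asarray(self.visibility_pct, dtype=np.float64)
        if self.values.shape != self.visibility_pct.shape:
            raise ValueError("parameter values and visibilities differ in length")
        if np.any((self.visibility_pct < -1e-9) | (self.visibility_pct > 100 + 1e-9)):
            raise ValueError("visibility out of [0, 100]")


def _box_kernel_samples(width_um: float, step_um: float, odd: bool = False) -> int:
    n = max(1, int(round(width_um / step_um)))
    if odd and n % 2 == 0:
        n += 1  # symmetric (zero-phase) filter
    return n


def smooth_box(profile: IntensityProfile, width_um: float) -> IntensityProfile:
    """Moving average with a unit-area box window of ``width_um``.

    The box is realized as round(width/step) samples, rounded up to an odd
    count so the filter is symmetric (zero phase); a width below one grid
    step is a no-op (with a warning).  The mean is preserved; total
    integrated intensity is preserved away from the window edges.
    """
    step = profile.grid.step
    if width_um < step:
        warnings.warn(
            f"smoothing width {width_um} um is below the grid step {step} um; no-op",
            stacklevel=2,
        )
        return IntensityProfile(profile.grid, profile.values.copy())
    n = _box_kernel_samples(width_um, step, odd=True)
    if n == 1:
        return IntensityProfile(profile.grid, profile.values.copy())
    kernel = np.full(n, 1.0 / n)
    sm = np.convolve(profile.values, kernel, mode="same")
    return IntensityProfile(profile.grid, sm)


def pixel_bin(profile: IntensityProfile, pixel_um: float) -> IntensityProfile:
    """Integrate over non-overlapping detector pixels of ``pixel_um``.

    Output values are per-pixel mean intensities on a bin-centered grid at
    pixel spacing (so the integrated intensity value*width is conserved).
    """
    step = profile.grid.step
    if pixel_um < step:
        warnings.warn(
            f"pixel {pixel_um} um below grid step {step} um; no-op", stacklevel=2
        )
        return IntensityProfile(profile.grid, profile.values.copy())
    m = _box_kernel_samples(pixel_um, step)
    if m == 1:
        return IntensityProfile(profile.grid, profile.values.copy())
    nbins = profile.grid.n // m
    if nbins < 2:
        raise CoverageError("fewer than two pixels fit in the profile")
    vals = profile.values[: nbins * m].reshape(nbins, m).mean(axis=1)
    start = profile.grid.start + (m - 1) / 2.0 * step
    return IntensityProfile(Grid1D(start=start, step=m * step, n=nbins), vals)


def visibility(
    profile: IntensityProfile,
    fringe_period_um: float,
    smooth_um: float | None = None,
) -> float:
    """Peak/trough fringe visibility in percent near the optical axis.

    Ipeak is the maximum of the (optionally box-smoothed) envelope within
    half a fringe period of the axis; Itrough the minimum between that peak
    and the adjacent peak one period away (searched on the side with
    coverage).  Returns 100*(Ipeak - Itrough)/(Ipeak + Itrough).
    """
    if fringe_period_um <= 0:
        raise ValueError("fringe period must be positive")
    x = profile.grid.positions
    if x[-1] - x[0] < 1.5 * fringe_period_um:
        raise CoverageError(
            f"profile spans {x[-1] - x[0]:.1f} um < 1.5 fringe periods "
            f"({1.5 * fringe_period_um:.1f} um)"
        )
    vals = profile.values
    if smooth_um is not None and smooth_um >= profile.grid.step:
        vals = smooth_box(profile, smooth_um).values
    central = np.abs(x) <= fringe_period_um / 2.0
    if not np.any(central):
        raise CoverageError("no samples within half a period of the axis")
    idx_central = np.flatnonzero(central)
    i_pk = idx_central[np.argmax(vals[idx_central])]
    x_pk = x[i_pk]
    # trough between this peak and the adjacent one, preferring the side
    # with full coverage
    side_hi = (x > x_pk) & (x < x_pk + fringe_period_um)
    side_lo = (x < x_pk) & (x > x_pk - fringe_period_um)
    if x_pk + fringe_period_um <= x[-1]:
        mask = side_hi
    elif x_pk - fringe_period_um >= x[0]:
        mask = side_lo
    else:
        raise CoverageError("no adjacent fringe period within the profile")
    i_peak_val = float(vals[i_pk])
    i_trough = float(np.min(vals[mask]))
    if i_peak_val <= 0.0:
        raise UndefinedVisibilityError("flat zero profile has no defined visibility")
    v = 100.0 * (i_peak_val - i_trough) / (i_peak_val + i_trough)
    return float(np.clip(v, 0.0, 100.0))


def fourier_visibility(profile: IntensityProfile, fringe_period_um: float) -> float:
    """First-harmonic visibility estimate 100*2*|c1|/c0 at frequency 1/W'.

    Independent cross-check of the peak/trough estimator; exact for a pure
    sinusoidal fringe I = c0*(1 + v*cos(2 pi x / W')) on a whole number of
    periods (a Hann window controls leakage otherwise).
    """
    x = profile.grid.positions
    vals = profile.values
    w = np.hanning(vals.size)
    c0 = np.sum(vals * w)
    if c0 <= 0:
        raise UndefinedVisibilityError("flat zero profile has no defined visibility")
    c1 = np.sum(vals * w * np.exp(-2j * np.pi * x / fringe_period_um))
    return float(np.clip(100.0 * 2.0 * np.abs(c1) / c0, 0.0, 100.0))


def fringe_harmonic(profile: IntensityProfile, fringe_period_um: float) -> float:
    """Unclipped first-harmonic amplitude ratio 2*|c1|/c0 at 1/period.

    Used to locate self-imaging maxima in a carpet: unlike a visibility it
    may exceed 1 (a binary square-wave fringe has 4/pi), but it varies
    smoothly through the maxima so they can be interpolated.
    """
    x = profile.grid.positions
    vals = profile.values
    w = np.hanning(vals.size)
    c0 = np.sum(vals * w)
    if c0 <= 0:
        raise UndefinedVisibilityError("flat zero profile has no harmonic ratio")
    c1 = np.sum(vals * w * np.exp(-2j * np.pi * x / fringe_period_um))
    return float(2.0 * np.abs(c1) / c0)


def locate_peaks(z_mm: np.ndarray, metric: np.ndarray, prominence: float | None = None) -> np.ndarray:
    """Positions of local maxima of ``metric(z)`` refined by quadratic
    interpolation around each discrete maximum."""
    from scipy.signal import find_peaks

    prom = prominence if prominence is not None else 0.1 * (np.max(metric) - np.min(metric))
    idx, _ = find_peaks(metric, prominence=prom)
    out = []
    for i in idx:
        if 0 < i < metric.size - 1:
            y0, y1, y2 = metric[i - 1], metric[i], metric[i + 1]
            denom = y0 - 2.0 * y1 + y2
            frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            out.append(z_mm[i] + frac * (z_mm[1] - z_mm[0]))
        else:
            out.append(z_mm[i])
    return np.asarray(out)


def sweep(
    parameter: str,
    values: Sequence[float],
    run: Callable[[float], float],
) -> VisibilityCurve:
    """Generic sweep driver: evaluate ``run(value) -> visibility_pct`` over
    ``values`` (z in mm, E in keV, P or W in um, ...)."""
    vis = np.array([run(float(v)) for v in values], dtype=np.float64)
    return VisibilityCurve(parameter=parameter, values=np.asarray(values, float), visibility_pct=vis)
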