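"""Configuration parsing and validation.

Configs are flat YAML mappings in the units the quantities are usually
quoted in: energies in keV, axial distances in mm, pitches/periods/source
sizes in um, sampling in nm.  Validation rejects unknown keys, checks every
geometric and grating invariant, and reports the derived quantities
(wavelength, magnification M, detector fringe period W', phase sensitivity
S) so a config can be sanity-checked before any propagation runs.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import yaml

from .core import Geometry, energy_to_wavelength, magnification
from .errors import ConfigError
from .gratings import GratingSpec
from .retrieval import phase_sensitivity
from .simulate import MPGSystem
from .sources import SourceSpec

_KNOWN_KEYS = {
    "energy_kev",
    "design_energy_kev",
    "dsg_mm",
    "dgd_mm",
    "dod_mm",
    "source",
    "line_width_um",
    "pitch_um",
    "duty",
    "phase_low_rad",
    "phase_high_rad",
    "modulation",
    "mod_period_um",
    "w_prime_um",
    "aperture_um",
    "grating_sampling_nm",
    "span_fringe_periods",
    "guard_fraction",
    "envelope_smooth_um",
}

_NOMINAL_PERIOD_GRID_UM = 25.0  # design fringe periods are quoted in round steps


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return raw


def validate_config(raw: dict[str, Any]) -> tuple[MPGSystem, dict[str, Any]]:
    """Validate a raw config mapping into an :class:`MPGSystem`.

    Returns the system plus a report of derived quantities and warnings.
    Every violated invariant raises a :class:`ConfigError` naming the key.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    def need(key, default=None):
        if key in raw:
            return raw[key]
        if default is None:
            raise ConfigError(f"missing required config key '{key}'")
        return default

    warnings: list[str] = []
    source_kind = need("source", "point")
    if source_kind not in ("parallel", "point", "line"):
        raise ConfigError(f"source: must be parallel/point/line, got {source_kind!r}")
    source = SourceSpec(
        kind=source_kind,
        line_width_um=raw.get("line_width_um") if source_kind == "line" else None,
    )

    parallel = source_kind == "parallel"
    try:
        geom = Geometry(
            d_sg=None if parallel else float(need("dsg_mm")),
            d_gd=float(need("dgd_mm")),
            d_od=float(raw["dod_mm"]) if "dod_mm" in raw else None,
            parallel=parallel,
        )
    except Exception as exc:  # re-raise with key context
        raise ConfigError(f"geometry (dsg_mm/dgd_mm/dod_mm): {exc}") from exc

    m = magnification(geom)
    mod = need("modulation", "triangular")
    mod_period = raw.get("mod_period_um")
    w_prime = raw.get("w_prime_um")
    if mod != "none":
        if mod_period is None and w_prime is None:
            raise ConfigError("modulated grating needs mod_period_um or w_prime_um")
        if mod_period is None:
            mod_period = float(w_prime) / m
    energy = float(need("energy_kev"))
    design_energy = float(raw.get("design_energy_kev", energy))
    try:
        grating = GratingSpec(
            pitch_um=float(need("pitch_um")),
            duty=float(need("duty", 0.5)),
            phase_low=float(need("phase_low_rad", 0.0)),
            phase_high=float(need("phase_high_rad", np.pi)),
            modulation=mod,
            mod_period_um=None if mod == "none" else float(mod_period),
            design_energy_kev=design_energy,
            aperture_um=raw.get("aperture_um"),
        )
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"grating: {exc}") from exc

    system = MPGSystem(
        grating=grating,
        geometry=geom,
        source=source,
        energy_kev=energy,
        grating_step_um=float(need("grating_sampling_nm", 1.0)) * 1e-3,
        span_fringe_periods=float(need("span_fringe_periods", 4.0)),
        guard_fraction=float(need("guard_fraction", 0.2)),
        envelope_smooth_um=raw.get("envelope_smooth_um"),
    )

    report: dict[str, Any] = {
        "wavelength_nm": energy_to_wavelength(energy),
        "magnification": m,
    }
    if grating.mod_period_um is not None:
        wp = grating.mod_period_um * m
        report["w_prime_um"] = wp
        nominal = round(wp / _NOMINAL_PERIOD_GRID_UM) * _NOMINAL_PERIOD_GRID_UM
        if nominal > 0 and wp != nominal and abs(wp - nominal) / nominal < 0.05:
            warnings.append(
                f"derived fringe period W' = {wp:.1f} um is close to, but not "
                f"exactly, the nominal design period {nominal:.0f} um"
            )
        if geom.d_od is not None:
            report["sensitivity"] = phase_sensitivity(geom.d_od, wp)
    report["warnings"] = warnings
    return system, report
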