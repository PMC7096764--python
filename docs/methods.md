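# Methods

## Physical model

The simulator is scalar wave optics in the projection approximation.  A
grating or object is a thin screen multiplying the field by
T(x) = A(x)·exp(jφ(x)); the gratings are phase-only by default (A ≡ 1),
since at 20–60 keV a micron-scale silicon/polymer grating is nearly
transparent.  Fields propagate between planes with the Rayleigh–Sommerfeld
diffraction integral; intensity is |A|².

**1D reduction.**  All gratings are line gratings, invariant along y, so
the y-integral of the 2D kernel is evaluated by stationary phase.  The
effective 1D kernel is ∝ exp(j(kr + π/4))/√(λr) with r = √(z² + Δx²),
times the obliquity z/r; constant phase offsets cancel in intensity.  A
direct quadrature of this kernel (`srdi_parallel`, `srdi_point_source`) is
the reference implementation; it is O(N₁·N₂) and guards against
undersampling (it refuses when the kernel phase advances more than π per
grating sample anywhere in the aperture).

**Fast path.**  Production runs use band-limited angular-spectrum
propagation: FFT, multiply by exp(jkz√(1−(λf)²)) with the evanescent part
dropped, inverse FFT.  The input is zero-padded (factor 2 by default) and
the transfer function truncated at the standard limit that keeps its
sampled phase below π per frequency bin, suppressing wrap-around replicas.
Cone-beam (point-source) geometry uses the Fresnel scaling theorem: a
spherical wave from distance R propagating a further d equals a plane-wave
propagation over R·d/(R+d) with coordinates magnified by (R+d)/R and
amplitude scaled by 1/√M.  Multi-plane chains (grating → object →
detector) update R stage by stage.  Both routes agree to <0.1% of the peak
intensity on oracle-sized instances (tested), and the fast path carries the
grids so that positions remain physical at every plane.

**Simulation aperture.**  The grating window spans a configurable number of
detector fringe periods (default 4 W′) plus a 20% guard band per side with
a raised-cosine taper; analysis happens near the optical axis, far from the
guard.  Grating sampling defaults to 1 nm.  Bar edges are sampled
left-closed (a node on a boundary belongs to the bar), which makes the
pointwise intensity converge first order in the step (≈0.3% change when
halving from 1 nm); integrated fringe observables (visibility, harmonic
amplitude) are converged to ≲10⁻⁵ at the default sampling, which is what
the simulator's outputs are built from.

## The modulated phase grating

The MPG is a binary comb of pitch P (duty 0.5) whose bar phase is slowly
modulated between φ₁ and φ₂ (π/4 and π at the 40-keV design energy) with
period W.  At other energies the bar phase scales as φ(E) = φ(E_d)·E_d/E,
because the material's refractive decrement δ scales as 1/E² while 1/λ
scales as E — the physical heights are fixed.

The exact envelope profile of the physical device is published only as a
sketch, so the envelope is pluggable:

* `sinusoidal` — φ_env(x) = φ₁ + (φ₂−φ₁)(1+cos 2πx/W)/2, crest on the axis;
* `triangular` — symmetric triangle wave between the same extremes;
* `rectangular` — alternating half-period blocks (the two-level combined
  grating used to demonstrate broad-fringe formation).

The reconstruction is calibrated against the published fringe-visibility
benchmarks of the breast-CT system, the only quantitative anchors
available.  The smooth cosine envelope overshoots all of them by 5–7
percentage points (e.g. 37.8% first-harmonic visibility for the
point-source system whose published value is 30.5%), while the triangular
envelope — which the source system's own description offers as the
approximation of its modulation — reproduces the point-source, line-source,
polychromatic and pitch-comparison values to within ≈1–2 points.
`bct_system()` therefore defaults to the triangular envelope; the cosine
variant remains one keyword away.  The residual ≈2–3-point overshoot of the
monochromatic point-source value is the remaining reconstruction
uncertainty and is visible in the test suite.

Broad fringes form because regions of bar phase φ scatter a fraction
sin²-like in φ out of the forward beam: where the envelope sits at φ₁ the
smoothed transmission is bright, at φ₂ dark.  The scattered pitch-scale
orders land λ·Dgd/P ≈ 31 μm away and partially refill the troughs, which is
what limits the visibility to ~30% rather than ~100%.

## Fringe visibility

Visibility is 100·(I_peak − I_trough)/(I_peak + I_trough): the peak is the
maximum of the smoothed envelope within ±W′/2 of the axis, the trough the
minimum between that peak and the adjacent one.  The profile first gets a
box smoothing whose default width is the *magnified* pitch P·M (2.04 μm for
the reference system): a box of exactly that width has sinc nulls on the
micro-fringe period and on every harmonic of it, while attenuating the
150-μm fringe by <0.1%.  The width is a knob; the test suite reports the
sensitivity of the read-off to it.  A Fourier estimator (2|c₁|/c₀ at 1/W′,
Hann-windowed) is provided as an independent cross-check, and its unclipped
variant (`fringe_harmonic`) is the peak locator for Talbot carpets, where
the peak/trough form saturates at 100% (binary π-grating patterns contain
deep zeros at most fractional Talbot planes).

## Sources and spectra

A finite line source (one G0 opening, width Ls) is modelled by convolving
the point-source detector intensity with a unit-area box of the projected
width Ls·Dgd/Dsg — the opening's sub-points are mutually incoherent and
Ls ≪ Dsg by five orders of magnitude, so quadrature over sub-points and
intensity convolution coincide.  Smoothing and convolution kernels are
rounded to odd sample counts (zero-phase filters).

Polychromatic beams are incoherent sums: each spectral bin is propagated
fully coherently with the bar phase rescaled as 1/E, and intensities are
added with the spectral weights.  The built-in spectrum is Kramers'
bremsstrahlung N(E) ∝ (kVp−E)/E times filter transmission exp(−μ(E)t),
with mass-attenuation tables for Cu and Al (log-log interpolated,
10–100 keV nodes) and a 10-keV cutoff under filtration.  Characteristic
tungsten K-lines are omitted: below 60 kVp and behind 0.2 mm Cu they carry
negligible weight.  The default 60 kVp + 0.2 mm Cu spectrum has mean energy
≈39.9 keV (the vendor-computed spectrum it stands in for reports ≈41 keV);
polychromatic visibilities consequently carry a ±2-point model tolerance.
Spectral bins default to 2 keV; 1 keV changes the polychromatic visibility
by <0.1 point.

## Coherence design (source grating G0)

For fringes to form, the coherence length at the MPG must span one pitch:
lc = λ·Dsg/Ls ≥ P, capping the opening at Ls = λ·Dsg/P (12.9 μm for
P = 0.6 μm, Dsg = 250 mm, 40 keV; 7.7 μm for P = 1.0 μm).  For the fringes
of adjacent openings to superpose in registry, the G0 pitch must be the
fringe period scaled back to the source plane, P0 = W′·Dsg/Dgd = 62.5 μm
for W′ = 150 μm — giving open ratios Ls/P0 of 20.7% and 12.4%.  G0 is
modelled as a single representative line source (registry makes the
openings equivalent); `design_g0` also reports the projected source blur
Ls·Dgd/Dsg against a chosen pixel size.  The focal-spot blur of the tube
itself affects the object image exactly as in non-interferometric CT and is
out of scope here.

## Phase sensitivity and single-shot retrieval

A thin object with projected phase Φ(y) refracts by α = (λ/2π)∂Φ/∂y and
shifts the fringes by Δy = α·Dod, i.e. Δφ = 2πΔy/W′; the sensitivity
S = Dod/W′ depends only on the object-to-detector distance and fringe
period (not on the grating position — verified as the inverse-geometry
invariance test).  Retrieval demodulates one fringe image at the carrier
1/W′: Hann window, FFT, isolate the sideband (half-width 0.5/W′ with a
raised-cosine outer taper — a hard band edge rings through the demodulated
phase), inverse FFT, take the argument of the analytic signal.  The
object-minus-reference phase is unwrapped outward from the optical axis,
converted to fringe shift, refraction angle and the projected phase
gradient dΦ/dy = 2πΔy/(λ·Dod·M_obj), and integrated by trapezoid over the
region with usable carrier power (≥20% of peak sideband amplitude, shrunk
by one period).  M_obj is the magnification of the *object plane* onto the
detector measured from the effective source — the G0 plane — i.e.
(Dsg+Dgd)/(Dsg+Dgd−Dod) = 2.125 for the reference geometry.  (The familiar
1.9 of the clinical layout measures from the focal spot and governs object
blur, not the wave simulation.)

The demodulation resolves phase structure on scales larger than ≈2W′ at
the detector.  Object gradients sharper than that act as diffractive phase
steps, outside the refractive model the retrieval inverts: slab-phantom
edges below ≈35 μm (object plane) produce multi-π retrieval errors, while
40-μm erf edges retrieve the projected profile to <0.05π.  The bundled
PMMA/polyimide phantom (1.4-mm, 0.79π PMMA block with an embedded 0.4-mm,
1.6π polyimide insert whose thickness displaces half the PMMA) therefore
defaults to 40-μm edges.  The printed phase shifts are used as ground
truth rather than recomputed from material δ tables.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| grating sampling | 1 nm | 5 nm in `--fast` mode (<0.9 pp visibility change) |
| aperture | 4 W′ + 20% guard/side | retrieval studies use 14–26 W′ |
| pad factor | 2 | 4 in oracle comparisons |
| envelope smoothing | P·M (auto) | knob `envelope_smooth_um` |
| spectral bins | 2 keV | 1 keV for full spectra |
| sideband half-width | 0.5/W′ | outer half raised-cosine tapered |
| phantom edge scale | 40 μm erf | resolution limit ≈35 μm |

A full visibility chain (point + line + polychromatic + 7-energy sweep) at
these defaults runs in ≈10 s on one CPU; the Talbot verification carpet
(200 planes) in ≈5 s; the phantom retrieval in ≈3 s.

## What the simulations do and do not emulate

The synthetic studies reproduce the deterministic wave-optics of the
system: coherent fringe formation, geometric magnification, partial
spatial coherence via the projected-source convolution, and spectral
dilution.  They do **not** include photon noise, detector MTF or energy
response (beyond optional pixel binning), Compton scatter, grating
fabrication errors, 2D effects (the y-dimension is handled analytically),
or dark-field signal extraction.  Passing tests therefore demonstrate the
optics and the retrieval algebra, not clinical image quality.

## Known limitations

* Paraxial cone-beam treatment (Fresnel scaling); exact at the ≤10⁻³ rad
  angles of this geometry but not for wide-angle optics.
* The envelope profile of the physical MPG is a calibrated reconstruction;
  monochromatic point-source visibility carries a ≈2–3-point uncertainty.
* The spectrum stand-in has no characteristic lines and a slightly softer
  mean energy than a vendor-computed spectrum.
* Retrieval assumes a rigid fringe carrier; strongly absorbing objects
  (amplitude contrast) and sub-resolution phase steps violate its model.
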