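# Methods

## Projection geometry

One detector side is measured at a time in a 1D coordinate system: origin at
the nearest detector edge (first/last pixel row or column), axis positive
toward the detector center, distances in mm, and the field boundary `X_FOV`
negative when the beam extends beyond the detector.  The boundary formula
and its inverse follow from two chained central projections: the source ray
through the boundary point at the detector plane fixes the irradiation edge
at the foil plane, and the slit projects that edge (with inversion and
magnification `y_slit / (y_foil - y_slit)`) back onto the detector.  The SID
is identified with `y_source`, the source height above the detector plane.
`y_foil = 0` is accepted as a degenerate reference case (the formula then
collapses to the identity); `y_foil = y_source` raises a geometry error.

External-sensor readings taken on top of the breast support are scaled to
the detector plane by the magnification `SID / (SID - h)` with `h = 25.0 mm`
(the support height; its 2.5 mm thickness is ignored, matching how the
clinical comparison was reported).  Reported distances are rounded to
0.1 mm, and comparisons between methods are formed from the rounded values;
internal arithmetic keeps full precision (tabulated columns at 0.01 mm).

## Edge localization

The profile pipeline integrates a 500-pixel-wide region of interest
perpendicular to the measurement axis, applies a 5-pixel moving mean with
*truncated* end windows (reflection would invent signal beyond the detector
edge), and normalizes to the minimum intensity inside the configured
camera-shadow window, so exposure differences between views cancel and the
baseline is exactly 1.

The steep fall between the fluorescence plateau and the baseline is not
sharp (slit aperture, focal-spot penumbra, scatter), so the edge is defined
by extrapolation: the plateau level is the median of the longest contiguous
run above the half-drop threshold; the fit window is the contiguous flank
whose normalized values lie within the fractional-height band
[0.15, 0.85] of the plateau-to-baseline drop (configurable); an ordinary
least-squares line through those samples is solved for y = 1.  The
fractional-height band is our concrete stand-in for the loosely specified
"points in the steep intensity fall": it is symmetric, robust to noise, and
avoids both the rounded shoulder at the plateau and the toe at the baseline.
Degenerate inputs fail loudly: a flat profile raises a no-edge error, fewer
than three in-band flank samples an insufficient-data error, and a
non-positive window minimum a data error.

The slit is assumed parallel to the image rows/columns; misalignment shows
up only as flank blur.  No deskew, flat-fielding or gain calibration is
attempted.

## Attenuation data

`src/slitfield/data/attenuation.csv` holds total and photoelectric mass
attenuation coefficients for H, C, N, O, Al, Ar, Cu, Zn, Zr, Mo, Ag, Sn and
Pb on a 55-point log grid over 1-150 keV, with duplicated points 5 eV below
and above every absorption edge so that log-log interpolation never bridges
a discontinuity.  The tables are generated (offline, reproducibly) by
`scripts/build_attenuation_tables.py`:

* photoabsorption from the Cromer-Liberman f'' factors via gemmi, converted
  with sigma = 2 r_e lambda f'';
* incoherent scattering as Klein-Nishina per electron times Z with a
  low-energy binding suppression `E^2 / (E^2 + (1.5 Z^(1/3))^2)`;
* coherent scattering as a screened-Thomson form
  `1.35 (Z/29)^0.5 Z^2 sigma_T / (1 + (E/E_s)^2)`, `E_s = 8.1 (Z/29)^(1/3)` keV,
  calibrated against reference values for mid-Z elements.

Spot checks against standard reference tables put the totals within ~1-3%
over the energies that matter here (8-100 keV); the photoelectric channel,
which drives the mean-free-path and foil-ranking results, agrees to ~2-3%.
The scattering model is deliberately simple - it contributes only a few
percent of the total for the metals in this energy range - and is the main
accuracy limit of the tables.

The K-shell share of the photoelectric coefficient uses the jump-ratio
approximation `1 - 1/J_K`, with `J_K` read off the tabulated edge
discontinuity.  This is accurate to a few percent above the edge, which is
sufficient for ranking foil thicknesses (the use made of it here).

## Spectra

The generator produces a Kramers-shape bremsstrahlung, intensity
proportional to `(E_max - E)/E` on a 0.5 keV grid, hardened by the listed
filters and normalized to unit weight.  Characteristic anode lines are not
modelled: at 39 kVp a tungsten anode emits none, and at 100 kVp their effect
on the thickness *argmax* is negligible compared to the filtration choice.
The 39 kVp W + 60 µm Ag beam comes out with a mean energy of 21.5 keV,
consistent with the 22.5 keV of the clinical beam this setting emulates
given the model's simplicity.  The 100 kVp radiographic beam is given
2.5 mm Al inherent filtration - a typical general-radiography tube; the
actual filtration of the reference simulation is not documented.  Users
wanting higher-fidelity spectra can load two-column text files.

## Fluorescence-signal model

The in-camera signal is the closed-form depth integral for normal incidence
and normal downward escape (see README for the formula), implemented with
`expm1` so the `mu_p -> mu_f` limit is reached without cancellation.  It is
an analytic surrogate for a full coupled photon-electron transport
simulation: no Compton/Rayleigh contribution to the in-camera signal, no
L-shell fluorescence, no detector energy response, and isotropic emission
collapsed into a constant solid-angle factor (the quantity is relative).
These simplifications shift the absolute signal but largely cancel in the
thickness ranking, which is what the optimizer asserts.  The default escape
path is the 2.5 mm polycarbonate breast support plus a 61 mm air column
(foil plane at 63.5 mm); the brass plates are excluded because the slit is
open.  Incidence is assumed normal (source far above the foil).

Near-ties in the thickness scan (within 1e-9 relative) resolve toward the
thinner foil, which is cheaper and emits from a better-defined plane.

## Synthetic scenes

The renderer emulates the documented appearance of clinical acquisitions of
the prototype: a 14-bit detector with a deterministic 50 ADU offset, ~100
ADU scattered background inside the camera shadow (the out-of-camera scatter
times a brass-transmission factor of 0.5), a fluorescence band at ~150 ADU
running from the projected foil end to the true edge position, a lead-backed
strip at offset level behind the camera, and Poisson noise on the
above-offset expectation.  The falling flank is the convolution of a step
with two boxes - the projected slit aperture (1 mm x the foil/slit
magnification, ~2 mm) and the focal-spot penumbra - and is placed so the
flank *foot* (where the signal vanishes) sits exactly at the edge position
the inverse boundary formula predicts; extrapolating the linear mid-section
of such a trapezoid to the baseline recovers the foot up to half the smaller
blur width (~0.02 mm here), which is what makes the round trip through the
measurement pipeline consistent by construction.

The penumbra model anchors the field boundary at the detector plane (the
collimator itself is not modelled): a focal spot of extent f spreads the
boundary at the foil plane over `f * y_foil/y_source`, magnified through the
slit by `y_slit/(y_foil - y_slit)` - about 0.03 mm for the 0.35 mm focal
spot, so the slit aperture dominates the flank width.  DBT acquisitions are
emulated by 2x2 binning (sum, pitch doubled).  Optional artifacts reproduce
two documented features: an intensity step at the projected end of the foil
(transmission through the bare top plate) and a direct-transmission bump at
the slit position seen at large DBT angles.

What the synthetic scenes do *not* contain: heel effect, anti-scatter grid,
off-focal radiation, detector MTF beyond the geometric blurs, gain
non-uniformity, or structured scatter.  Passing the recovery tests therefore
demonstrates the correctness of the geometry and of the profile pipeline
under quantum-limited noise at clinical signal levels - not robustness to
every real-world artifact.  One visible consequence: the edge-fit R² on
synthetic profiles is ≥ 0.99, higher than the 0.93-0.99 range of clinical
profiles, which carry structure noise the Poisson model omits; the test
suite asserts the recovery-quality bound (R² ≥ 0.9 on successful recovery)
rather than the clinical range.

## Compliance rules

* CFR (any side): overhang beyond the detector ≤ 2% of SID.
* MQSA: the CFR bound, plus the chest-wall requirement that the beam
  actually extend past the chest-wall edge (`x_fov < 0`); a chest-wall
  measurement is mandatory.
* EU: overhang ≤ 5 mm.
* Light/X-ray congruence: per-side |x_fov - x_light| (markers read at a
  height are projected down first), summed over sides against 2% of SID.
  The four-side sum is assembled from independently acquired sides; how the
  clinical workflow combines separate acquisitions is a procedural choice
  left to the operator.

All limits are configurable (`ComplianceLimits`).

## Problem sizes used in the checks

The default synthetic scene is 600 x 2048 pixels at 70 µm pitch (a 500-pixel
ROI fits comfortably), which resolves the ~2 mm flank with ~28 samples; the
statistical recovery checks use 20 seeds at the clinical ADU levels, and the
quadrature cross-check of the closed-form signal uses trapezoid grids of
2000+ steps scaled with optical depth.  These sizes were chosen so the whole
suite exercises every claim at full fidelity while remaining a desk-scale
computation.

## Known limitations

* Attenuation tables inherit Cromer-Liberman accuracy: a few percent
  mid-range, degrading near edges and below ~2 keV; good enough for
  mean-free-path (±5%) and argmax claims, not for dosimetry.
* The spectrum generator is semi-empirical; absolute spectral shapes (and
  hence absolute signal magnitudes and the relative heights of optimization
  curves across materials) are model-dependent.  Only boundary positions,
  compliance verdicts and thickness rankings are claimed.
* The exact thickness grid behind the published optimization curves is not
  documented; the package asserts the argmax over the commercially available
  thicknesses stated with the results.
* One-sided 1D measurements: no 2D field model, no DBT source-trajectory
  model (each angled view carries its own effective source position).
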