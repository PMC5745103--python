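# Methods

## The measurement being emulated

Three parallel sampling beams, arranged on an equilateral triangle of side
*s* = 2.5 mm in the pupil plane, are focused by the eye's optics onto a
mutual retinal spot. Each beam therefore illuminates the retina from a
different azimuthal direction (default channel azimuths 90°, 210°, 330°)
with a chief-ray inclination to the eye's axis of

  θ = arctan( (s/√3) / L ) ≈ 3.4°  for an eye of axial length L = 24 mm,

where s/√3 is the circumradius of the beam triangle. The pairwise angle
between two beams, arctan(s/L) ≈ 5.9°, is exposed separately
(`pairwise_beam_inclination`); the package reports the chief-ray-to-axis
reading as "the" inclination since that is the angle each channel's view
differs from a pupil-centred acquisition. The smallest centred pupil
aperture passing all three beam footprints is 2·(s/√3) + d ≈ 3.7 mm for
beam diameter d = 0.8 mm; smaller pupils vignette a channel and corrupt
the directional analysis.

## Phantom model

The phantom is *phenomenological*: it reproduces the geometry and the
statistics of multi-directional retinal B-scans, not wave optics.

**Layers.** A fixed stack of slabs (RNFL, lumped GCL–OPL, HFL, ONL, ELM,
IS/OS, OS, COST, rod-tip gap, RPE, choroid) with interface rows stored per
A-scan; a gentle common sinusoidal undulation (±5 px) moves the retina as
a whole so layer thicknesses stay constant. The axial pixel pitch is fixed
at 3.5 µm, consistent with the evaluation-window definitions (20 px ≈
70 µm, 15 px ≈ 53 µm). The RPE reference row used by segmentation and the
evaluation windows is the *centre* of the RPE band, which is also where a
brightness-path segmentation converges.

**Directional reflectance.** Each layer's expected intensity is
base reflectivity × gain(Δφ), Δφ = scan azimuth − channel azimuth:

* photoreceptor bands (IS/OS, COST): `exp(κ(cos Δφ − 1))` — a single
  von Mises-type lobe per revolution, peak 1 toward the beam, modelling
  the optical Stiles–Crawford-like apodization; default κ = 1.5;
* RNFL: `(1−m) + m·cos²Δφ` — two lobes 180° apart, the simplest form with
  the periodicity of cylindrical scatterers; the default modulation
  m = 0.3 is deliberately mild (the RNFL effect is reported as faint
  compared to the photoreceptor bands), and the RNFL-lobe experiment uses
  m = 0.6;
* HFL: `max(0, cos Δφ)^p` — visible only on the beam-aligned side of the
  fovea (p = 2 by default);
* everything else isotropic (gain 1), in particular the RPE, which is the
  normalization reference precisely because it is directionally invariant.

These functional forms are design choices: the literature establishes the
periodicities (one lobe per revolution for photoreceptors, two for RNFL,
one-sided HFL visibility) but not parametric shapes, so the simplest
periodic forms with the observed symmetry are used. Closed-form azimuthal
means (e^{-κ}I₀(κ), 1 − m/2, Γ((p+1)/2)/(2√π Γ(p/2+1))) are verified
against numerical integration in the tests.

**Statistics.** Intensity is expected value × unit-mean exponential
speckle (fully developed), independent across channels by default; an
optional ρ correlates the underlying complex fields (intensity
correlation ≈ ρ²). Additive zero-mean Gaussian background noise (default
σ = 30 counts) is independent across channels; the region above the ILM
contains noise only. Intensities are in arbitrary detector counts with the
RPE at 1000, so 10·log₁₀ images have the positive means that log-domain
metrics (CNR, ENL) assume on real scanner data. Vessels are azimuth
intervals whose columns are attenuated ×0.2 below a depth 25 px under the
ILM; no flow is modelled. Per-channel axial depth offsets emulate
sample-arm length mismatch.

**Spectral fringes.** For the reconstruction chain the phantom also
synthesizes raw spectra on a 1024-pixel wavelength-uniform grid spanning
790–890 nm (hence chirped in wavenumber): Gaussian source envelope
(Δλ_FWHM = 50 nm) times 1 + Σ_r 2√R_r cos(2kz_r + a₂(k−k₀)² + a₃(k−k₀)³),
with one reflector per nonzero row of the expected-intensity column.
Reflector depths are mapped through the grid's own depth-pixel pitch
π/(NΔk) ≈ 3.5 µm, so a reflector placed at depth pixel p reconstructs at
pixel p. Depths beyond N/2 pixels raise an aliasing error. Only quadratic
and cubic dispersion are synthesized; with k in rad/nm, coefficients of
order 10⁸ rad·nm² produce clearly visible broadening.

## Reconstruction

The chain is mean-spectrum subtraction (per spectral pixel over the frame;
frames of fewer than two A-scans are rejected because the mean would
cancel the signal) → resampling to a uniform k grid (cubic spline by
default, endpoints preserved) → analytic signal via Hilbert transform →
multiplication by exp(−i[a₂(k−k₀)² + a₃(k−k₀)³]) (pure phase; Parseval
energy preserved) → Hann apodization → FFT, keeping the magnitude of the
positive-frequency half. Interpolation order, window and zero-padding
(1/2/4) are configurable; defaults follow common SD-OCT practice.
Dispersion coefficients are applied, not estimated.

## Registration, flattening, fusion

Channels 2 and 3 are registered to channel 1 by exhaustive FFT
cross-correlation over translation (default search ±100 px axial, ±20 px
lateral) with a coarse-plus-quadratic search over rotation (±2°, step
0.5°) and quadratic sub-pixel peak interpolation. Both images are blurred
(Gaussian σ = 1 px) before scoring so the similarity is driven by
structure rather than by the speckle smoothing that rotation interpolation
introduces. Out-of-field pixels are filled with 0 so near-edge windows are
flagged rather than biased. One transform per channel is estimated from
the B-scan-averaged image (the channels are co-acquired) and applied to
every B-scan.

Flattening shifts each A-scan by an integer so the ILM lies on a common
row; shifts are circular (np.roll) so flatten→unflatten is exactly
invertible. Volume fusion flattens all three channels to one common target
row (the median channel-1 ILM row), fuses per voxel (mean or max) and
unflattens with channel-1's shifts, so the fused volume regains
channel-1's realistic surface shape.

## Segmentation

Boundaries are exact minimum-cost left-to-right paths (dynamic
programming; column-to-column jump ≤ 2 px; ties broken toward the smaller
row index; verified against an independent graph shortest path and, at
tiny sizes, literal path enumeration). Costs are computed on log₁₀
intensity (floor 1 count) blurred with σ = 2 px:

* **ILM**: 1 − normalized signed vertical gradient (dark→bright), plus a
  small linear depth penalty (0.3 over the full depth) so the topmost
  strong edge wins; if the mean gradient cost along the found path exceeds
  0.25 the image is declared retina-free (calibrated: phantom ILM paths
  score ≈ 0.1, pure-noise paths ≥ 0.3).
* **RPE**: 1 − normalized log intensity (brightest band), restricted to
  ≥ 40 px below the ILM. Columns whose 7-px RPE-band mean falls below 0.4
  of the B-scan median are flagged as vessel-shadowed and the boundary is
  linearly interpolated across them.

Only ILM and RPE are segmented — all quantification windows anchor on
them; other boundaries come from phantom truth or a user-supplied table
(e.g. a manually segmented HFL lower boundary).

## Directional quantification

The IS/OS–COST window spans rows [RPE−29, RPE−10] (depth 20, ending 10 px
anterior of the RPE row to exclude the directionally invariant RPE
signal); the RNFL window spans [ILM+3, ILM+17] (depth 15, starting 3 px
posterior of the ILM to exclude the specular vitreoretinal reflection).
The stated shift positions the window edge nearest the anchor away from
it; this reading is unit-tested explicitly since the prose convention is
ambiguous.

Per channel, the window mean per A-scan is averaged over ten consecutive
B-scans, divided by the B-scan median of a 10-px RPE-band mean (per
B-scan, vessel-flagged columns excluded from the median; a per-A-scan
normalization is available as an option) and rescaled to maximum 1 for
display parity. Smoothing is locally weighted regression with tricube
weights — degree 1 (lowess) or degree 2 (loess) — over a default span of
0.05; on the uniform circular azimuth grid the local fit reduces to a
fixed convolution kernel, applied on the circularly extended profile.
Peaks are local maxima with prominence ≥ 0.1 of the profile range on the
circularly extended profile; sector counting labels each azimuth with its
brightest channel and counts circular runs, merging runs shorter than 3%
of the circumference.

Color fusion tints the display-scaled (log-compressed, 1st–99.5th
percentile clipped) channels cyan (0,1,1), magenta (1,0,1) and yellow
(1,1,0); averaging the tinted images makes equal channels exactly
achromatic, per-component maxima give the color MIP. The per-pixel
intensity MIP compensates directional reflectivity (its azimuthal max/min
profile ratio is below every single channel's); the per-pixel intensity
average is the speckle-reduction operator. The en-face color MIP projects
a thin slab (≈ 7 px ≈ 25 µm) anchored on a boundary surface.

## Speckle metrics

SNR, CNR and ENL as defined in the README, averaged over five paired
100×50-px ROIs (one background ROI may be shared). The log transform is
10·log₁₀ with a floor at the 0.1th percentile of positive values (the
additive-noise background straddles zero). In the phantom experiment the
signal ROIs are auto-placed inside the RNFL band (avoiding vessel
columns), the background ROIs above the ILM. With independent background
noise, averaging the three channels leaves the signal mean unchanged and
divides the background variance by 3, so the expected SNR gain is
10·log₁₀ 3 ≈ 4.77 dB; CNR and ENL gains come from speckle-variance
reduction and are direction-tested rather than matched to instrument
absolute values, which depend on scanner-specific scaling.

## Problem sizes and determinism

The standard experiments use 1024 A-scans per circular B-scan with ten
B-scans averaged (the instrument's native 6144 is available via
configuration); the SNR experiment averages ten independent seeds. All
randomness flows from a single integer seed through
`numpy.random.SeedSequence`, and fixed seeds give bit-identical phantoms,
profiles and tables.

## Known limitations

* No wave-optics/PSF model, no eye aberrations, no sensitivity roll-off,
  no Doppler phase; absolute dB levels are not matched to any instrument.
* The directional gain shapes are the simplest forms with the observed
  periodicities; real photoreceptor pointing disorder, HFL geometry around
  a real fovea, and the reported hyporeflective network inside HFL are not
  modelled.
* Speckle is spatially white (one pixel per grain); real speckle grain is
  set by the system PSF.
* Registration assumes fine alignment (|θ| ≤ 5°, dominant axial shift);
  there is no deformable model and no inter-session registration.
* Segmentation is ILM/RPE only and is not claimed robust to pathology.
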