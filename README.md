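# mdoct — multi-directional OCT simulation and analysis

Multi-directional OCT probes a retinal location with **three simultaneous
sampling beams** entering the pupil at the corners of an equilateral
triangle (side ~2.5 mm). Because several retinal layers — the retinal nerve
fiber layer (RNFL), Henle's fiber layer (HFL) and the photoreceptor IS/OS
and COST bands — scatter light *directionally*, the three channels see
systematically different reflectivities, and comparing them separates true
tissue change from angle-of-incidence effects. This matters clinically:
reflectivity changes in the RNFL and photoreceptor bands are candidate
early markers of glaucoma and macular degeneration, but on a single-beam
scanner they are confounded by beam-entry geometry.

`mdoct` is a complete, instrument-free re-implementation of the processing
and analysis side of this technique for researchers in ophthalmic image
analysis:

* **phantom** — a forward simulator producing three-channel retinal
  B-scans/volumes (and raw spectral fringes) with known ground truth:
  layered retina, azimuth-dependent layer reflectance, fully developed
  speckle, background noise, vessel shadows, per-channel depth offsets.
* **recon** — standard SD-OCT reconstruction: mean-spectrum subtraction,
  λ→k resampling, numerical dispersion compensation, FFT.
* **register** — rigid-body inter-channel registration (the dominant term
  is the axial offset from sample-arm length mismatch), B-scan flattening
  and 3D fusion re-warped to the channel-1 surface.
* **segment** — ILM and RPE segmentation as an exact shortest-path graph
  search with a hard jump constraint; vessel-shadow flagging.
* **direction** — the core analysis: layer-anchored evaluation windows
  (20 px ≈ 70 µm ending 10 px anterior of the RPE for IS/OS–COST; 15 px ≈
  53 µm starting 3 px posterior of the ILM for the RNFL), RPE-normalized
  and lowess/loess-smoothed azimuthal profiles, sector/lobe detection,
  additive cyan/magenta/yellow color fusion, intensity/color MIP and
  average projections, en-face slab MIP.
* **metrics** — speckle-reduction metrics over five 100×50-pixel ROI pairs:

  SNR = 10·log₁₀(μ²ₛ,lin / σ²_b,lin),
  CNR = (μₛ,log − μ_b,log) / √(σ²ₛ,log + σ²_b,log),
  ENL = μ²ₛ,log / σ²ₛ,log.

## Worked example

The `report` command runs the whole chain — phantom, segmentation,
windows, normalization, smoothing, detection, fusion, metrics — and prints
a summary:

```sh
mdoct report --seed 1 --ascans 512
```

```json
{
  "photoreceptor_sector_separations_deg": [130.78, 117.42, 111.80],
  "photoreceptor_sector_count": 3,
  "rnfl_lobe_separations_deg": [165.94, 177.19, 172.97],
  "delta_snr_db": 4.81,
  "single_channel_mean": {"snr_db": 23.78, "cnr": 1.71, "enl": 11.03},
  "intensity_average": {"snr_db": 28.59, "cnr": 2.55, "enl": 81.75},
  "mip_max_min_ratio": 1.58,
  "single_channel_max_min_ratios": [6.30, 7.01, 7.70],
  "directional_compensation": true
}
```

Reading this: the three photoreceptor-window profiles peak ~120° apart —
one sector per beam, a direct consequence of the triangular pupil-entry
geometry — and dominant-channel labeling of the fused color image yields
exactly three sectors. The bilobed RNFL model produces two lobes per
channel ~180° apart (cylindrical scattering). Averaging the three channels
improves SNR by ~4.8 dB (the √3 gain expected for independent background
noise; instruments of this class report ~5 dB) and raises CNR and ENL; the
per-pixel maximum projection flattens the azimuthal intensity modulation
(max/min ratio 1.6 versus 6.3–7.7 for single channels), i.e. it
compensates directional reflectivity.

Individual stages are available as subcommands (`simulate`, `reconstruct`,
`register`, `segment`, `analyze`, `fuse`, `metrics`) writing TIFF stacks,
tab-separated tables and PNG profile plots; see `mdoct --help`.

## Documentation

`docs/methods.md` describes the phantom's reflectance models and their
assumptions, the numerical choices in every stage, and known limitations.
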