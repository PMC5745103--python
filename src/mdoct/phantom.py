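"""Forward simulator for three-channel (multi-directional) retinal OCT.

The phantom emulates the situation of three sampling beams entering the pupil
at the corners of an equilateral triangle and probing a mutual retinal spot
from three azimuthal orientations 120 degrees apart.  It produces

* beam/pupil geometry quantities (minimum pupil aperture, chief-ray
  inclination),
* linear-intensity B-scan stacks for the three channels with known
  ground-truth layer boundaries, azimuth-dependent layer reflectance,
  fully developed speckle, additive background noise, vessel shadows and
  per-channel axial depth offsets, and
* raw spectral fringe frames so the SD-OCT reconstruction chain can be
  exercised end to end.

All angles are degrees, azimuths live on the half-open interval [0, 360),
depth indices are 0-based and increase posteriorly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeamGeometry",
    "ScanPattern",
    "LayerModel",
    "PhantomTruth",
    "SpectralFrameSet",
    "MultiChannelStack",
    "min_pupil_aperture",
    "chief_ray_inclination",
    "pairwise_beam_inclination",
    "directional_gain",
    "default_layers",
    "default_truth",
    "expected_intensity",
    "render_multichannel",
    "render_spectra",
    "depth_pixel_pitch",
]

CHANNEL_COLORS = ("cyan", "magenta", "yellow")
CHANNEL_TINTS = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])

# Order of layer interfaces (top row of each slab) in the phantom retina.
LAYER_ORDER = (
    "ILM",      # top of RNFL (vitreous/retina interface)
    "GCL",      # RNFL bottom: lumped GCL..OPL inner retina
    "HFL",      # Henle's fiber layer
    "ONL",      # outer nuclear layer
    "ELM",      # external limiting membrane
    "ISOS",     # inner/outer segment junction
    "OS",       # outer segments
    "COST",     # cone outer segment tips
    "ROST",     # rod tips / pre-RPE gap
    "RPE",      # retinal pigment epithelium (bright band)
    "CHOROID",
)


@dataclass(frozen=True)
class BeamGeometry:
    """Pupil-plane beam triangle and eye parameters.

    The three collimated sample beams are parallel and arranged on the
    corners of an equilateral triangle of side ``triangle_side`` (mm) in the
    pupil plane; the eye's optics focus them onto a mutual retinal spot.
    """

    center_wavelength_nm: float = 840.0
    bandwidth_fwhm_nm: float = 50.0
    beam_diameter_pupil_mm: float = 0.8
    triangle_side_mm: float = 2.5
    channel_azimuths_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    eye_axial_length_mm: float = 24.0
    vitreous_index: float = 1.336

    def __post_init__(self) -> None:
        if self.triangle_side_mm <= 0:
            raise ValueError("triangle_side_mm must be positive")
        if self.beam_diameter_pupil_mm < 0:
            raise ValueError("beam_diameter_pupil_mm must be non-negative")
        if self.eye_axial_length_mm <= 0:
            raise ValueError("eye_axial_length_mm must be positive")
        az = np.mod(np.asarray(self.channel_azimuths_deg, dtype=float), 360.0)
        if len(az) != 3 or len(np.unique(np.round(az, 9))) != 3:
            raise ValueError("channel azimuths must be three distinct angles mod 360")

    @property
    def circumradius_mm(self) -> float:
        """Distance of each beam centre from the pupil centre."""
        return self.triangle_side_mm / np.sqrt(3.0)


def min_pupil_aperture(geometry: BeamGeometry) -> float:
    """Diameter (mm) of the smallest centred pupil circle passing all beams.

    2 * circumradius + beam diameter: each beam footprint must clear the
    iris, so the aperture must span the beam-centre circle plus one beam
    width.  With the default 2.5 mm triangle and 0.8 mm beams this is
    ~3.7 mm; smaller pupils vignette at least one channel.
    """
    if geometry.beam_diameter_pupil_mm <= 0 and geometry.triangle_side_mm <= 0:
        raise ValueError("degenerate beam geometry")
    return 2.0 * geometry.circumradius_mm + geometry.beam_diameter_pupil_mm


def chief_ray_inclination(geometry: BeamGeometry) -> float:
    """Angle (degrees) between each beam's chief ray and the eye's axis.

    The beams pass the pupil at the triangle circumradius off centre and
    meet on the retina, so each chief ray is inclined by
    arctan(circumradius / axial length) to the central axis (~3.4 degrees
    for the default geometry and a 24 mm eye).
    """
    return float(np.degrees(np.arctan2(geometry.circumradius_mm, geometry.eye_axial_length_mm)))


def pairwise_beam_inclination(geometry: BeamGeometry) -> float:
    """Angle (degrees) between two beams' chief rays at the retina.

    Adjacent beam centres are a full triangle side apart in the pupil plane,
    so the pairwise angle is larger than the chief-ray-to-axis angle by
    about a factor sqrt(3).
    """
    return float(np.degrees(np.arctan2(geometry.triangle_side_mm, geometry.eye_axial_length_mm)))


@dataclass(frozen=True)
class ScanPattern:
    """Scan geometry: circumpapillary circle, macular line or raster.

    For ``circumpapillary`` scans the lateral axis is azimuth: A-scan i of N
    sits at 360*i/N degrees (half-open [0, 360)).
    """

    kind: str = "circumpapillary"
    ascans_per_bscan: int = 6144
    bscans: int = 1
    fov_degrees: float = 10.0

    KINDS = ("circumpapillary", "linear", "raster")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scan kind {self.kind!r}")
        if self.ascans_per_bscan < 2:
            raise ValueError("ascans_per_bscan must be >= 2")
        if self.bscans < 1:
            raise ValueError("bscans must be >= 1")

    @classmethod
    def circumpapillary(cls, ascans: int = 6144, bscans: int = 1) -> "ScanPattern":
        return cls("circumpapillary", ascans, bscans, 10.0)

    @classmethod
    def linear(cls, ascans: int = 8192) -> "ScanPattern":
        return cls("linear", ascans, 1, 10.0)

    @classmethod
    def raster(cls, ascans: int = 2048, bscans: int = 250) -> "ScanPattern":
        return cls("raster", ascans, bscans, 10.0)

    def azimuths(self) -> np.ndarray:
        """Per-(B-scan, A-scan) sample azimuth in degrees, shape (bscans, ascans).

        Circumpapillary: position angle on the scan circle.  Linear: 0 on the
        right half of the line, 180 on the left (direction from the line
        centre).  Raster: polar angle of (x, y) about the raster centre.
        """
        n = self.ascans_per_bscan
        if self.kind == "circumpapillary":
            az = 360.0 * np.arange(n) / n
            return np.tile(az, (self.bscans, 1))
        if self.kind == "linear":
            x = np.arange(n) - (n - 1) / 2.0
            az = np.where(x >= 0, 0.0, 180.0)
            return az[None, :].repeat(self.bscans, axis=0)
        x = np.arange(n) - (n - 1) / 2.0
        y = np.arange(self.bscans) - (self.bscans - 1) / 2.0
        return np.mod(np.degrees(np.arctan2(y[:, None], x[None, :])), 360.0)


@dataclass(frozen=True)
class LayerModel:
    """Phenomenological reflectance model of one retinal layer.

    ``directional_kind`` selects how the layer's backscattering depends on
    the angle between the local sample azimuth and a channel's beam azimuth:

    * ``isotropic`` — no dependence (RPE, nuclear layers, choroid).
    * ``photoreceptor_vonmises`` — one lobe per revolution,
      exp(kappa*(cos(dphi) - 1)); models the optical Stiles-Crawford-like
      apodization of IS/OS and COST about the beam direction.
    * ``rnfl_bilobed`` — (1-m) + m*cos^2(dphi); cylindrical scatterers
      (axon bundles) reflect strongest perpendicular to the fibres, giving
      two lobes 180 degrees apart.
    * ``hfl_onesided`` — max(0, cos(dphi))^p; Henle fibres are only visible
      where the beam is near-perpendicular to the obliquely running fibres,
      i.e. on the beam-aligned side of the fovea.
    """

    name: str
    base_reflectivity: float
    directional_kind: str = "isotropic"
    concentration: float = 0.0
    modulation_depth: float = 0.0

    KINDS = ("isotropic", "photoreceptor_vonmises", "rnfl_bilobed", "hfl_onesided")

    def __post_init__(self) -> None:
        if self.base_reflectivity < 0:
            raise ValueError("base_reflectivity must be >= 0")
        if self.directional_kind not in self.KINDS:
            raise ValueError(f"unknown directional kind {self.directional_kind!r}")
        if self.concentration < 0:
            raise ValueError("concentration (kappa/power) must be >= 0")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")


def directional_gain(layer: LayerModel, scan_azimuth_deg, channel_azimuth_deg: float):
    """Dimensionless directional gain factor (>= 0, peak value 1).

    ``scan_azimuth_deg`` may be a scalar or array; broadcasting applies.
    """
    phi = np.deg2rad(np.asarray(scan_azimuth_deg, dtype=float) - channel_azimuth_deg)
    kind = layer.directional_kind
    if kind == "isotropic":
        return np.ones_like(phi) if phi.ndim else 1.0
    if kind == "photoreceptor_vonmises":
        return np.exp(layer.concentration * (np.cos(phi) - 1.0))
    if kind == "rnfl_bilobed":
        m = layer.modulation_depth
        return (1.0 - m) + m * np.cos(phi) ** 2
    # hfl_onesided
    return np.maximum(0.0, np.cos(phi)) ** layer.concentration


def default_layers(
    rnfl_modulation: float = 0.3,
    pr_kappa: float = 1.5,
    hfl_power: float = 2.0,
) -> list[LayerModel]:
    """Standard phantom layer set (linear intensity in arbitrary counts).

    Reflectivities are scaled so the RPE band sits at 1000 counts; the RNFL
    is moderately bright (photographic appearance of peripapillary scans),
    the nuclear layers dim, the photoreceptor bands bright and strongly
    directional.  The default RNFL modulation is mild — its directional
    lobes are a faint effect compared to the photoreceptor bands.
    """
    return [
        LayerModel("RNFL", 550.0, "rnfl_bilobed", modulation_depth=rnfl_modulation),
        LayerModel("GCL", 220.0),
        LayerModel("HFL", 300.0, "hfl_onesided", concentration=hfl_power),
        LayerModel("ONL", 80.0),
        LayerModel("ELM", 350.0),
        LayerModel("ISOS", 700.0, "photoreceptor_vonmises", concentration=pr_kappa),
        LayerModel("OS", 100.0),
        LayerModel("COST", 650.0, "photoreceptor_vonmises", concentration=pr_kappa),
        LayerModel("ROST", 120.0),
        LayerModel("RPE", 1000.0),
        LayerModel("CHOROID", 250.0),
    ]


@dataclass
class PhantomTruth:
    """Ground truth of a rendered phantom.

    ``boundaries`` maps each interface name of :data:`LAYER_ORDER` to the
    top row (0-based depth index) of that slab, shape (bscans, ascans);
    depth increases posteriorly and boundaries are strictly ordered at every
    A-scan.  ``rpe_reference`` (the row the segmentation and the evaluation
    windows anchor on) is the centre of the RPE band.
    """

    boundaries: dict[str, np.ndarray]
    depth: int
    vessel_azimuths: list[tuple[float, float]] = field(default_factory=list)
    channel_depth_offsets: tuple[int, int, int] = (0, 0, 0)
    axial_pixel_pitch_um: float = 3.5

    def __post_init__(self) -> None:
        prev = None
        for name in LAYER_ORDER:
            if name not in self.boundaries:
                raise ValueError(f"missing boundary {name!r}")
            b = np.atleast_2d(np.asarray(self.boundaries[name]))
            self.boundaries[name] = b
            if np.any(b < 0) or np.any(b >= self.depth):
                raise ValueError(f"boundary {name!r} outside depth range")
            if prev is not None and not np.all(b > prev):
                raise ValueError(f"boundaries out of order at {name!r}")
            prev = b

    @property
    def rpe_band_halfwidth(self) -> int:
        return 3

    def rpe_reference(self) -> np.ndarray:
        """Row of the RPE band centre, shape (bscans, ascans)."""
        return self.boundaries["RPE"] + self.rpe_band_halfwidth

    def ilm(self) -> np.ndarray:
        return self.boundaries["ILM"]

    def vessel_mask(self, pattern: ScanPattern) -> np.ndarray:
        """Boolean (bscans, ascans) mask of A-scans under a vessel."""
        az = pattern.azimuths()
        mask = np.zeros(az.shape, dtype=bool)
        for center, radius in self.vessel_azimuths:
            d = np.abs((az - center + 180.0) % 360.0 - 180.0)
            mask |= d <= radius
        return mask


def default_truth(
    pattern: ScanPattern,
    depth: int = 384,
    undulation_px: float = 5.0,
    vessels: tuple[tuple[float, float], ...] = ((45.0, 2.0), (200.0, 2.5)),
    channel_depth_offsets: tuple[int, int, int] = (0, 0, 0),
) -> PhantomTruth:
    """Build the standard layered-retina truth for a scan pattern.

    Layer interfaces sit at fixed depths plus a gentle common sinusoidal
    undulation (the retina tilts/curves as a whole, so layer thicknesses are
    constant).  At the default 3.5 um pitch the 384-pixel A-scan spans
    ~1.34 mm.
    """
    base_rows = {
        "ILM": 80, "GCL": 140, "HFL": 200, "ONL": 220, "ELM": 252,
        "ISOS": 256, "OS": 262, "COST": 270, "ROST": 276, "RPE": 284,
        "CHOROID": 290,
    }
    n = pattern.ascans_per_bscan
    if pattern.kind == "circumpapillary":
        phase = 2.0 * np.pi * np.arange(n) / n
        wobble = undulation_px * np.sin(2.0 * phase + 0.7)
    else:
        x = np.linspace(-np.pi, np.pi, n)
        wobble = undulation_px * np.sin(x + 0.3)
    offs = np.round(wobble).astype(int)[None, :].repeat(pattern.bscans, axis=0)
    boundaries = {k: v + offs for k, v in base_rows.items()}
    vessel_list = list(vessels) if pattern.kind == "circumpapillary" else []
    return PhantomTruth(
        boundaries=boundaries,
        depth=depth,
        vessel_azimuths=vessel_list,
        channel_depth_offsets=channel_depth_offsets,
    )


@dataclass
class MultiChannelStack:
    """Co-acquired linear-intensity B-scans of the three channels.

    ``data`` has shape (3, bscans, depth, ascans).
    """

    data: np.ndarray
    pattern: ScanPattern
    axial_pixel_pitch_um: float = 3.5
    channel_azimuths_deg: tuple[float, float, float] = (90.0, 210.0, 330.0)
    registered: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("stack data must have shape (3, bscans, depth, ascans)")
        if self.data.shape[1] != self.pattern.bscans or self.data.shape[3] != self.pattern.ascans_per_bscan:
            raise ValueError("stack dimensions do not match the scan pattern")

    @property
    def n_channels(self) -> int:
        return 3

    @property
    def depth(self) -> int:
        return self.data.shape[2]

    def bscan(self, channel: int, index: int = 0) -> np.ndarray:
        return self.data[channel, index]


VESSEL_SHADOW_FACTOR = 0.2
VESSEL_DEPTH_BELOW_ILM = 25


def _layer_slabs(truth: PhantomTruth) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(name, top_rows, bottom_rows) for every slab, bottom exclusive."""
    out = []
    names = list(LAYER_ORDER)
    for i, name in enumerate(names):
        top = truth.boundaries[name]
        if i + 1 < len(names):
            bottom = truth.boundaries[names[i + 1]]
        else:
            bottom = np.full_like(top, truth.depth)
        out.append((name, top, bottom))
    return out


def expected_intensity(
    truth: PhantomTruth,
    pattern: ScanPattern,
    layers: list[LayerModel],
    geometry: BeamGeometry,
    channel: int,
) -> np.ndarray:
    """Noise- and speckle-free expected intensity, shape (bscans, depth, ascans).

    Serves as the analytic oracle for everything downstream: each pixel is
    the local layer's base reflectivity times its directional gain at the
    A-scan azimuth for the given channel, with vessel-shadow attenuation
    applied below the vessel depth.  The per-channel axial offset is *not*
    applied here (this is the field in retina coordinates).
    """
    by_name = {l.name: l for l in layers}
    az = pattern.azimuths()  # (bscans, ascans)
    phi_c = geometry.channel_azimuths_deg[channel]
    nb, na = az.shape
    rows = np.arange(truth.depth)[None, :, None]
    out = np.zeros((nb, truth.depth, na))
    for name, top, bottom in _layer_slabs(truth):
        # the slab below the ILM interface is RNFL material
        layer = by_name.get("RNFL" if name == "ILM" else name)
        if layer is None or layer.base_reflectivity == 0:
            continue
        gain = directional_gain(layer, az, phi_c)  # (nb, na)
        mask = (rows >= top[:, None, :]) & (rows < bottom[:, None, :])
        out += mask * (layer.base_reflectivity * gain)[:, None, :]
    if truth.vessel_azimuths:
        vmask = truth.vessel_mask(pattern)  # (nb, na)
        vessel_row = truth.ilm() + VESSEL_DEPTH_BELOW_ILM
        shadow = (rows >= vessel_row[:, None, :]) & vmask[:, None, :]
        out = np.where(shadow, out * VESSEL_SHADOW_FACTOR, out)
    return out


def _axial_shift_int(img: np.ndarray, shift: int) -> np.ndarray:
    """Shift rows of (depth, ascans) image by integer `shift`, zero fill."""
    if shift == 0:
        return img
    out = np.zeros_like(img)
    if shift > 0:
        out[shift:] = img[:-shift]
    else:
        out[:shift] = img[-shift:]
    return out


def render_multichannel(
    truth: PhantomTruth,
    geometry: BeamGeometry,
    pattern: ScanPattern,
    layers: list[LayerModel],
    seed: int,
    noise_sigma: float = 30.0,
    speckle: bool = True,
    speckle_rho: float = 0.0,
) -> MultiChannelStack:
    """Render the three-channel linear-intensity stack.

    intensity = expected * speckle + N(0, noise_sigma), where the speckle is
    fully developed (unit-mean exponential).  ``speckle_rho`` in [0, 1]
    correlates the underlying complex speckle fields between channels
    (intensity correlation ~ rho^2); 0 (default) gives independent speckle.
    Fixed ``seed`` gives bit-identical output.
    """
    if not 0.0 <= speckle_rho <= 1.0:
        raise ValueError("speckle_rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nb = pattern.bscans
    na = pattern.ascans_per_bscan
    shape = (nb, truth.depth, na)
    if truth.boundaries["ILM"].shape != (nb, na):
        raise ValueError("truth boundary dimensions do not match scan pattern")

    if speckle:
        shared = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    channels = []
    for c in range(3):
        mean = expected_intensity(truth, pattern, layers, geometry, c)
        if speckle:
            own = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            g = np.sqrt(speckle_rho) * shared + np.sqrt(1.0 - speckle_rho) * own
            mean = mean * (np.abs(g) ** 2 / 2.0)
        if noise_sigma > 0:
            mean = mean + rng.normal(0.0, noise_sigma, shape)
        d = truth.channel_depth_offsets[c]
        if d:
            mean = np.stack([_axial_shift_int(b, int(d)) for b in mean])
        channels.append(mean)
    data = np.stack(channels)
    return MultiChannelStack(
        data=data,
        pattern=pattern,
        axial_pixel_pitch_um=truth.axial_pixel_pitch_um,
        channel_azimuths_deg=geometry.channel_azimuths_deg,
        registered=all(d == 0 for d in truth.channel_depth_offsets),
    )


# ---------------------------------------------------------------------------
# Raw spectral fringe synthesis


@dataclass
class SpectralFrameSet:
    """Raw spectral fringes: (channel, ascan, spectral pixel) detector counts.

    ``wavelength_grid_nm`` is strictly increasing and (being uniform in
    wavelength) non-uniform in wavenumber; ``dispersion_coeffs`` are the
    quadratic/cubic phase coefficients (rad per (rad/nm)^2 and ^3) baked
    into the fringes.
    """

    spectra: np.ndarray
    wavelength_grid_nm: np.ndarray
    dispersion_coeffs: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelength_grid_nm = np.asarray(self.wavelength_grid_nm, dtype=float)
        if np.any(np.diff(self.wavelength_grid_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")


def wavelength_grid(n_spectral: int = 1024, center_nm: float = 840.0, span_nm: float = 100.0) -> np.ndarray:
    """Spectrometer wavelength axis, uniform in wavelength (so chirped in k)."""
    return np.linspace(center_nm - span_nm / 2.0, center_nm + span_nm / 2.0, n_spectral)


def depth_pixel_pitch(wavelength_grid_nm: np.ndarray) -> float:
    """Depth-pixel size (nm) of the FFT reconstruction on the uniform-k grid.

    pi / (N * dk) where dk is the uniform wavenumber spacing spanning the
    grid; ~3.5 um for the default 790-890 nm, 1024-pixel grid.
    """
    lam = np.asarray(wavelength_grid_nm, dtype=float)
    k = 2.0 * np.pi / lam
    n = lam.size
    dk = (k.max() - k.min()) / (n - 1)
    return float(np.pi / (n * dk))


def render_spectra(
    truth: PhantomTruth,
    geometry: BeamGeometry,
    pattern: ScanPattern,
    layers: list[LayerModel],
    dispersion_coeffs: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    n_spectral: int = 1024,
    noise_sigma: float = 0.0,
    reflectivity_scale: float = 1e-6,
) -> SpectralFrameSet:
    """Synthesize raw spectral fringes for the phantom's expected intensity.

    Each A-scan spectrum is  E(k) * [1 + sum_r 2 sqrt(R_r) cos(2 k z_r +
    a2 (k-k0)^2 + a3 (k-k0)^3)]  sampled on the (wavelength-uniform) grid,
    with E(k) a Gaussian source envelope.  Reflector depths z_r are taken
    from the nonzero rows of the expected-intensity column (channel-offset
    applied), mapped through the reconstruction depth-pixel pitch so a
    reflector at depth pixel p reconstructs at pixel p.
    """
    lam = wavelength_grid(n_spectral, geometry.center_wavelength_nm)
    k = 2.0 * np.pi / lam  # decreasing
    k0 = 2.0 * np.pi / geometry.center_wavelength_nm
    # Gaussian envelope with the source FWHM (in k through the lambda FWHM)
    dk_fwhm = 2.0 * np.pi * geometry.bandwidth_fwhm_nm / geometry.center_wavelength_nm**2
    env = np.exp(-4.0 * np.log(2.0) * ((k - k0) / dk_fwhm) ** 2)
    pitch = depth_pixel_pitch(lam)
    max_px = n_spectral // 2
    a2, a3 = dispersion_coeffs
    rng = np.random.default_rng(seed)

    nb, na = pattern.bscans, pattern.ascans_per_bscan
    spectra = np.empty((3, nb * na, n_spectral))
    for c in range(3):
        field2d = expected_intensity(truth, pattern, layers, geometry, c)
        d = truth.channel_depth_offsets[c]
        idx = 0
        for b in range(nb):
            img = _axial_shift_int(field2d[b], int(d)) if d else field2d[b]
            for a in range(na):
                col = img[:, a]
                rows = np.nonzero(col)[0]
                if rows.size and rows.max() >= max_px:
                    raise ValueError(
                        f"reflector at depth pixel {rows.max()} beyond the unambiguous "
                        f"range {max_px} of the spectral sampling"
                    )
                fringe = np.ones_like(k)
                if rows.size:
                    z = rows * pitch
                    amp = 2.0 * np.sqrt(col[rows] * reflectivity_scale)
                    phase = (
                        2.0 * np.outer(k, z)
                        + (a2 * (k - k0) ** 2 + a3 * (k - k0) ** 3)[:, None]
                    )
                    fringe = fringe + (np.cos(phase) * amp[None, :]).sum(axis=1)
                s = env * fringe
                if noise_sigma > 0:
                    s = s + rng.normal(0.0, noise_sigma, s.shape)
                spectra[c, idx] = s
                idx += 1
    return SpectralFrameSet(spectra=spectra, wavelength_grid_nm=lam, dispersion_coeffs=dispersion_coeffs)
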