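"""Directional-reflectivity quantification and multi-channel fusion.

This is the analysis heart of the package: layer-anchored evaluation
windows, RPE-normalized and smoothed azimuthal intensity profiles of the
three channels, detection of the angular sectors/lobes they form,
additive cyan/magenta/yellow color fusion, and the maximum-intensity /
average projections used for directional-reflectivity compensation and
speckle reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .phantom import CHANNEL_COLORS, CHANNEL_TINTS, MultiChannelStack
from .segment import LayerMap

__all__ = [
    "EvaluationWindow",
    "isos_cost_window",
    "rnfl_window",
    "DirectionalProfile",
    "SectorSummary",
    "window_mean",
    "normalize_to_rpe",
    "smooth_profile",
    "azimuthal_profiles",
    "detect_sectors",
    "dominant_channel_sectors",
    "circular_separation",
    "display_scale",
    "color_average",
    "color_mip",
    "intensity_mip",
    "intensity_average",
    "enface_color_mip",
]


@dataclass(frozen=True)
class EvaluationWindow:
    """Depth window anchored to a segmented boundary.

    ``shift`` positions the window edge nearest the anchor away from it
    (negative = anterior), ``depth`` is the window height in pixels.  For
    an anterior window (negative shift) the window's *bottom* row is
    anchor + shift; for a posterior window its *top* row is anchor + shift.
    """

    anchor: str
    shift: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("window depth must be >= 1")

    def rows(self, anchor_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(top, bottom) inclusive row indices per A-scan."""
        anchor_rows = np.round(np.asarray(anchor_rows, dtype=float)).astype(int)
        if self.shift < 0:
            bottom = anchor_rows + self.shift
            top = bottom - self.depth + 1
        else:
            top = anchor_rows + self.shift
            bottom = top + self.depth - 1
        return top, bottom


def isos_cost_window() -> EvaluationWindow:
    """20-pixel (~70 um) photoreceptor window, ending 10 px anterior of the RPE.

    Rows [RPE-29, RPE-10]: covers the IS/OS-COST complex while excluding
    the directionally invariant RPE signal itself.
    """
    return EvaluationWindow(anchor="RPE", shift=-10, depth=20)


def rnfl_window() -> EvaluationWindow:
    """15-pixel (~53 um) RNFL window starting 3 px posterior of the ILM.

    Rows [ILM+3, ILM+17]: excludes the specular reflection at the
    vitreoretinal transition.
    """
    return EvaluationWindow(anchor="ILM", shift=3, depth=15)


@dataclass
class DirectionalProfile:
    """Window-mean intensity of one channel versus azimuth (or position)."""

    channel: int
    color: str
    azimuth_deg: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    n_averaged_bscans: int = 1
    vessel_flags: np.ndarray | None = None


@dataclass
class SectorSummary:
    """Detected profile peaks per channel and their circular separations."""

    peak_azimuths: list[list[float]]

    def sector_count(self, channel: int) -> int:
        return len(self.peak_azimuths[channel])

    def cross_channel_separations(self) -> list[float]:
        """Pairwise circular separations between each channel's main peak."""
        mains = [p[0] for p in self.peak_azimuths if p]
        return [
            circular_separation(mains[i], mains[j])
            for i in range(len(mains))
            for j in range(i + 1, len(mains))
        ]

    def within_channel_separations(self, channel: int) -> list[float]:
        p = self.peak_azimuths[channel]
        return [
            circular_separation(p[i], p[j])
            for i in range(len(p))
            for j in range(i + 1, len(p))
        ]


def circular_separation(a: float, b: float) -> float:
    """Circular distance between two azimuths in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def window_mean(bscan: np.ndarray, window: EvaluationWindow, anchor_rows: np.ndarray) -> np.ndarray:
    """Mean linear intensity over the window rows, per A-scan.

    Vessel-shadowed columns are not dropped here; callers carry flags.
    """
    bscan = np.asarray(bscan, dtype=float)
    top, bottom = window.rows(anchor_rows)
    depth, n_cols = bscan.shape
    if np.any(top < 0) or np.any(bottom > depth - 1):
        raise ValueError("evaluation window outside image")
    cs = np.vstack([np.zeros(n_cols), np.cumsum(bscan, axis=0)])
    cols = np.arange(n_cols)
    return (cs[bottom + 1, cols] - cs[top, cols]) / window.depth


def rpe_band_mean(bscan: np.ndarray, rpe_rows: np.ndarray, band: int = 10) -> np.ndarray:
    """Per-A-scan mean over a band of ``band`` rows centred on the RPE row."""
    half = band // 2
    return window_mean(bscan, EvaluationWindow("RPE", 0, band),
                       np.asarray(rpe_rows, dtype=float) - half)


def normalize_to_rpe(
    profile: np.ndarray,
    rpe_band: np.ndarray,
    flags: np.ndarray | None = None,
    rescale_max: bool = True,
) -> np.ndarray:
    """Normalize a window profile to the RPE intensity.

    Divides by the B-scan median of the per-A-scan RPE-band mean (flagged
    vessel columns excluded from the median), then rescales to max 1 for
    display.  The RPE is the directionally invariant reference, so this
    removes overall brightness differences between channels and scans.
    """
    rpe_band = np.asarray(rpe_band, dtype=float)
    good = ~flags if flags is not None else np.ones(rpe_band.size, dtype=bool)
    norm = float(np.median(rpe_band[good]))
    if norm <= 0:
        raise ValueError("non-positive RPE normalizer")
    out = np.asarray(profile, dtype=float) / norm
    if rescale_max:
        m = out.max()
        if m > 0:
            out = out / m
    return out


def _local_poly_kernel(window: int, degree: int) -> np.ndarray:
    """Equivalent kernel of a tricube-weighted local polynomial fit.

    On a uniform grid the locally weighted regression estimate at the
    window centre is a fixed linear combination of the samples, so the
    whole smoother is a convolution.
    """
    h = window // 2
    x = np.arange(-h, h + 1, dtype=float)
    w = (1.0 - np.abs(x / (h + 1)) ** 3) ** 3
    X = np.vander(x, degree + 1, increasing=True)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW)
    return beta[0]  # value of the fitted polynomial at x = 0


def smooth_profile(
    profile: np.ndarray,
    method: str = "lowess",
    span: float = 0.05,
    circular: bool = True,
) -> np.ndarray:
    """Locally weighted regression smoothing of a profile.

    ``lowess`` fits local lines (degree 1), ``loess`` local parabolas
    (degree 2), both with tricube weights over a window of ``span`` times
    the profile length.  Circumpapillary profiles wrap around, so the
    profile is circularly extended before smoothing and cropped after.
    """
    if method not in ("lowess", "loess"):
        raise ValueError("method must be 'lowess' or 'loess'")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    y = np.asarray(profile, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples to smooth")
    degree = 1 if method == "lowess" else 2
    window = max(degree + 2, int(round(span * n)))
    if window % 2 == 0:
        window += 1
    window = min(window, n if n % 2 else n - 1)
    kern = _local_poly_kernel(window, degree)
    h = window // 2
    if circular:
        padded = np.concatenate([y[-h:], y, y[:h]])
    else:
        padded = np.concatenate([y[h:0:-1], y, y[-2:-h - 2:-1]])
    return np.convolve(padded, kern[::-1], mode="valid")


def azimuthal_profiles(
    stack: MultiChannelStack,
    layer_map: LayerMap,
    preset: str = "isos_cost",
    n_bscans: int = 10,
    method: str = "lowess",
    span: float = 0.05,
) -> list[DirectionalProfile]:
    """Per-channel normalized, smoothed window-mean profiles of a CP stack.

    The evaluation window (``isos_cost`` or ``rnfl`` preset) is anchored on
    the segmented boundaries, its mean intensity computed per A-scan and
    averaged over ``n_bscans`` consecutive B-scans per channel, normalized
    to the RPE and smoothed.  The azimuth axis comes from the scan pattern.
    """
    if preset == "isos_cost":
        window = isos_cost_window()
        anchor_rows = layer_map.rpe
    elif preset == "rnfl":
        window = rnfl_window()
        anchor_rows = layer_map.ilm
    else:
        raise ValueError("preset must be 'isos_cost' or 'rnfl'")
    available = stack.data.shape[1]
    if available < n_bscans:
        warnings.warn(
            f"requested {n_bscans} B-scans but only {available} available; using all",
            stacklevel=2,
        )
        n_bscans = available
    azimuth = stack.pattern.azimuths()[0]
    flags = layer_map.vessel_flags
    profiles = []
    for c in range(3):
        raws = [
            window_mean(stack.data[c, b], window, anchor_rows)
            for b in range(n_bscans)
        ]
        raw = np.mean(raws, axis=0)
        bands = [
            rpe_band_mean(stack.data[c, b], layer_map.rpe) for b in range(n_bscans)
        ]
        normalized = normalize_to_rpe(raw, np.mean(bands, axis=0), flags)
        smoothed = smooth_profile(
            normalized, method=method, span=span,
            circular=stack.pattern.kind == "circumpapillary",
        )
        profiles.append(
            DirectionalProfile(
                channel=c,
                color=CHANNEL_COLORS[c],
                azimuth_deg=azimuth,
                raw=raw,
                normalized=normalized,
                smoothed=smoothed,
                n_averaged_bscans=n_bscans,
                vessel_flags=flags,
            )
        )
    return profiles


def detect_sectors(
    profiles: list[DirectionalProfile] | list[np.ndarray],
    prominence_frac: float = 0.1,
    azimuth_deg: np.ndarray | None = None,
) -> SectorSummary:
    """Detect the angular intensity lobes of each channel's smoothed profile.

    Peaks are local maxima of the circularly extended profile with
    prominence above ``prominence_frac`` of the profile range; peak lists
    are sorted by prominence (strongest first).
    """
    peak_lists = []
    for p in profiles:
        if isinstance(p, DirectionalProfile):
            y = p.smoothed
            az = p.azimuth_deg
        else:
            y = np.asarray(p, dtype=float)
            az = azimuth_deg if azimuth_deg is not None else 360.0 * np.arange(y.size) / y.size
        n = y.size
        tiled = np.concatenate([y, y, y])
        prom = prominence_frac * (y.max() - y.min())
        if prom <= 0:
            raise ValueError("flat profile: no peaks")
        idx, props = find_peaks(tiled, prominence=prom)
        keep = (idx >= n) & (idx < 2 * n)
        idx, proms = idx[keep] - n, props["prominences"][keep]
        if idx.size == 0:
            raise ValueError("no peaks above the prominence threshold")
        order = np.argsort(-proms)
        peak_lists.append([float(az[i]) for i in idx[order]])
    return SectorSummary(peak_azimuths=peak_lists)


def dominant_channel_sectors(
    channel_profiles: np.ndarray, min_run_frac: float = 0.03
) -> int:
    """Count circular runs of the dominant channel along the azimuth.

    ``channel_profiles`` is (3, N): e.g. the smoothed window profiles.  Each
    azimuth sample is labelled with its brightest channel; contiguous
    circular runs shorter than ``min_run_frac`` of the circumference are
    merged into their neighbours before counting.  Three beams 120 degrees
    apart with single-lobed layers give exactly 3 sectors.
    """
    labels = np.argmax(np.asarray(channel_profiles, dtype=float), axis=0)
    n = labels.size
    if np.all(labels == labels[0]):
        return 1
    # circular run-length encoding, starting at a label change
    start = int(np.argmax(labels != labels[0]))
    rolled = np.roll(labels, -start)
    change = np.nonzero(np.diff(rolled))[0] + 1
    bounds = np.concatenate([[0], change, [n]])
    runs = [[int(rolled[bounds[i]]), int(bounds[i + 1] - bounds[i])]
            for i in range(len(bounds) - 1)]
    min_len = max(1, int(min_run_frac * n))

    def _merge_same(rs: list[list[int]]) -> list[list[int]]:
        out: list[list[int]] = []
        for lab, length in rs:
            if out and out[-1][0] == lab:
                out[-1][1] += length
            else:
                out.append([lab, length])
        while len(out) > 1 and out[0][0] == out[-1][0]:
            out[0][1] += out[-1][1]
            out.pop()
        return out

    runs = _merge_same(runs)
    while len(runs) > 1:
        short = [i for i, (_, length) in enumerate(runs) if length < min_len]
        if not short:
            break
        i = min(short, key=lambda i: runs[i][1])
        prev_i, next_i = (i - 1) % len(runs), (i + 1) % len(runs)
        target = prev_i if runs[prev_i][1] >= runs[next_i][1] else next_i
        runs[target][1] += runs[i][1]
        runs.pop(i)
        runs = _merge_same(runs)
    return len(runs)


# ---------------------------------------------------------------------------
# Color fusion and projections


def display_scale(
    image: np.ndarray, clip_percentiles: tuple[float, float] = (1.0, 99.5)
) -> np.ndarray:
    """Map linear intensity to display range [0, 1]: log compress + clip."""
    img = np.log10(np.maximum(np.asarray(image, dtype=float), 1.0))
    lo, hi = np.percentile(img, clip_percentiles)
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _tinted(display_channels: np.ndarray) -> np.ndarray:
    """(3, ...) display-scaled channels -> (3, ..., 3) tinted RGB images."""
    return display_channels[..., None] * CHANNEL_TINTS[:, None, None, :]


def _check_registered(stack: MultiChannelStack, allow_unregistered: bool) -> None:
    if not stack.registered and not allow_unregistered:
        raise ValueError("stack is not registered; register first or pass allow_unregistered=True")


def color_average(
    channels: np.ndarray | MultiChannelStack,
    bscan: int = 0,
    allow_unregistered: bool = False,
) -> np.ndarray:
    """Additive cyan/magenta/yellow average of the three channels.

    Input display-scaled channel images (3, H, W) in [0, 1] or a registered
    stack (display scaling applied per channel).  Equal channel intensities
    give an achromatic pixel (the three tints add to white); a dominant
    channel tints the pixel with its hue.
    """
    if isinstance(channels, MultiChannelStack):
        _check_registered(channels, allow_unregistered)
        channels = np.stack([display_scale(channels.data[c, bscan]) for c in range(3)])
    return _tinted(np.asarray(channels, dtype=float)).mean(axis=0)


def color_mip(
    channels: np.ndarray | MultiChannelStack,
    bscan: int = 0,
    allow_unregistered: bool = False,
) -> np.ndarray:
    """Per-RGB-component maximum of the three tinted channel images."""
    if isinstance(channels, MultiChannelStack):
        _check_registered(channels, allow_unregistered)
        channels = np.stack([display_scale(channels.data[c, bscan]) for c in range(3)])
    return _tinted(np.asarray(channels, dtype=float)).max(axis=0)


def intensity_mip(stack: MultiChannelStack, allow_unregistered: bool = False) -> np.ndarray:
    """Per-pixel maximum of the three linear-intensity channels.

    The MIP compensates directional reflectivity: wherever at least one
    beam sees a directionally reflective layer well, the fused image does.
    Returns (bscans, depth, ascans).
    """
    _check_registered(stack, allow_unregistered)
    return stack.data.max(axis=0)


def intensity_average(stack: MultiChannelStack, allow_unregistered: bool = False) -> np.ndarray:
    """Per-pixel mean of the three linear-intensity channels (speckle reduction)."""
    _check_registered(stack, allow_unregistered)
    return stack.data.mean(axis=0)


def enface_color_mip(
    volumes: np.ndarray,
    anchor_rows: np.ndarray,
    slab_offset: int,
    slab_thickness: int,
) -> np.ndarray:
    """Color en-face MIP of a thin slab anchored to a boundary surface.

    ``volumes`` is (3, bscans, depth, ascans) of registered, flattened
    channels; ``anchor_rows`` (bscans, ascans) is the boundary surface the
    slab follows (e.g. the HFL top), the slab covering rows
    [anchor+slab_offset, anchor+slab_offset+slab_thickness).  ~7 px at the
    3.5 um pitch gives the ~25 um slab used for HFL visualization.
    Returns an RGB en-face map (bscans, ascans, 3).
    """
    volumes = np.asarray(volumes, dtype=float)
    if slab_thickness < 1:
        raise ValueError("slab thickness must be >= 1 pixel")
    nb, depth, na = volumes.shape[1:]
    anchor = np.round(np.asarray(anchor_rows, dtype=float)).astype(int)
    top = anchor + slab_offset
    if np.any(top < 0) or np.any(top + slab_thickness > depth):
        raise ValueError("slab outside volume")
    maps = np.zeros((3, nb, na))
    for t in range(slab_thickness):
        rows = top + t
        vals = np.take_along_axis(volumes, rows[None, :, None, :], axis=2)[:, :, 0, :]
        maps = np.maximum(maps, vals)
    m = maps.max()
    disp = maps / m if m > 0 else maps
    tinted = disp[..., None] * CHANNEL_TINTS[:, None, None, :]
    return tinted.max(axis=0)
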