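"""Speckle-reduction performance metrics: SNR, CNR and ENL.

SNR  = 10 log10( mu_s,lin^2 / sigma_b,lin^2 )           [dB, linear data]
CNR  = (mu_s,log - mu_b,log) / sqrt(sigma_s,log^2 + sigma_b,log^2)
ENL  = mu_s,log^2 / sigma_s,log^2

where the signal ROI sits in a homogeneous image part (here: within the
RNFL) and the background ROI above the ILM; the log quantities are
computed on 10*log10 scaled data.  Reported values are means over five
100x50-pixel ROI pairs per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiStats",
    "SpeckleMetrics",
    "log_scale",
    "roi_stats",
    "snr_db",
    "cnr",
    "enl",
    "evaluate_image",
    "place_rois_from_boundaries",
]

ROI_SHAPE = (50, 100)  # rows x cols = 100 px wide, 50 px deep


@dataclass(frozen=True)
class RoiStats:
    """Moments of one signal/background ROI pair."""

    mu_s_lin: float
    sigma_b_lin: float
    mu_s_log: float
    sigma_s_log: float
    mu_b_log: float
    sigma_b_log: float
    roi_shape: tuple[int, int] = ROI_SHAPE


@dataclass
class SpeckleMetrics:
    """ROI-averaged SNR/CNR/ENL of one image."""

    snr_db: float
    cnr: float
    enl: float
    n_rois: int
    per_roi: list[RoiStats] = field(default_factory=list)


def log_scale(image: np.ndarray, floor_percentile: float = 0.1) -> np.ndarray:
    """10*log10 of the linear image with a floor at a low positive percentile.

    The floor keeps background noise (which straddles zero in the additive
    noise model) finite without compressing the signal statistics.
    """
    image = np.asarray(image, dtype=float)
    pos = image[image > 0]
    if pos.size == 0:
        raise ValueError("image has no positive values")
    floor = np.percentile(pos, floor_percentile)
    return 10.0 * np.log10(np.maximum(image, floor))


def _extract(image: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
        raise ValueError(f"ROI {roi} outside image {image.shape}")
    return image[r : r + h, c : c + w]


def roi_stats(
    linear_image: np.ndarray,
    signal_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    log_image: np.ndarray | None = None,
) -> RoiStats:
    """Compute the linear- and log-domain ROI moments for one ROI pair.

    ROIs are (row, col, height, width), non-overlapping by construction of
    the protocol (signal in the RNFL, background above the ILM).
    """
    linear_image = np.asarray(linear_image, dtype=float)
    if log_image is None:
        log_image = log_scale(linear_image)
    s_lin = _extract(linear_image, signal_roi)
    b_lin = _extract(linear_image, background_roi)
    s_log = _extract(log_image, signal_roi)
    b_log = _extract(log_image, background_roi)
    return RoiStats(
        mu_s_lin=float(s_lin.mean()),
        sigma_b_lin=float(b_lin.std()),
        mu_s_log=float(s_log.mean()),
        sigma_s_log=float(s_log.std()),
        mu_b_log=float(b_log.mean()),
        sigma_b_log=float(b_log.std()),
        roi_shape=(signal_roi[2], signal_roi[3]),
    )


def snr_db(stats: RoiStats) -> float:
    """Signal-to-noise ratio in dB on linear data."""
    if stats.sigma_b_lin <= 0:
        raise ValueError("zero background standard deviation: SNR undefined")
    return 10.0 * np.log10(stats.mu_s_lin**2 / stats.sigma_b_lin**2)


def cnr(stats: RoiStats) -> float:
    """Contrast-to-noise ratio between signal and background (log data)."""
    denom = stats.sigma_s_log**2 + stats.sigma_b_log**2
    if denom <= 0:
        raise ValueError("zero variances: CNR undefined")
    return (stats.mu_s_log - stats.mu_b_log) / np.sqrt(denom)


def enl(stats: RoiStats) -> float:
    """Equivalent number of looks of the signal ROI (log data).

    Measures the smoothness of a speckle-corrupted homogeneous region;
    grows with the number of averaged independent looks.
    """
    if stats.sigma_s_log <= 0:
        raise ValueError("zero signal standard deviation: ENL undefined (constant ROI)")
    return stats.mu_s_log**2 / stats.sigma_s_log**2


def evaluate_image(
    linear_image: np.ndarray,
    signal_rois: list[tuple[int, int, int, int]],
    background_rois: list[tuple[int, int, int, int]],
) -> SpeckleMetrics:
    """SNR/CNR/ENL of one image, averaged over paired ROIs.

    Signal ROI i is paired with background ROI i (a single background ROI
    is reused for all pairs).
    """
    if not signal_rois:
        raise ValueError("need at least one signal ROI")
    if len(background_rois) not in (1, len(signal_rois)):
        raise ValueError("background ROIs must number 1 or match the signal ROIs")
    log_image = log_scale(np.asarray(linear_image, dtype=float))
    per_roi = []
    vals = {"snr": [], "cnr": [], "enl": []}
    for i, s_roi in enumerate(signal_rois):
        b_roi = background_rois[i % len(background_rois)]
        st = roi_stats(linear_image, s_roi, b_roi, log_image=log_image)
        per_roi.append(st)
        vals["snr"].append(snr_db(st))
        vals["cnr"].append(cnr(st))
        vals["enl"].append(enl(st))
    return SpeckleMetrics(
        snr_db=float(np.mean(vals["snr"])),
        cnr=float(np.mean(vals["cnr"])),
        enl=float(np.mean(vals["enl"])),
        n_rois=len(signal_rois),
        per_roi=per_roi,
    )


def place_rois_from_boundaries(
    ilm_rows: np.ndarray,
    image_shape: tuple[int, int],
    n_rois: int = 5,
    roi_shape: tuple[int, int] = ROI_SHAPE,
    signal_offset: int = 4,
    background_top: int = 8,
    exclude_cols: np.ndarray | None = None,
) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int, int, int]]]:
    """Auto-place paired signal (RNFL) and background (vitreous) ROIs.

    ROIs are spread evenly across the B-scan width; each signal ROI starts
    ``signal_offset`` rows below the local ILM maximum, each background ROI
    ends above the local ILM minimum.  Columns in ``exclude_cols`` (e.g.
    vessels) are avoided by nudging the ROI sideways.
    """
    ilm_rows = np.asarray(ilm_rows)
    h, w = roi_shape
    depth, n_cols = image_shape
    if n_rois * w > n_cols:
        raise ValueError("too many ROIs for the image width")
    centers = (np.arange(n_rois) + 0.5) * n_cols / n_rois
    signal, background = [], []
    for c0 in centers:
        col = int(round(c0 - w / 2))
        col = max(0, min(col, n_cols - w))
        if exclude_cols is not None:
            for shift in range(0, n_cols, max(1, w // 4)):
                for cand in (col + shift, col - shift):
                    if 0 <= cand <= n_cols - w and not exclude_cols[cand : cand + w].any():
                        col = cand
                        break
                else:
                    continue
                break
        local = ilm_rows[col : col + w]
        s_top = int(local.max()) + signal_offset
        if s_top + h > depth:
            raise ValueError("signal ROI does not fit below the ILM")
        b_top = background_top
        if b_top + h > int(local.min()) - 4:
            b_top = max(0, int(local.min()) - 4 - h)
        signal.append((s_top, col, h, w))
        background.append((b_top, col, h, w))
    return signal, background
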