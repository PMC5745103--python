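"""Graph-based retinal boundary segmentation (ILM and RPE).

Each boundary is the exact minimum-cost left-to-right path through a cost
image, solved by dynamic programming with a hard column-to-column jump
constraint.  The ILM uses a signed vertical-gradient cost (dark-to-bright
edge, with a small depth penalty selecting the topmost strong edge); the
RPE uses a brightness cost (path through the brightest band below the
ILM).  Vessel-shadowed columns are flagged and the boundary is linearly
interpolated across them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LayerMap",
    "gradient_cost",
    "find_boundary",
    "segment_ilm",
    "segment_rpe",
    "segment_layers",
    "SegmentationError",
]


class SegmentationError(RuntimeError):
    """Raised when no plausible boundary is found."""


@dataclass
class LayerMap:
    """Named per-A-scan boundary rows of one B-scan (0-based, real-valued).

    ILM must lie above the RPE everywhere; vessel-flagged columns mark
    A-scans whose boundary was interpolated under a vessel shadow.
    """

    boundaries: dict[str, np.ndarray]
    depth: int
    vessel_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, rows in self.boundaries.items():
            rows = np.asarray(rows, dtype=float)
            self.boundaries[name] = rows
            if np.any(rows < 0) or np.any(rows > self.depth - 1):
                raise ValueError(f"boundary {name!r} outside [0, depth-1]")
        if "ILM" in self.boundaries and "RPE" in self.boundaries:
            if not np.all(self.boundaries["ILM"] < self.boundaries["RPE"]):
                raise ValueError("ILM must lie anterior to RPE at every A-scan")

    @property
    def ilm(self) -> np.ndarray:
        return self.boundaries["ILM"]

    @property
    def rpe(self) -> np.ndarray:
        return self.boundaries["RPE"]


def _log_blur(bscan: np.ndarray, sigma: float, log_floor: float) -> np.ndarray:
    return ndimage.gaussian_filter(np.log10(np.maximum(bscan, log_floor)), sigma)


def gradient_cost(
    bscan: np.ndarray,
    polarity: str = "dark_to_bright",
    sigma: float = 2.0,
    log_floor: float = 1.0,
) -> np.ndarray:
    """Edge cost in [0, 1]: low at vertical edges of the requested polarity.

    Computed as 1 minus the min-max-normalized signed vertical gradient of
    the log-scaled, lightly blurred intensity; ``dark_to_bright`` rewards
    intensity increasing with depth.  A constant image has uniform cost 1.
    """
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError("polarity must be 'dark_to_bright' or 'bright_to_dark'")
    bscan = np.asarray(bscan, dtype=float)
    g = np.gradient(_log_blur(bscan, sigma, log_floor), axis=0)
    if polarity == "bright_to_dark":
        g = -g
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.ones_like(g)
    return 1.0 - (g - lo) / (hi - lo)


def find_boundary(cost: np.ndarray, jump_limit: int = 2) -> np.ndarray:
    """Exact minimum-cost left-to-right path through a cost image.

    Dynamic programming over columns; successive columns may differ by at
    most ``jump_limit`` rows.  Ties are broken toward the smaller row
    index.  Returns one row index per column.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        raise ValueError("empty cost image")
    n_rows, n_cols = cost.shape
    j = int(jump_limit)
    acc = cost[:, 0].copy()
    back = np.zeros((n_rows, n_cols), dtype=np.int32)
    pad = np.full(j, np.inf)
    for c in range(1, n_cols):
        # windows of prior accumulated costs reachable within the jump limit
        padded = np.concatenate([pad, acc, pad])
        win = np.lib.stride_tricks.sliding_window_view(padded, 2 * j + 1)
        arg = np.argmin(win, axis=1)  # first minimum -> smaller row on ties
        back[:, c] = np.arange(n_rows) + arg - j
        acc = win[np.arange(n_rows), arg] + cost[:, c]
    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(acc))  # argmin takes the first (smallest row) tie
    for c in range(n_cols - 1, 0, -1):
        path[c - 1] = back[path[c], c]
    return path


def segment_ilm(
    bscan: np.ndarray,
    jump_limit: int = 2,
    sigma: float = 2.0,
    depth_penalty: float = 0.3,
    max_mean_cost: float = 0.25,
) -> np.ndarray:
    """Segment the ILM: topmost strong dark-to-bright edge.

    The gradient cost gets a small linear depth penalty so that among
    strong edges the most anterior one wins; after pathfinding the mean
    edge cost along the path must be below ``max_mean_cost`` or a
    :class:`SegmentationError` is raised (no retina in the image).
    """
    bscan = np.asarray(bscan, dtype=float)
    cost = gradient_cost(bscan, "dark_to_bright", sigma=sigma)
    n_rows = cost.shape[0]
    biased = cost + depth_penalty * (np.arange(n_rows) / n_rows)[:, None]
    path = find_boundary(biased, jump_limit)
    mean_cost = float(cost[path, np.arange(cost.shape[1])].mean())
    if mean_cost > max_mean_cost:
        raise SegmentationError(
            f"no ILM edge found (mean path cost {mean_cost:.2f} > {max_mean_cost})"
        )
    return path


def _vessel_flags(
    bscan: np.ndarray, rpe_path: np.ndarray, shadow_fraction: float
) -> np.ndarray:
    """Columns whose RPE-band intensity collapses under a vessel shadow."""
    n_cols = bscan.shape[1]
    rows = np.clip(rpe_path[None, :] + np.arange(-3, 4)[:, None], 0, bscan.shape[0] - 1)
    band = bscan[rows, np.arange(n_cols)[None, :]].mean(axis=0)
    return band < shadow_fraction * np.median(band)


def _interp_flagged(path: np.ndarray, flags: np.ndarray) -> np.ndarray:
    if not flags.any() or flags.all():
        return path.astype(float)
    x = np.arange(path.size)
    return np.where(
        flags, np.interp(x, x[~flags], path[~flags].astype(float)), path.astype(float)
    )


def segment_rpe(
    bscan: np.ndarray,
    ilm_rows: np.ndarray | None = None,
    jump_limit: int = 2,
    sigma: float = 2.0,
    ilm_margin: int = 40,
    shadow_fraction: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment the RPE: brightest-band path below the ILM.

    Cost is 1 minus the normalized blurred log intensity, with rows above
    ILM + ``ilm_margin`` excluded.  Columns whose RPE-band intensity falls
    below ``shadow_fraction`` of the B-scan median are flagged as
    vessel-shadowed and linearly interpolated.  Returns (rows, flags).
    """
    bscan = np.asarray(bscan, dtype=float)
    if ilm_rows is None:
        ilm_rows = segment_ilm(bscan, jump_limit=jump_limit, sigma=sigma)
    smooth = _log_blur(bscan, sigma, 1.0)
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:
        raise SegmentationError("flat image: no RPE band")
    cost = 1.0 - (smooth - lo) / (hi - lo)
    n_rows = cost.shape[0]
    rows = np.arange(n_rows)[:, None]
    cost = np.where(rows < (np.asarray(ilm_rows) + ilm_margin)[None, :], 2.0, cost)
    path = find_boundary(cost, jump_limit)
    flags = _vessel_flags(bscan, path, shadow_fraction)
    return _interp_flagged(path, flags), flags


def segment_layers(bscan: np.ndarray, **kwargs) -> LayerMap:
    """Segment ILM and RPE of one B-scan into a :class:`LayerMap`."""
    ilm = segment_ilm(bscan)
    rpe, flags = segment_rpe(bscan, ilm_rows=ilm, **kwargs)
    return LayerMap(
        boundaries={"ILM": ilm.astype(float), "RPE": rpe},
        depth=bscan.shape[0],
        vessel_flags=flags,
    )
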