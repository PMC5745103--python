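"""Rigid-body registration, flattening and fusion of the three channels.

The three channels are acquired simultaneously, so the dominant
misalignment is an axial (depth) offset caused by small sample-arm length
mismatches; lateral shift and rotation are small.  Registration is
exhaustive FFT cross-correlation over translation with a small angular
search and quadratic sub-pixel refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

from .phantom import MultiChannelStack

__all__ = [
    "RigidTransform",
    "estimate_rigid",
    "apply_rigid",
    "register_triplet",
    "flatten",
    "unflatten",
    "fuse_volume",
]


@dataclass(frozen=True)
class RigidTransform:
    """dz/dx in pixels (axial/lateral), theta in degrees, about image centre.

    ``apply_rigid`` rotates by theta first, then shifts by (dz, dx).
    """

    dz: float = 0.0
    dx: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.theta) > 5.0:
            raise ValueError("rigid registration is fine alignment; |theta| <= 5 degrees")

    def inverse(self) -> "RigidTransform":
        # T(p) = R p + t  =>  T^-1(p) = R^-1 (p - t): rotate -theta then
        # shift by -R(-theta) t.
        th = np.deg2rad(-self.theta)
        c, s = np.cos(th), np.sin(th)
        # rows (z) and cols (x); rotation convention matches apply_rigid
        dz = -(c * self.dz - s * self.dx)
        dx = -(s * self.dz + c * self.dx)
        return RigidTransform(dz=dz, dx=dx, theta=-self.theta)


def apply_rigid(image: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample an image under a rigid transform; out-of-field pixels are 0."""
    image = np.asarray(image, dtype=float)
    out = image
    if transform.theta != 0.0:
        out = _sk_rotate(out, transform.theta, order=order, preserve_range=True, cval=0.0)
    if transform.dz != 0.0 or transform.dx != 0.0:
        out = ndimage.shift(out, (transform.dz, transform.dx), order=order, cval=0.0)
    return out


def _quadratic_peak(y_m1: float, y_0: float, y_p1: float) -> float:
    """Sub-sample offset of a parabola's vertex through three samples."""
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))

def _xcorr_peak(ref: np.ndarray, mov: np.ndarray, dz_range: int, dx_range: int):
    """Best translation of `mov` onto `ref` by FFT cross-correlation.

    Returns (dz, dx, score) with quadratic sub-pixel refinement; the search
    is restricted to |dz| <= dz_range, |dx| <= dx_range.
    """
    a = ref - ref.mean()
    b = mov - mov.mean()
    c = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    nz, nx = c.shape
    zs = np.fft.fftfreq(nz, 1.0 / nz).astype(int)  # signed shift per row index
    xs = np.fft.fftfreq(nx, 1.0 / nx).astype(int)
    zmask = np.abs(zs) <= dz_range
    xmask = np.abs(xs) <= dx_range
    sub = c[np.ix_(zmask, xmask)]
    iz, ix = np.unravel_index(np.argmax(sub), sub.shape)
    z_idx = np.nonzero(zmask)[0][iz]
    x_idx = np.nonzero(xmask)[0][ix]
    dz = float(zs[z_idx])
    dx = float(xs[x_idx])
    peak = c[z_idx, x_idx]
    dz += _quadratic_peak(c[(z_idx - 1) % nz, x_idx], peak, c[(z_idx + 1) % nz, x_idx])
    dx += _quadratic_peak(c[z_idx, (x_idx - 1) % nx], peak, c[z_idx, (x_idx + 1) % nx])
    norm = np.sqrt((a**2).sum() * (b**2).sum())
    return dz, dx, float(peak / norm) if norm > 0 else 0.0


def estimate_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    dz_range: int = 100,
    dx_range: int = 20,
    theta_range: float = 2.0,
    theta_step: float = 0.5,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``reference``.

    Maximizes the intensity cross-correlation over (dz, dx, theta); the
    angular search is a coarse grid over [-theta_range, theta_range]
    refined quadratically, translation is exhaustive within the stated
    ranges with sub-pixel interpolation.  An image moved down by +d yields
    dz = -d.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must have the same shape")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("flat image: no content to register")
    # light blur before scoring: keeps the similarity driven by structure
    # rather than by the speckle smoothing that interpolation introduces
    reference = ndimage.gaussian_filter(reference, 1.0)
    moving = ndimage.gaussian_filter(moving, 1.0)

    if theta_range <= 0:
        thetas = np.array([0.0])
    else:
        n = max(1, int(round(theta_range / theta_step)))
        thetas = np.linspace(-theta_range, theta_range, 2 * n + 1)
    results = []
    for th in thetas:
        mov = _sk_rotate(moving, th, order=1, preserve_range=True, cval=0.0) if th else moving
        results.append(_xcorr_peak(reference, mov, dz_range, dx_range))
    scores = np.array([r[2] for r in results])
    i = int(np.argmax(scores))
    theta = thetas[i]
    if 0 < i < len(thetas) - 1:
        step = thetas[1] - thetas[0]
        theta += step * _quadratic_peak(scores[i - 1], scores[i], scores[i + 1])
        mov = _sk_rotate(moving, theta, order=1, preserve_range=True, cval=0.0)
        dz, dx, _ = _xcorr_peak(reference, mov, dz_range, dx_range)
    else:
        dz, dx, _ = results[i]
    return RigidTransform(dz=dz, dx=dx, theta=float(theta))


def register_triplet(
    stack: MultiChannelStack, **search_kwargs
) -> tuple[MultiChannelStack, list[RigidTransform]]:
    """Register channels 2 and 3 onto channel 1.

    One transform per channel is estimated from the B-scan-averaged image
    (the channels are co-acquired, so the transform is common to all
    B-scans) and applied to every B-scan.  Returns the registered stack and
    the two transforms.
    """
    data = stack.data.copy()
    transforms = []
    ref = data[0].mean(axis=0)
    for c in (1, 2):
        t = estimate_rigid(ref, data[c].mean(axis=0), **search_kwargs)
        transforms.append(t)
        for b in range(data.shape[1]):
            data[c, b] = apply_rigid(data[c, b], t)
    out = MultiChannelStack(
        data=data,
        pattern=stack.pattern,
        axial_pixel_pitch_um=stack.axial_pixel_pitch_um,
        channel_azimuths_deg=stack.channel_azimuths_deg,
        registered=True,
    )
    return out, transforms


def flatten(
    bscan: np.ndarray, ilm_rows: np.ndarray, target_row: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each A-scan so the ILM lies on a common row (the median ILM row,
    or ``target_row`` when several channels must share one flat surface).

    Integer circular shifts are used so flatten -> unflatten is exactly
    invertible; returns (flattened image, per-column shifts).
    """
    bscan = np.asarray(bscan, dtype=float)
    ilm_rows = np.asarray(ilm_rows)
    depth, na = bscan.shape
    if ilm_rows.shape != (na,):
        raise ValueError("need one ILM row per A-scan")
    if np.any(ilm_rows < 0) or np.any(ilm_rows > depth - 1):
        raise ValueError("ILM boundary outside image range")
    target = int(round(float(np.median(ilm_rows)))) if target_row is None else int(target_row)
    shifts = target - np.round(ilm_rows).astype(int)
    rows = (np.arange(depth)[:, None] - shifts[None, :]) % depth
    return bscan[rows, np.arange(na)[None, :]], shifts


def unflatten(bscan: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Invert :func:`flatten` given its per-column shifts."""
    bscan = np.asarray(bscan, dtype=float)
    depth, na = bscan.shape
    rows = (np.arange(depth)[:, None] + np.asarray(shifts)[None, :]) % depth
    return bscan[rows, np.arange(na)[None, :]]


def fuse_volume(
    volumes: np.ndarray,
    ilm_maps: np.ndarray,
    mode: str = "mean",
) -> np.ndarray:
    """Fuse three registered volumes into one, re-warped to channel-1's surface.

    Each channel's B-scans are flattened with that channel's own ILM map,
    fused per voxel (``mean`` or ``max``), then unflattened with
    channel-1's shifts so the fused volume regains channel-1's realistic
    surface shape.  ``volumes`` is (3, bscans, depth, ascans); ``ilm_maps``
    is (3, bscans, ascans).
    """
    volumes = np.asarray(volumes, dtype=float)
    ilm_maps = np.asarray(ilm_maps)
    if volumes.ndim != 4 or volumes.shape[0] != 3:
        raise ValueError("volumes must be (3, bscans, depth, ascans)")
    if ilm_maps.shape != (3, volumes.shape[1], volumes.shape[3]):
        raise ValueError("ilm_maps must be (3, bscans, ascans)")
    if mode not in ("mean", "max"):
        raise ValueError("mode must be 'mean' or 'max'")
    nb = volumes.shape[1]
    fused = np.empty(volumes.shape[1:])
    for b in range(nb):
        # one common flat row per B-scan so the channels align after flattening
        target = int(round(float(np.median(ilm_maps[0, b]))))
        flats = []
        ch1_shifts = None
        for c in range(3):
            f, s = flatten(volumes[c, b], ilm_maps[c, b], target_row=target)
            flats.append(f)
            if c == 0:
                ch1_shifts = s
        combined = np.mean(flats, axis=0) if mode == "mean" else np.max(flats, axis=0)
        fused[b] = unflatten(combined, ch1_shifts)
    return fused
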