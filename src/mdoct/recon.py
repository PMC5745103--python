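"""Spectral-domain OCT reconstruction.

Raw spectral fringes are turned into linear-intensity A-scans by the
standard four-step chain: mean-spectrum subtraction, lambda-to-k
resampling, numerical dispersion compensation and FFT.  The A-scan is the
magnitude of the positive-frequency half of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import hilbert

from .phantom import MultiChannelStack, ScanPattern, SpectralFrameSet

__all__ = [
    "ReconConfig",
    "mean_spectrum_subtract",
    "resample_lambda_to_k",
    "dispersion_compensate",
    "reconstruct",
]


@dataclass(frozen=True)
class ReconConfig:
    """Parameters of the reconstruction chain.

    The four processing steps are fixed; these are their knobs: resampling
    interpolation order, the dispersion phase coefficients to compensate
    (same sign convention as the synthesis — the stage removes them), the
    spectral apodization window and optional FFT zero padding.
    """

    resample_interpolation: str = "cubic-spline"
    dispersion_coeffs: tuple[float, float] = (0.0, 0.0)
    window: str = "hann"
    zero_pad_factor: int = 1

    def __post_init__(self) -> None:
        if self.resample_interpolation not in ("linear", "cubic-spline"):
            raise ValueError("resample_interpolation must be 'linear' or 'cubic-spline'")
        if self.window not in ("none", "hann"):
            raise ValueError("window must be 'none' or 'hann'")
        if self.zero_pad_factor not in (1, 2, 4):
            raise ValueError("zero_pad_factor must be 1, 2 or 4")


def mean_spectrum_subtract(spectra: np.ndarray) -> np.ndarray:
    """Remove the DC/reference spectrum: subtract the per-spectral-pixel mean.

    ``spectra`` is (ascans, spectral pixels); output column means are zero.
    A single-A-scan frame is rejected (the mean would cancel the signal).
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need a frame of at least 2 A-scans")
    return spectra - spectra.mean(axis=0, keepdims=True)


def resample_lambda_to_k(
    spectra: np.ndarray,
    wavelength_grid_nm: np.ndarray,
    interpolation: str = "cubic-spline",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample spectra from the wavelength axis to a uniform wavenumber axis.

    k = 2*pi/lambda.  The output grid spans [k_min, k_max] with the same
    number of points, increasing; endpoints are preserved exactly.  Returns
    (resampled spectra, uniform k grid).
    """
    lam = np.asarray(wavelength_grid_nm, dtype=float)
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength grid must be strictly monotone")
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    k = 2.0 * np.pi / lam
    order = np.argsort(k)
    k_sorted = k[order]
    k_uniform = np.linspace(k_sorted[0], k_sorted[-1], lam.size)
    if interpolation == "cubic-spline":
        out = np.empty_like(spectra)
        for i, s in enumerate(spectra):
            out[i] = CubicSpline(k_sorted, s[order])(k_uniform)
    else:
        f = interp1d(k_sorted, spectra[:, order], axis=1, kind="linear")
        out = f(k_uniform)
    return out, k_uniform


def dispersion_compensate(
    complex_spectrum_k: np.ndarray,
    k_uniform: np.ndarray,
    coeffs: tuple[float, float],
    k0: float | None = None,
) -> np.ndarray:
    """Multiply the analytic spectrum by exp(-i [a2 (k-k0)^2 + a3 (k-k0)^3]).

    Pure phase: the magnitude spectrum is unchanged.  ``k0`` defaults to the
    grid centre.
    """
    a2, a3 = coeffs
    if k0 is None:
        k0 = 0.5 * (k_uniform[0] + k_uniform[-1])
    dk = k_uniform - k0
    return complex_spectrum_k * np.exp(-1j * (a2 * dk**2 + a3 * dk**3))


def _reconstruct_frame(
    frame: np.ndarray, lam: np.ndarray, config: ReconConfig, k0: float
) -> np.ndarray:
    """Full chain for one frame (ascans, n_spec) -> (depth, ascans) magnitudes."""
    sub = mean_spectrum_subtract(frame)
    res, k_uniform = resample_lambda_to_k(sub, lam, config.resample_interpolation)
    analytic = hilbert(res, axis=1)
    comp = dispersion_compensate(analytic, k_uniform, config.dispersion_coeffs, k0)
    n = lam.size
    if config.window == "hann":
        comp = comp * np.hanning(n)[None, :]
    n_fft = n * config.zero_pad_factor
    spec = np.fft.fft(comp, n=n_fft, axis=1)
    depth = (n // 2) * config.zero_pad_factor
    return np.abs(spec[:, :depth]).T


def reconstruct(
    frameset: SpectralFrameSet,
    config: ReconConfig | None = None,
    pattern: ScanPattern | None = None,
    center_wavelength_nm: float = 840.0,
) -> MultiChannelStack:
    """Run the four-step chain on every channel of a spectral frame set.

    Output depth pixels = spectral pixels / 2 * zero_pad_factor.  If
    ``pattern`` is omitted, the frames of each channel are treated as one
    B-scan.
    """
    config = config or ReconConfig()
    lam = frameset.wavelength_grid_nm
    k0 = 2.0 * np.pi / center_wavelength_nm
    n_ascans = frameset.spectra.shape[1]
    if pattern is None:
        pattern = ScanPattern("circumpapillary", ascans_per_bscan=n_ascans, bscans=1)
    nb, na = pattern.bscans, pattern.ascans_per_bscan
    if nb * na != n_ascans:
        raise ValueError("scan pattern does not match frame count")
    channels = []
    for c in range(3):
        frames = frameset.spectra[c].reshape(nb, na, lam.size)
        channels.append(np.stack([_reconstruct_frame(f, lam, config, k0) for f in frames]))
    depth = (lam.size // 2) * config.zero_pad_factor
    data = np.stack(channels)
    assert data.shape == (3, nb, depth, na)
    return MultiChannelStack(data=data, pattern=pattern, registered=True)
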