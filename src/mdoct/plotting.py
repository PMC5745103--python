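"""Profile and image figures (linear and polar azimuthal plots, RGB fusions)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_profiles", "plot_profiles_polar", "save_rgb"]


def plot_profiles(profiles, path: str | Path, kind: str = "smoothed") -> Path:
    """Normalized window-intensity vs azimuth, one curve per channel."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for p in profiles:
        ax.plot(p.azimuth_deg, getattr(p, kind), color=p.color, label=f"channel-{p.channel + 1}")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("normalized intensity")
    ax.set_xlim(0, 360)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_profiles_polar(profiles, path: str | Path, kind: str = "smoothed") -> Path:
    """Polar plot: intensity as radius vs azimuth angle."""
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    for p in profiles:
        theta = np.deg2rad(np.append(p.azimuth_deg, p.azimuth_deg[0]))
        r = getattr(p, kind)
        ax.plot(theta, np.append(r, r[0]), color=p.color)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def save_rgb(image: np.ndarray, path: str | Path) -> Path:
    """Save an RGB image in [0, 1] as PNG."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(np.clip(image, 0, 1), aspect="auto")
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
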